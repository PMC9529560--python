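# Methods

This note documents the models and procedures implemented in `vrascreen`,
the parameters that matter, the design choices made where the design was
genuinely open, and the limits of what the synthetic-data tests demonstrate.

## Fingerprint and similarity search

A molecule is fingerprinted by enumerating every linear fragment of 1–7
atoms via depth-first traversal of the bond graph. Single-atom fragments
whose element is C, N or O are discarded (they carry no discriminating
information and would saturate the bit vector). A step onto an atom already
on the current path terminates the fragment and records a ring-closure flag.
The fragment alphabet is deliberately minimal and deterministic: an atom is
`(atomic number, aromatic flag)`, a bond its order 1/2/3 or 4 for aromatic.
The canonical form of a fragment is the lexicographically smaller of its
forward and reversed encodings, so chemically identical fragments collapse
regardless of traversal direction. Each canonical fragment is hashed by a
fixed polynomial rolling hash (base 131) modulo 1021 — the largest prime not
exceeding 1023 — so bits 1021–1023 of the 1024-bit vector are never set.
No bit-compatibility with any external fingerprint implementation is
claimed; only the construction principle is shared.

Tanimoto similarity is `c/(a+b−c)` over set bits. Two all-zero fingerprints
compare as 1.0 (they describe the same — empty — fragment set, and this
avoids 0/0); empty vs non-empty is 0.0. The search index buckets the library
by popcount and prunes candidates with the bound `T ≤ min(a,b)/max(a,b)`;
pruning is exact, and the test suite verifies index ≡ exhaustive scan on
500-compound libraries. The similarity threshold comparison is non-strict
(≥ 0.7 by default) with a `strict` flag, since both conventions appear in
screening practice.

Diverse selection clusters fingerprint bit vectors with k-means
(k-means++ initialisation, fixed seed, 100 iterations) and takes up to a
configured number of members nearest each centroid, ties broken by library
index. Manual "visual inspection" steps of real campaigns are modelled by
this seeded cluster-then-pick procedure, since no reproducible manual
criterion exists.

## Ionization and charge groups

pKas are assigned from a SMARTS pattern table covering the common ionizable
groups (carboxylic, phosphonic/phosphate and sulfonic acids, tetrazole,
phenol, thiol; aliphatic amines, guanidine, amidine, imidazole, aniline,
pyridine), each mapped to a literature mean micro-pKa. Patterns match in
priority order and claim their atoms, so a guanidine nitrogen is never
re-counted as an amine; polyprotic phosphonates count one group per acidic
O–H (at the first-dissociation pKa — a documented simplification). A
per-compound override CSV replaces table values where better data exist; the
shipped amino-acid table carries reference free-amino-acid pKas.

Two counting rules are exposed:

* **threshold** (screening default): acids with pKa < 6.4 count as negative
  charge groups, bases with pKa > 8.4 as positive. The cutoffs bracket the
  pH 6 formulation window so counted groups are essentially fully charged
  there; the rule itself is pH-independent.
* **window**: a group counts when its Henderson–Hasselbalch charged fraction
  at the target pH (default 6.0) reaches `min_charged_fraction`
  (default 0.10). This is the rule under which histidine's imidazole
  (pKa ≈ 6.0, half-protonated at pH 6) counts, reproducing the amino-acid
  census {Arg, His, Lys, Glu, Asp} — the threshold rule alone would exclude
  histidine. Screening reproduction uses threshold mode; amino-acid and
  dipeptide analyses use window mode.

Charges at a pH come from the independent-sites (non-interacting)
Henderson–Hasselbalch model: net charge is the expected signed sum, absolute
charge the sum of charged fractions, and the major-species charge rounds
each site to its most populated state (ties round to uncharged). Site–site
coupling and microstate enumeration are deliberately out of scope; for the
small, flexible excipients targeted here the independent model preserves the
rule-level conclusions the pipeline rests on.

## Descriptors

MW (average atomic masses), SlogP, H-bond donors/acceptors, rotatable bonds,
ring count, fraction Csp³ and topological PSA come from RDKit. SlogP is
computed on the neutralised species, matching the convention that partition
coefficients describe the uncharged form. SASA is the Labute
atomic-contribution approximate surface area, chosen so the pipeline never
needs a 3D conformer; PSA/SASA is used only as a bounded polarity covariate,
where an approximate surface preserves ordering. Because PSA and SASA come
from two different approximations the raw ratio can marginally exceed 1 for
densely polar molecules; it is clipped to [0, 1].

## Screening cascade

All numeric bounds are inclusive. Filters are conjunctive, so pass/fail is
order-independent; the per-stage removal counts are reported in the fixed
order MW → SlogP → charge groups → alerts (cheap filters first) to keep
reports reproducible. Substructure exclusion lists (assay interference,
reactive groups) are user-supplied data files; two small starter lists ship
with the package. The toxicity gate is a pluggable structural-alert stub
with expert-system gating semantics — a compound is alert-free iff no
matched alert has likelihood ≥ "plausible" — and carries no alert knowledge
of its own.

## Dipeptide dual excipients

The 20 canonical proteinogenic amino acids are enumerated into all 400
ordered dipeptides (sequence direction distinguishes AB from BA) by textual
SMILES condensation with loss of one water; the mass identity
`MW(AB) = MW(A) + MW(B) − 18.02 Da` is verified across the full library.
Dipeptide pKas use the independent-groups model with backbone shifts: the
free N-terminal amine is set to 8.2 and the C-terminal carboxyl to 3.1
(typical peptide backbone values), while side chains inherit free-amino-acid
pKas. A dual excipient must buffer near the target pH — at least one pKa in
the inclusive window [5, 7] — and carry ≥ 3 charge groups under the window
rule. Under the shipped table only histidine contributes a pKa in [5, 7], so
the 39 His-containing dipeptides qualify; all of them also pass the
charge-group requirement.

## Viscosity model and classifier

Protein-in-water baselines follow `η = a·e^{b·c}`. The fit is linear least
squares on `ln η` — it weights relative rather than absolute error, matching
the multiplicative error structure of viscometry, and is deterministic.
Relative viscosity divides each excipient measurement by the baseline
prediction at that sample's own (spectrophotometrically determined, hence
jittered) protein concentration. Concentrations extrapolating more than 10%
beyond the fitted range trigger a warning, not an error. Per-mAb replicates
are averaged first; the average over mAbs is the unweighted arithmetic mean
(the geometric mean was the plausible alternative; arithmetic was chosen as
the conventional reading of "average" and the two differ negligibly at the
observed ratio spread). A compound is a VRA iff that average is ≤ 0.8,
inclusive — one experimental error (~0.1 in relative viscosity) above the
0.5–0.6 benchmark range of arginine, the reference excipient.

## Statistics

The VRA label is encoded 1/0 and correlated with descriptors by Pearson's r,
which for a binary variable is the point-biserial coefficient; constant
columns are reported as undefined rather than zero, and no multiple-testing
correction is applied (the correlations are descriptive). The ≥ 3 vs ≤ 2
charge-group comparison of average relative viscosity uses the two-sided
Mann–Whitney U test: exact null enumeration when both groups have ≤ 8
observations without ties, otherwise the tie- and continuity-corrected
normal approximation (at the 8/8 switchover the two paths agree to ~0.01 in
p). The charge-group rule of thumb `n_charge_groups ≥ k` is scored against
the measured labels by its confusion matrix (sensitivity, specificity,
precision, accuracy, balanced accuracy), with k sweepable over 1–5.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

| parameter | default | rationale |
|---|---|---|
| compounds per study | 94 | size of the experimentally evaluated set |
| charge-count distribution (0–5) | .05/.10/.20/.30/.20/.15 | screening sets are enriched in multi-charge candidates |
| P(true reducer) | logistic(−7 + 3·n_cg) | reducers concentrate at ≥ 3 charge groups |
| reducer ratio | 0.6 ± 0.1 | arginine benchmark 0.5–0.6 |
| non-reducer ratio | 1.0 ± 0.1 | stated experimental error ~0.1 |
| mAb baselines (a, b) | (0.85, 0.021), (0.60, 0.020) | both 10–30 cP at 150 mg/mL |
| baseline grid | 120–200 mg/mL, 6 points | measured baseline range |
| measurement noise | 5% cv, log-normal | multiplicative, preserves positivity |
| concentration jitter | sd 5 mg/mL at 150 | per-sample concentration determination |
| excipient concentration | 25 mM | study design |

Compound structures come from a scaffold grammar (alkyl backbone, ionizable
substituents on separated carbons, random neutral decorations), which keeps
the charge ground truth exact by construction — verified by round-tripping
every generated structure through the pKa annotator — and the library
download-free. The grammar does **not** emulate vendor-catalog chemistry:
generated molecules are homologous polyfunctional alkanes, so passing tests
demonstrate that the pipeline recovers planted statistical structure
(charge–viscosity association, effect sizes, calibrated type-I error), not
that the charge-group rule generalises to arbitrary chemotypes or real
formulations. Replicate-based checks use 100 studies for power and 400 for
type-I calibration, sizes at which the binomial uncertainty on the reported
rates is ~2%.

## Known limitations

* The pattern-table pKas are literature means for isolated functional
  groups; they do not reproduce any commercial predictor, and sequential
  (interacting) pKas of peptides are approximated by independent sites with
  fixed backbone shifts.
* The fingerprint is not bit-compatible with the original path-based
  implementations; only rule-level behaviour (similar compounds score high)
  is comparable.
* The toxicity stub supplies gating semantics only; its predictive value is
  entirely that of the user-supplied alert list.
* The viscosity model is Newtonian and shear-rate free; pH drift during
  up-concentration is carried as metadata, not corrected.
* Screening counts against multi-million-compound vendor catalogs are out of
  scope; the cascade is validated on synthetic and fixture-scale libraries.
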