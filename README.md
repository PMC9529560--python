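# vrascreen

Computational screening and analysis toolkit for discovering
**viscosity-reducing agents (VRAs)** — small-molecule excipients that lower
the viscosity of concentrated monoclonal-antibody (mAb) formulations so that
high-dose products remain syringeable for subcutaneous administration.

It is written for formulation scientists and cheminformaticians who want to
triage excipient candidates *in silico* before committing viscometer time.
The package implements the full pipeline:

* **Path-based 1024-bit fingerprints** — all linear fragments of 1–7 atoms
  (single-atom C/N/O ignored; ring closures terminate and flag a fragment)
  are canonicalised, hashed into [0, 1020] and set as bits; similarity is the
  Tanimoto index `T = c/(a + b − c)` with a popcount-pruned search index, plus
  k-means clustering for diverse subset selection.
* **Charge-group calculus** — ionizable groups are assigned pKas from a
  transparent SMARTS pattern table (overridable per compound); a *negative
  charge group* is an acid with pKa < 6.4 and a *positive charge group* a base
  with pKa > 8.4 (threshold rule), or any group ≥ 10% charged at the target pH
  (window rule). Net, absolute and major-species charges follow
  Henderson–Hasselbalch under an independent-sites model.
* **Screening campaigns** — similarity search, physicochemical windows
  (MW 100–300 Da, SlogP −2 to 2, ≥ 3 charge groups), substructure exclusion
  lists, a pluggable structural-alert toxicity gate, and a dipeptide
  dual-excipient design that pairs buffering capacity (a pKa in [5, 7]) with
  ≥ 3 charge groups.
* **Viscosity model** — per-mAb exponential baselines `η = a·e^{b·c}` fitted
  in log space over 120–200 mg/mL; relative viscosity `η/η0` at each sample's
  own protein concentration; a compound is a VRA when its average relative
  viscosity over the model mAbs is ≤ 0.8.
* **Analysis layer** — point-biserial correlations of the binary VRA label
  with molecular descriptors, two-sided Mann–Whitney comparison of the ≥ 3 vs
  ≤ 2 charge-group strata, confusion-matrix metrics for the charge-group rule
  of thumb, and the standard scatter panels.
* **Synthetic study generator** — seeded libraries with exact charge-group
  ground truth and two-mAb measurement sets (10–30 cP baselines at
  150 mg/mL, 5% multiplicative noise), so the entire pipeline runs and is
  testable without any external data.

## Worked example

Simulate a 94-compound screening study on two mAbs and analyse it:

```python
from vrascreen.simulate import SimConfig, run_synthetic_study
from vrascreen.vstats import correlate_classifier, group_comparison, evaluate_rule

table = run_synthetic_study(SimConfig(seed=1))
print(f"compounds tested:        {len(table)}")
print(f"classified as VRA:       {int(table['is_vra'].sum())} ({100*table['is_vra'].mean():.1f}%)")
r = correlate_classifier(table, ["mw", "slogp", "n_charge_groups"])
print("point-biserial r vs VRA: " + ", ".join(f"{k}={v:+.3f}" for k, v in r.items()))
t = group_comparison(table)
print(f"Mann-Whitney (>=3 vs <=2 charge groups): U={t.u:.0f}, p={t.p:.2e} ({t.n1} vs {t.n2})")
e = evaluate_rule(table, k=3)
print(f"rule 'n_charge_groups >= 3': sensitivity={e.sensitivity:.3f}, "
      f"specificity={e.specificity:.3f}, balanced accuracy={e.balanced_accuracy:.3f}")
```

which prints:

```
compounds tested:        94
classified as VRA:       67 (71.3%)
point-biserial r vs VRA: mw=+0.570, slogp=-0.106, n_charge_groups=+0.774
Mann-Whitney (>=3 vs <=2 charge groups): U=77, p=2.59e-12 (66 vs 28)
rule 'n_charge_groups >= 3': sensitivity=0.955, specificity=0.926, balanced accuracy=0.941
```

Reading the output: about 71% of compounds reduce viscosity below the 0.8
cutoff; the charge-group count correlates with the VRA label far more
strongly (r = +0.77) than molecular weight or SlogP; compounds with three or
more charge groups have significantly lower relative viscosities than the
rest; and the simple rule "three or more charge groups" recovers the true
reducers with ~94% balanced accuracy.

The same steps are available from the shell:

```bash
vrascreen simulate --seed 1 --outdir fixtures/
vrascreen viscfit  --measurements fixtures/measurements.csv --out fits.json
vrascreen classify --measurements fixtures/measurements.csv --fits fits.json --out vra.csv
vrascreen similarity --queries known_vras.smi --library vendor.smi --threshold 0.7 --out hits.csv
vrascreen filter --library safe.smi --campaign safe_library --report report.json
```

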