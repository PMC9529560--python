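"""The virtual-screening cascade: composable filter stages over a library.

Three screening campaigns are expressed as filter pipelines:

* ``similarity`` — fingerprint Tanimoto search against known viscosity
  reducers, followed by a seeded diverse sample of the hits (the study's
  manual "diverse selection" steps are modelled as cluster-then-pick).
* ``chemspace`` — substructure exclusions (assay interference, reactive
  groups) then the physicochemical window: MW in [100, 300] Da, SlogP in
  [-2, 2], at least three charge groups under the pKa threshold rule.
* ``safe_library`` — duplicate removal, SlogP <= 2, at least three charge
  groups at pH 6.0, and a structural-alert toxicity gate.
* ``dipeptide`` — delegated to the peptide builder's dual-excipient filter.

All numeric bounds are inclusive. Stages run in the fixed order
MW -> SlogP -> charge groups -> alerts and the report records the count
removed at each stage, so pass/fail is order-independent (conjunctive
filters) while per-stage counts are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

from rdkit import Chem

from .chem import Compound, compute_descriptors
from .ionization import ChargeRule, assign_pkas, count_charge_groups
from . import pathfp

__all__ = [
    "FilterSpec",
    "ScreenReport",
    "ConfigError",
    "apply_physchem_filter",
    "apply_pattern_exclusions",
    "toxicity_alert_stub",
    "run_campaign",
    "load_pattern_file",
    "load_alert_file",
    "CAMPAIGNS",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Physicochemical filter bounds; ``None`` disables a bound."""

    mw_min: float | None = 100.0
    mw_max: float | None = 300.0
    slogp_min: float | None = -2.0
    slogp_max: float | None = 2.0
    min_charge_groups: int = 3
    charge_rule: ChargeRule = field(default_factory=ChargeRule.threshold)
    require_alert_free: bool = False

    def __post_init__(self) -> None:
        if self.mw_min is not None and self.mw_max is not None and not self.mw_min < self.mw_max:
            raise ConfigError("mw_min must be < mw_max")
        if self.slogp_min is not None and self.slogp_max is not None and not self.slogp_min < self.slogp_max:
            raise ConfigError("slogp_min must be < slogp_max")
        if self.min_charge_groups < 0:
            raise ConfigError("min_charge_groups must be >= 0")


@dataclass
class ScreenReport:
    """Outcome of a filter pipeline: per-stage removal counts + survivors."""

    input_count: int
    removed_by_stage: dict[str, int]
    passed: list[str]
    passed_compounds: list[Compound] = field(default_factory=list, repr=False)

    def check(self) -> None:
        assert self.input_count == sum(self.removed_by_stage.values()) + len(self.passed)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"input_count": self.input_count, "removed_by_stage": self.removed_by_stage, "passed": self.passed},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_physchem_filter(
    library: Sequence[Compound],
    spec: FilterSpec,
    *,
    alert_db: Sequence[tuple[str, str, str]] = (),
    pka_overrides: Mapping[tuple[str, str], float] | None = None,
) -> ScreenReport:
    """MW -> SlogP -> charge-group -> (optional) alert gate, inclusive bounds."""
    removed = {"mw": 0, "slogp": 0, "charge_groups": 0, "alerts": 0}
    passed: list[Compound] = []
    for c in library:
        d = compute_descriptors(c)
        if (spec.mw_min is not None and d.mw < spec.mw_min) or (spec.mw_max is not None and d.mw > spec.mw_max):
            removed["mw"] += 1
            continue
        if (spec.slogp_min is not None and d.slogp < spec.slogp_min) or (
            spec.slogp_max is not None and d.slogp > spec.slogp_max
        ):
            removed["slogp"] += 1
            continue
        groups = assign_pkas(c, overrides=pka_overrides)
        n_pos, n_neg = count_charge_groups(groups, spec.charge_rule)
        if n_pos + n_neg < spec.min_charge_groups:
            removed["charge_groups"] += 1
            continue
        if spec.require_alert_free and not alert_free(c, alert_db):
            removed["alerts"] += 1
            continue
        passed.append(c)
    report = ScreenReport(
        input_count=len(library),
        removed_by_stage=removed,
        passed=[c.id for c in passed],
        passed_compounds=passed,
    )
    report.check()
    return report


# ---------------------------------------------------------------------------
# Substructure exclusion lists
# ---------------------------------------------------------------------------

def _compile_pattern(smarts: str) -> Chem.Mol:
    patt = Chem.MolFromSmarts(smarts)
    if patt is None:
        raise ConfigError(f"invalid substructure pattern: {smarts!r}")
    return patt


def load_pattern_file(path: str | Path) -> list[tuple[str, str]]:
    """Read '(SMARTS name)' lines; '#' comments allowed. Returns (smarts, name)."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        out.append((parts[0], parts[1] if len(parts) > 1 else parts[0]))
    return out


def builtin_pattern_list(name: str) -> list[tuple[str, str]]:
    """Shipped starter lists: 'assay_interference' or 'reactive_groups'."""
    text = resources.files("vrascreen.data").joinpath(f"{name}.txt").read_text()
    out = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if line:
            parts = line.split()
            out.append((parts[0], parts[1] if len(parts) > 1 else parts[0]))
    return out


def apply_pattern_exclusions(
    library: Sequence[Compound], patterns: Sequence[tuple[str, str]]
) -> ScreenReport:
    """Remove any compound matching at least one substructure pattern."""
    compiled = [(_compile_pattern(sm), name) for sm, name in patterns]
    passed = []
    n_removed = 0
    for c in library:
        mol = c.mol()
        if any(mol.HasSubstructMatch(p) for p, _ in compiled):
            n_removed += 1
        else:
            passed.append(c)
    report = ScreenReport(
        input_count=len(library),
        removed_by_stage={"pattern_exclusion": n_removed},
        passed=[c.id for c in passed],
        passed_compounds=passed,
    )
    report.check()
    return report


# ---------------------------------------------------------------------------
# Toxicity structural-alert stub
# ---------------------------------------------------------------------------

_LIKELIHOOD_ORDER = {
    "impossible": 0, "improbable": 1, "doubted": 2, "equivocal": 3,
    "plausible": 4, "probable": 5, "certain": 6,
}


def toxicity_alert_stub(
    c: Compound, alert_db: Sequence[tuple[str, str, str]]
) -> list[tuple[str, str, str]]:
    """Return every (pattern, endpoint, likelihood) alert the compound triggers.

    This is a pluggable stand-in with the same gating semantics as a
    rule-based expert system: the alert knowledge itself is user-supplied
    data, not part of the package.
    """
    mol = c.mol()
    triggered = []
    for smarts, endpoint, likelihood in alert_db:
        if likelihood.lower() not in _LIKELIHOOD_ORDER:
            raise ConfigError(f"unknown likelihood {likelihood!r} for alert {smarts!r}")
        if mol.HasSubstructMatch(_compile_pattern(smarts)):
            triggered.append((smarts, endpoint, likelihood))
    return triggered


def alert_free(c: Compound, alert_db: Sequence[tuple[str, str, str]]) -> bool:
    """Alert-free iff no triggered alert has likelihood >= plausible."""
    return not any(
        _LIKELIHOOD_ORDER[lk.lower()] >= _LIKELIHOOD_ORDER["plausible"]
        for _, _, lk in toxicity_alert_stub(c, alert_db)
    )


def load_alert_file(path: str | Path) -> list[tuple[str, str, str]]:
    """Alert DB CSV: columns {pattern, endpoint, likelihood}."""
    import csv

    with open(path, newline="") as fh:
        return [(r["pattern"], r["endpoint"], r["likelihood"]) for r in csv.DictReader(fh)]


# ---------------------------------------------------------------------------
# Campaigns
# ---------------------------------------------------------------------------

CAMPAIGNS = ("similarity", "chemspace", "safe_library", "dipeptide")


def _dedupe(library: Sequence[Compound]) -> tuple[list[Compound], int]:
    seen: set[str] = set()
    out = []
    for c in library:
        can = c.canonical_smiles()
        if can in seen:
            continue
        seen.add(can)
        out.append(c)
    return out, len(library) - len(out)


def run_campaign(
    library: Sequence[Compound], campaign: str, config: Mapping | None = None
) -> ScreenReport:
    """Run one named screening campaign over a library.

    ``config`` keys (all optional unless noted): queries (similarity;
    required), threshold, sample_size, seed, patterns, filters (a FilterSpec),
    alert_db, pka_overrides, amino_acids / min_groups / pka window (dipeptide).
    """
    cfg = dict(config or {})
    if campaign == "similarity":
        queries = cfg.get("queries")
        if not queries:
            raise ConfigError("similarity campaign requires non-empty 'queries'")
        hits = pathfp.similarity_search(
            queries, library, threshold=cfg.get("threshold", 0.7), strict=cfg.get("strict", False)
        )
        hit_ids = {h.hit_id for h in hits}
        hit_compounds = [c for c in library if c.id in hit_ids]
        removed = {"similarity": len(library) - len(hit_compounds)}
        sample_size = cfg.get("sample_size")
        if sample_size is not None and sample_size < len(hit_compounds):
            picked = pathfp.cluster_and_pick(
                hit_compounds, k=sample_size, per_cluster=1, seed=cfg.get("seed", 0)
            )
            removed["diverse_sample"] = len(hit_compounds) - len(picked)
            hit_compounds = picked
        report = ScreenReport(len(library), removed, [c.id for c in hit_compounds], hit_compounds)
        report.check()
        return report

    if campaign == "chemspace":
        patterns = list(cfg.get("patterns", builtin_pattern_list("assay_interference") + builtin_pattern_list("reactive_groups")))
        excl = apply_pattern_exclusions(library, patterns)
        spec = cfg.get("filters", FilterSpec())
        phys = apply_physchem_filter(excl.passed_compounds, spec, pka_overrides=cfg.get("pka_overrides"))
        removed = {**excl.removed_by_stage, **phys.removed_by_stage}
        report = ScreenReport(len(library), removed, phys.passed, phys.passed_compounds)
        report.check()
        return report

    if campaign == "safe_library":
        deduped, n_dup = _dedupe(library)
        spec = cfg.get(
            "filters",
            FilterSpec(mw_min=None, mw_max=None, slogp_min=None, slogp_max=2.0,
                       min_charge_groups=3, charge_rule=ChargeRule.window(ph=6.0),
                       require_alert_free=True),
        )
        phys = apply_physchem_filter(
            deduped, spec, alert_db=cfg.get("alert_db", ()), pka_overrides=cfg.get("pka_overrides")
        )
        removed = {"duplicates": n_dup, **phys.removed_by_stage}
        report = ScreenReport(len(library), removed, phys.passed, phys.passed_compounds)
        report.check()
        return report

    if campaign == "dipeptide":
        from . import peptides

        aas = cfg.get("amino_acids") or peptides.load_amino_acids()
        dps = peptides.enumerate_dipeptides(aas)
        candidates = peptides.dual_excipient_candidates(
            dps,
            rule=cfg.get("charge_rule", ChargeRule.window(ph=6.0)),
            min_groups=cfg.get("min_groups", 3),
            pka_low=cfg.get("pka_low", 5.0),
            pka_high=cfg.get("pka_high", 7.0),
        )
        kept_ids = [cand.dipeptide.compound.id for cand in candidates]
        buffered = peptides.buffering_filter(dps, cfg.get("pka_low", 5.0), cfg.get("pka_high", 7.0))
        removed = {
            "buffering": len(dps) - len(buffered),
            "charge_groups": len(buffered) - len(kept_ids),
        }
        report = ScreenReport(len(dps), removed, kept_ids, [cand.dipeptide.compound for cand in candidates])
        report.check()
        return report

    raise ConfigError(f"unknown campaign {campaign!r}; expected one of {CAMPAIGNS}")
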