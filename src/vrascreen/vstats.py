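"""Descriptor-viscosity analysis: correlations, group tests, rule metrics, plots.

Joins the per-compound VRA classification with the descriptor panel and
charge profile into one analysis table, then provides

* point-biserial Pearson correlations between the binary VRA label and each
  descriptor (the label is encoded 1 = VRA, so descriptors enriched in
  viscosity reducers correlate positively);
* a two-sided Mann-Whitney U comparison of average relative viscosity
  between compounds with >= 3 and <= 2 charge groups (exact null enumeration
  for small tie-free groups, tie-corrected normal approximation otherwise);
* confusion-matrix metrics for the rule "n_charge_groups >= k predicts VRA";
* the descriptor scatter panels with the 0.8 threshold line.

Correlations are descriptive; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import Compound, compute_descriptors, DescriptorSet
from .ionization import ChargeProfile
from .viscosity import VRARecord

DEFAULT_CORRELATION_COLUMNS = (
    "mw", "slogp", "hbd", "hba", "rot_bonds", "rings", "frac_csp3",
    "psa", "psa_sasa", "n_charge_groups", "net_charge",
)


def build_analysis_table(
    records: Sequence[VRARecord],
    compounds: Mapping[str, Compound] | Sequence[Compound] | None = None,
    profiles: Mapping[str, ChargeProfile] | None = None,
) -> pd.DataFrame:
    """One row per classified compound: VRA label + descriptors + charges."""
    if compounds is not None and not isinstance(compounds, Mapping):
        compounds = {c.id: c for c in compounds}
    rows = []
    for r in records:
        row: dict = {
            "compound_id": r.compound_id,
            "avg_rel_visc": r.avg_rel_visc,
            "is_vra": int(r.is_vra),
        }
        for mab, v in r.rel_visc_per_mab.items():
            row[f"rel_visc_{mab}"] = v
        if compounds is not None and r.compound_id in compounds:
            d = compute_descriptors(compounds[r.compound_id])
            row.update({f: getattr(d, f) for f in DescriptorSet.FIELDS})
        if profiles is not None and r.compound_id in profiles:
            p = profiles[r.compound_id]
            row.update(
                n_charge_groups=p.n_charge_groups, n_pos=p.n_pos, n_neg=p.n_neg,
                net_charge=p.net_charge, abs_charge=p.abs_charge,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_classifier(
    table: pd.DataFrame, descriptors: Sequence[str] = DEFAULT_CORRELATION_COLUMNS
) -> dict[str, float | None]:
    """Pearson r between the 1/0 VRA label and each descriptor column.

    With a binary variable this is the point-biserial coefficient. Constant
    columns (zero variance) are reported as ``None`` (undefined), not 0.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows for correlation")
    y = table["is_vra"].to_numpy(dtype=float)
    out: dict[str, float | None] = {}
    for col in descriptors:
        if col not in table.columns:
            continue
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[col] = None
            continue
        out[col] = float(stats.pearsonr(y, x).statistic)
    return out


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    n1: int  # >= min_groups side
    n2: int
    method: str  # "exact" | "asymptotic"


EXACT_MAX_GROUP = 8


def group_comparison(
    table: pd.DataFrame,
    min_groups: int = 3,
    value_col: str = "avg_rel_visc",
    group_col: str = "n_charge_groups",
    method: str | None = None,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U: value_col in the >= min_groups vs the rest.

    Uses exact null enumeration when both groups have <= 8 observations and
    there are no ties across groups; otherwise the tie-corrected normal
    approximation with continuity correction. ``method`` forces one path.
    """
    hi = table.loc[table[group_col] >= min_groups, value_col].to_numpy(dtype=float)
    lo = table.loc[table[group_col] < min_groups, value_col].to_numpy(dtype=float)
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both charge-group strata must be non-empty")
    if method is None:
        no_ties = len(np.unique(np.concatenate([hi, lo]))) == len(hi) + len(lo)
        method = (
            "exact"
            if len(hi) <= EXACT_MAX_GROUP and len(lo) <= EXACT_MAX_GROUP and no_ties
            else "asymptotic"
        )
    res = stats.mannwhitneyu(hi, lo, alternative="two-sided", method=method)
    return MannWhitneyResult(
        u=float(res.statistic), p=float(res.pvalue), n1=len(hi), n2=len(lo), method=method
    )


@dataclass(frozen=True)
class RuleEvaluation:
    """Confusion matrix + derived metrics for 'n_charge_groups >= k' vs is_vra."""

    k: int
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


def evaluate_rule(table: pd.DataFrame, k: int = 3) -> RuleEvaluation:
    """Score the charge-group cutoff rule against the measured VRA labels."""
    if table.empty:
        raise ValueError("empty analysis table")
    pred = (table["n_charge_groups"] >= k).to_numpy()
    label = table["is_vra"].to_numpy().astype(bool)
    return RuleEvaluation(
        k=k,
        tp=int(np.sum(pred & label)),
        fp=int(np.sum(pred & ~label)),
        tn=int(np.sum(~pred & ~label)),
        fn=int(np.sum(~pred & label)),
    )


def sweep_rule(table: pd.DataFrame, ks: Sequence[int] = (1, 2, 3, 4, 5)) -> dict[int, RuleEvaluation]:
    return {k: evaluate_rule(table, k) for k in ks}


@dataclass
class PanelSet:
    """Rendered figure panels plus the metadata the plots encode."""

    figures: dict
    threshold: float
    filter_windows: dict[str, tuple[float, float]]

    def savefig(self, outdir) -> list[str]:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, fig in self.figures.items():
            p = outdir / f"{name}.png"
            fig.savefig(p, dpi=120)
            paths.append(str(p))
        return paths


def descriptor_panels(table: pd.DataFrame, threshold: float = 0.8) -> PanelSet:
    """Scatter panels of the analysis table.

    Relative-viscosity panels (vs SlogP, charge groups, MW) draw the dashed
    VRA threshold line and shade the screening filter window; charge-group
    panels plot SlogP/HBD/PSA/PSA-SASA against the charge-group count.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    windows = {"slogp": (-2.0, 2.0), "mw": (100.0, 300.0), "n_charge_groups": (3.0, float("inf"))}
    figures: dict = {}
    for col, label in (("slogp", "SlogP"), ("n_charge_groups", "charge groups"), ("mw", "MW (Da)")):
        if col not in table.columns:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(table[col], table["avg_rel_visc"], s=18, alpha=0.8)
        ax.axhline(threshold, ls="--", color="black", lw=1)
        lo, hi = windows[col]
        xmax = max(float(table[col].max()), lo) if np.isinf(hi) else hi
        ax.axvspan(lo, xmax, color="green", alpha=0.12)
        ax.set_xlabel(label)
        ax.set_ylabel("average relative viscosity")
        fig.tight_layout()
        figures[f"rel_visc_vs_{col}"] = fig
    for col, label in (("slogp", "SlogP"), ("hbd", "H-bond donors"), ("psa", "PSA (A^2)"), ("psa_sasa", "PSA/SASA")):
        if col not in table.columns or "n_charge_groups" not in table.columns:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(table["n_charge_groups"], table[col], s=18, alpha=0.8)
        ax.set_xlabel("charge groups")
        ax.set_ylabel(label)
        fig.tight_layout()
        figures[f"{col}_vs_charge_groups"] = fig
    return PanelSet(figures=figures, threshold=threshold, filter_windows=windows)


def analysis_summary(table: pd.DataFrame, ks: Sequence[int] = (1, 2, 3, 4, 5)) -> dict:
    """JSON-ready bundle: correlations, Mann-Whitney test, rule sweep."""
    test = group_comparison(table)
    return {
        "correlations": correlate_classifier(table),
        "test": {"U": test.u, "p": test.p, "n1": test.n1, "n2": test.n2, "method": test.method},
        "rule_eval": {
            k: {
                "tp": e.tp, "fp": e.fp, "tn": e.tn, "fn": e.fn,
                "sensitivity": e.sensitivity, "specificity": e.specificity,
                "precision": e.precision, "accuracy": e.accuracy,
                "balanced_accuracy": e.balanced_accuracy,
            }
            for k, e in sweep_rule(table, ks).items()
        },
    }
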