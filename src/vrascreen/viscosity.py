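"""Concentration-viscosity baseline model, relative viscosity, VRA classifier.

The viscosity of a concentrated protein solution grows exponentially with
protein concentration, eta = a * exp(b * c). The baseline (protein in water,
no excipient) is fitted per mAb by linear least squares on ln(eta) over the
measured concentration range (120-200 mg/mL in the study design). For each
excipient measurement, the relative viscosity eta/eta0 divides the measured
viscosity by the baseline prediction at that sample's own protein
concentration. A compound is classified as a viscosity-reducing agent (VRA)
when its average relative viscosity across the model mAbs is <= 0.8 — a
threshold one experimental error (~0.1 in relative viscosity) above the
arginine benchmark range of 0.5-0.6.
"""

from __future__ import annotations

import csv
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

VRA_THRESHOLD = 0.8


class FitError(ValueError):
    """Raised when a baseline fit is requested on insufficient data."""


@dataclass(frozen=True)
class ViscosityMeasurement:
    """One viscosity reading; ``compound_id=None`` marks a baseline point."""

    mab_id: str
    compound_id: str | None
    concentration: float  # protein concentration, mg/mL
    viscosity: float  # cP
    ph: float = 6.0
    excipient_mm: float = 25.0
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if self.concentration <= 0 or self.viscosity <= 0:
            raise ValueError("concentration and viscosity must be positive")


@dataclass(frozen=True)
class BaselineFit:
    """Fitted eta = a*exp(b*c) baseline for one mAb, with the fitted c-range."""

    mab_id: str
    a: float  # cP
    b: float  # mL/mg
    n_points: int
    rms_log_residual: float
    c_min: float
    c_max: float

    def predict(self, concentration: float) -> float:
        return self.a * np.exp(self.b * concentration)


def fit_baseline(points: Sequence[ViscosityMeasurement]) -> BaselineFit:
    """Least-squares fit of ln(eta) = ln(a) + b*c on baseline points.

    Fitting in log space weights relative rather than absolute error, which
    matches the multiplicative error structure of viscometry, and makes the
    fit a deterministic linear problem.
    """
    baseline = [p for p in points if p.compound_id is None]
    mabs = {p.mab_id for p in baseline}
    if len(mabs) > 1:
        raise FitError(f"baseline points span multiple mAbs: {sorted(mabs)}")
    concs = np.array([p.concentration for p in baseline])
    if len(baseline) < 2 or len(set(concs.tolist())) < 2:
        raise FitError("need >= 2 baseline points at distinct concentrations")
    log_eta = np.log([p.viscosity for p in baseline])
    b, log_a = np.polyfit(concs, log_eta, 1)
    resid = log_eta - (log_a + b * concs)
    return BaselineFit(
        mab_id=baseline[0].mab_id,
        a=float(np.exp(log_a)),
        b=float(b),
        n_points=len(baseline),
        rms_log_residual=float(np.sqrt(np.mean(resid**2))),
        c_min=float(concs.min()),
        c_max=float(concs.max()),
    )


def relative_viscosity(m: ViscosityMeasurement, fit: BaselineFit) -> float:
    """eta/eta0 at the measurement's own protein concentration."""
    if m.mab_id != fit.mab_id:
        raise ValueError(f"measurement mAb {m.mab_id!r} does not match fit {fit.mab_id!r}")
    span = fit.c_max - fit.c_min
    if m.concentration < fit.c_min - 0.1 * span or m.concentration > fit.c_max + 0.1 * span:
        warnings.warn(
            f"concentration {m.concentration:.1f} mg/mL extrapolates >10% beyond "
            f"the fitted range [{fit.c_min:.0f}, {fit.c_max:.0f}]",
            stacklevel=2,
        )
    return m.viscosity / fit.predict(m.concentration)


@dataclass(frozen=True)
class VRARecord:
    """Per-compound relative viscosities and the binary VRA label."""

    compound_id: str
    rel_visc_per_mab: Mapping[str, float]
    avg_rel_visc: float
    is_vra: bool


def classify_vra(
    measurements: Iterable[ViscosityMeasurement],
    fits: Mapping[str, BaselineFit],
    threshold: float = VRA_THRESHOLD,
) -> list[VRARecord]:
    """Classify each measured compound: VRA iff mean eta/eta0 <= threshold.

    Replicates within one mAb are averaged first; the average over mAbs is the
    unweighted arithmetic mean. Compounds on mAbs lacking a baseline fit are
    skipped with a warning. The threshold comparison is inclusive.
    """
    per_compound: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for m in measurements:
        if m.compound_id is None:
            continue
        if m.mab_id not in fits:
            warnings.warn(f"no baseline fit for mAb {m.mab_id!r}; skipping {m.compound_id}", stacklevel=2)
            continue
        per_compound[m.compound_id][m.mab_id].append(relative_viscosity(m, fits[m.mab_id]))
    records = []
    for cid in sorted(per_compound):
        per_mab = {mab: float(np.mean(vals)) for mab, vals in sorted(per_compound[cid].items())}
        avg = float(np.mean(list(per_mab.values())))
        records.append(VRARecord(compound_id=cid, rel_visc_per_mab=per_mab, avg_rel_visc=avg, is_vra=avg <= threshold))
    return records


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_measurements_csv(path: str | Path) -> list[ViscosityMeasurement]:
    """Measurements CSV: {sample_id, mab_id, compound_id (empty = baseline),
    concentration_mg_ml, viscosity_cp, ph, excipient_mm}."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ViscosityMeasurement(
                    sample_id=row.get("sample_id") or None,
                    mab_id=row["mab_id"],
                    compound_id=row["compound_id"] or None,
                    concentration=float(row["concentration_mg_ml"]),
                    viscosity=float(row["viscosity_cp"]),
                    ph=float(row.get("ph") or 6.0),
                    excipient_mm=float(row.get("excipient_mm") or 25.0),
                )
            )
    return out


def write_measurements_csv(path: str | Path, measurements: Sequence[ViscosityMeasurement]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("sample_id", "mab_id", "compound_id", "concentration_mg_ml", "viscosity_cp", "ph", "excipient_mm"))
        for m in measurements:
            w.writerow((m.sample_id or "", m.mab_id, m.compound_id or "",
                        f"{m.concentration:.6g}", f"{m.viscosity:.6g}", m.ph, m.excipient_mm))


def write_vra_csv(path: str | Path, records: Sequence[VRARecord]) -> None:
    mabs = sorted({mab for r in records for mab in r.rel_visc_per_mab})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id"] + [f"rel_visc_{m}" for m in mabs] + ["avg_rel_visc", "is_vra"])
        for r in records:
            w.writerow([r.compound_id]
                       + [f"{r.rel_visc_per_mab[m]:.4f}" if m in r.rel_visc_per_mab else "" for m in mabs]
                       + [f"{r.avg_rel_visc:.4f}", int(r.is_vra)])


def load_tested_compounds(path: str | Path, threshold: float = VRA_THRESHOLD):
    """Load a tested-compound table (Excel or CSV) and apply the VRA rule.

    Expects an identifier column (named like "id" or "compound") and one
    relative-viscosity column per mAb (header containing "relative" or
    starting with "rel_visc"). Returns a DataFrame with per-mAb relative
    viscosities, their mean and the inclusive <= threshold VRA label.
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_excel(path) if path.suffix.lower() in (".xlsx", ".xls") else pd.read_csv(path)
    id_col = next(
        (c for c in df.columns if str(c).strip().lower() in ("id", "compound", "compound_id", "code", "identifier")),
        df.columns[0],
    )
    rv_cols = [c for c in df.columns
               if "relative" in str(c).lower() or str(c).lower().startswith("rel_visc")]
    if not rv_cols:
        raise ValueError(f"no relative-viscosity columns found in {path}")
    out = df[[id_col] + rv_cols].copy()
    out = out.rename(columns={id_col: "compound_id"})
    out["avg_rel_visc"] = out[rv_cols].astype(float).mean(axis=1)
    out["is_vra"] = out["avg_rel_visc"] <= threshold
    return out
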