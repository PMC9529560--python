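"""Synthetic study generator: compound libraries and two-mAb viscosity data.

The generator reproduces the statistical structure the analysis layer
assumes, with exact ground truth:

* **Library** — compounds are assembled from a scaffold grammar: an alkyl
  backbone decorated with 0-5 ionizable substituents (carboxylate, sulfonate,
  phosphonate, primary amine, guanidine) drawn to hit a configured
  charge-group count distribution, plus random neutral decorations (methyl,
  hydroxyl, ...) that vary MW and SlogP independently of charge. Because the
  substituents are placed on separated backbone carbons, the charge-group
  ground truth is exact by construction and recoverable by the pattern-based
  pKa annotator.
* **Effect model** — each compound is a true viscosity reducer with
  probability logistic(beta0 + beta1 * n_charge_groups); reducers draw a true
  relative viscosity around 0.6 (the arginine benchmark range) and
  non-reducers around 1.0, each with sd 0.1 (the stated experimental error
  scale).
* **Measurements** — per mAb, baseline points follow eta = a*exp(b*c) on a
  120-200 mg/mL grid with multiplicative log-normal noise (cv 5%); each
  compound gets one measurement per mAb at a protein concentration jittered
  around the 150 mg/mL target (sd 5 mg/mL, mimicking per-sample concentration
  determination). Both default mAb curves give 10-30 cP at 150 mg/mL.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import Compound, write_library
from .ionization import ChargeProfile, ChargeRule, IonizableGroup, charge_profile
from .viscosity import ViscosityMeasurement, write_measurements_csv

DEFAULT_CHARGE_DISTRIBUTION: dict[int, float] = {0: 0.05, 1: 0.10, 2: 0.20, 3: 0.30, 4: 0.20, 5: 0.15}
# (a [cP], b [mL/mg]); both give 10-30 cP at the 150 mg/mL target.
DEFAULT_MAB_PARAMS: dict[str, tuple[float, float]] = {"mabA": (0.85, 0.021), "mabB": (0.60, 0.020)}


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic data generator."""

    seed: int = 0
    n_compounds: int = 94
    charge_group_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_CHARGE_DISTRIBUTION)
    )
    effect_beta0: float = -7.0  # logistic intercept on P(true reducer)
    effect_beta1: float = 3.0  # slope per charge group
    reducer_mean: float = 0.6
    reducer_sd: float = 0.1
    nonreducer_mean: float = 1.0
    nonreducer_sd: float = 0.1
    mab_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MAB_PARAMS)
    )
    noise_cv: float = 0.05  # multiplicative measurement noise
    baseline_concentrations: Sequence[float] = (120.0, 135.0, 150.0, 165.0, 180.0, 200.0)
    target_concentration: float = 150.0  # mg/mL
    concentration_jitter_sd: float = 5.0  # mg/mL
    ph: float = 6.0
    excipient_mm: float = 25.0

    def __post_init__(self) -> None:
        probs = dict(self.charge_group_distribution)
        if not probs or abs(sum(probs.values()) - 1.0) > 1e-9 or any(p < 0 for p in probs.values()):
            raise SimConfigError("charge_group_distribution must be non-negative and sum to 1")
        if any(not 0 <= k <= 5 for k in probs):
            raise SimConfigError("charge-group counts must lie in 0..5")
        if self.noise_cv < 0:
            raise SimConfigError("noise_cv must be >= 0")
        for mab, (a, b) in self.mab_params.items():
            eta150 = a * np.exp(b * self.target_concentration)
            if not 10.0 <= eta150 <= 30.0:
                raise SimConfigError(
                    f"{mab}: baseline {eta150:.1f} cP at {self.target_concentration:.0f} mg/mL "
                    "outside the 10-30 cP design window"
                )


# Ionizable substituents: (SMILES branch, group kind, table pKa, label).
_ACID_SUBS = [
    ("C(=O)O", "acid", 4.0, "carboxylic_acid"),
    ("S(=O)(=O)O", "acid", 0.5, "sulfonic_acid"),
    ("P(=O)(O)O", "acid", 2.2, "phosphonic_acid"),  # counts one group per O-H
]
_BASE_SUBS = [
    ("N", "base", 10.5, "aliphatic_amine"),
    ("NC(=N)N", "base", 12.5, "guanidine"),
]
_NEUTRAL_SUBS = ["C", "O", "CC", "CO", "C(C)C", "CCC"]


@dataclass(frozen=True)
class SyntheticCompound:
    compound: Compound
    profile: ChargeProfile

    @property
    def n_charge_groups(self) -> int:
        return self.profile.n_charge_groups


def generate_library(cfg: SimConfig, rule: ChargeRule | None = None) -> list[SyntheticCompound]:
    """Build the synthetic compound library with exact charge ground truth."""
    rng = np.random.default_rng(cfg.seed)
    rule = rule or ChargeRule.threshold()
    counts = sorted(cfg.charge_group_distribution)
    probs = np.array([cfg.charge_group_distribution[k] for k in counts])
    out: list[SyntheticCompound] = []
    for i in range(cfg.n_compounds):
        target = int(rng.choice(counts, p=probs))
        groups: list[IonizableGroup] = []
        branches: list[str] = []
        for _ in range(target):
            # phosphonic branch carries two acidic O-H, i.e. two charge groups;
            # only use it when two more groups are still needed
            pool = _ACID_SUBS + _BASE_SUBS if rng.random() < 0.5 else _BASE_SUBS + _ACID_SUBS
            candidates = [s for s in pool if s[3] != "phosphonic_acid"]
            if target - len(groups) >= 2 and rng.random() < 0.15:
                candidates = [s for s in _ACID_SUBS if s[3] == "phosphonic_acid"]
            smi, kind, pka, label = candidates[rng.integers(len(candidates))]
            n_sites = 2 if label == "phosphonic_acid" else 1
            branches.append(smi)
            for _ in range(n_sites):
                groups.append(IonizableGroup(kind=kind, pka=pka, label=label))
            if len(groups) >= target:
                break
        while len(groups) < target:  # top up if the phosphonic draw overshot logic left a gap
            smi, kind, pka, label = _BASE_SUBS[0] if rng.random() < 0.5 else _ACID_SUBS[0]
            branches.append(smi)
            groups.append(IonizableGroup(kind=kind, pka=pka, label=label))
        for _ in range(int(rng.integers(0, 4))):
            branches.append(_NEUTRAL_SUBS[rng.integers(len(_NEUTRAL_SUBS))])
        rng.shuffle(branches)
        smiles = "C" + "".join(f"C({b})C" for b in branches)
        profile = charge_profile(groups, rule=rule, ph=cfg.ph)
        if profile.n_charge_groups != target:
            raise SimConfigError(
                f"infeasible charge target {target} under the active rule (got {profile.n_charge_groups})"
            )
        out.append(
            SyntheticCompound(
                compound=Compound(id=f"S{i + 1:03d}", smiles=smiles, source="synthetic"),
                profile=profile,
            )
        )
    return out


def generate_measurements(
    library: Sequence[SyntheticCompound], cfg: SimConfig
) -> tuple[list[ViscosityMeasurement], pd.DataFrame]:
    """Baseline + per-compound measurements and the ground-truth table.

    Returns (measurements, truth) where truth has one row per compound:
    n_charge_groups, is_reducer (the planted label) and the per-mAb true
    relative-viscosity ratios before measurement noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    sigma = float(np.sqrt(np.log1p(cfg.noise_cv**2)))  # log-normal sd for the given cv

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0

    measurements: list[ViscosityMeasurement] = []
    for mab, (a, b) in cfg.mab_params.items():
        for c in cfg.baseline_concentrations:
            eta = a * np.exp(b * c) * noise()
            measurements.append(
                ViscosityMeasurement(
                    mab_id=mab, compound_id=None, concentration=float(c), viscosity=eta,
                    ph=cfg.ph, excipient_mm=0.0, sample_id=f"{mab}_baseline_{c:.0f}",
                )
            )

    truth_rows = []
    for sc in library:
        n_cg = sc.n_charge_groups
        p_reduce = 1.0 / (1.0 + np.exp(-(cfg.effect_beta0 + cfg.effect_beta1 * n_cg)))
        is_reducer = bool(rng.random() < p_reduce)
        row = {"compound_id": sc.compound.id, "n_charge_groups": n_cg, "is_reducer": is_reducer}
        for mab, (a, b) in cfg.mab_params.items():
            mean, sd = (
                (cfg.reducer_mean, cfg.reducer_sd) if is_reducer else (cfg.nonreducer_mean, cfg.nonreducer_sd)
            )
            ratio = max(float(rng.normal(mean, sd)), 0.05)
            conc = float(rng.normal(cfg.target_concentration, cfg.concentration_jitter_sd))
            conc = min(max(conc, 1.0), 1000.0)
            eta = ratio * a * np.exp(b * conc) * noise()
            measurements.append(
                ViscosityMeasurement(
                    mab_id=mab, compound_id=sc.compound.id, concentration=conc, viscosity=eta,
                    ph=cfg.ph, excipient_mm=cfg.excipient_mm, sample_id=f"{mab}_{sc.compound.id}",
                )
            )
            row[f"true_ratio_{mab}"] = ratio
        truth_rows.append(row)
    return measurements, pd.DataFrame(truth_rows)


def run_synthetic_study(cfg: SimConfig, with_descriptors: bool = True) -> pd.DataFrame:
    """Generate a study and push it through the full analysis path.

    Returns the per-compound analysis table (VRA label, charge profile and —
    optionally — the descriptor panel), ready for the correlation and
    group-comparison layer.
    """
    from .viscosity import classify_vra, fit_baseline
    from .vstats import build_analysis_table

    library = generate_library(cfg)
    measurements, _ = generate_measurements(library, cfg)
    fits = {
        mab: fit_baseline([m for m in measurements if m.mab_id == mab]) for mab in cfg.mab_params
    }
    records = classify_vra(measurements, fits)
    return build_analysis_table(
        records,
        {sc.compound.id: sc.compound for sc in library} if with_descriptors else None,
        {sc.compound.id: sc.profile for sc in library},
    )


@dataclass(frozen=True)
class FixturePaths:
    library_smi: Path
    measurements_csv: Path
    truth_csv: Path
    config_json: Path


def end_to_end_fixture(cfg: SimConfig, outdir: str | Path) -> FixturePaths:
    """Write library.smi, measurements.csv, truth.csv and the config echo."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library = generate_library(cfg)
    measurements, truth = generate_measurements(library, cfg)
    paths = FixturePaths(
        library_smi=outdir / "library.smi",
        measurements_csv=outdir / "measurements.csv",
        truth_csv=outdir / "truth.csv",
        config_json=outdir / "sim_config.json",
    )
    write_library(paths.library_smi, [sc.compound for sc in library])
    write_measurements_csv(paths.measurements_csv, measurements)
    truth.to_csv(paths.truth_csv, index=False)
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict["charge_group_distribution"] = {str(k): v for k, v in cfg.charge_group_distribution.items()}
    cfg_dict["mab_params"] = {k: list(v) for k, v in cfg.mab_params.items()}
    cfg_dict["baseline_concentrations"] = list(cfg.baseline_concentrations)
    paths.config_json.write_text(json.dumps(cfg_dict, indent=2))
    return paths
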