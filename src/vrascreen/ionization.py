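"""Ionizable-group assignment and charge-group/charge-state calculus.

Ionizable groups are found by a transparent SMARTS pattern table mapping the
common acidic and basic functional groups to literature mean micro-pKa values;
a per-compound override table can replace any assigned pKa. Two charge-group
counting rules are exposed:

* threshold mode (the screening rule): an acid is a negative charge group iff
  its pKa < 6.4; a base is a positive charge group iff its pKa > 8.4. These
  cutoffs bracket the formulation pH window so that a counted group is
  essentially fully charged there.
* window mode: a group counts iff its Henderson-Hasselbalch charged fraction
  at the target pH reaches ``min_charged_fraction`` (default 10%). This is the
  rule under which histidine's imidazole (pKa ~= 6.0, 50% protonated at
  pH 6.0) counts as a charge group.

Net and absolute charge at a pH are expectations under the independent-groups
(non-interacting sites) model; the major-species charge rounds each group to
its most populated protonation state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from .chem import Compound, StructureError

__all__ = [
    "IonizableGroup",
    "ChargeRule",
    "ChargeProfile",
    "assign_pkas",
    "count_charge_groups",
    "charge_at_ph",
    "charged_fraction",
    "charge_profile",
    "load_pka_overrides",
]


@dataclass(frozen=True)
class IonizableGroup:
    """One ionizable site: acid (0/-1) or base (+1/0) with its pKa."""

    kind: str  # "acid" | "base"
    pka: float
    label: str
    position: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base"):
            raise ValueError(f"kind must be acid|base, got {self.kind!r}")


# Pattern table: (label, kind, SMARTS, pKa). Order encodes priority — earlier,
# more specific patterns claim their atoms so that e.g. a guanidine nitrogen is
# never re-counted as an aliphatic amine. pKa values are literature means for
# the isolated functional group.
_PATTERN_TABLE: list[tuple[str, str, str, float]] = [
    # one match per acidic O-H so polyprotic phosphonates/sulfonates count each
    ("sulfonic_acid", "acid", "[OX2H;$([OX2H][SX4](=O)=O)]", 0.5),
    ("phosphonic_acid", "acid", "[OX2H;$([OX2H][PX4]=O)]", 2.2),
    ("tetrazole", "acid", "[nH]1nnnc1", 4.9),
    ("carboxylic_acid", "acid", "[CX3](=O)[OX2H1]", 4.0),
    ("thiol", "acid", "[SX2H]", 8.3),
    ("phenol", "acid", "[OX2H][c]", 10.0),
    ("guanidine", "base", "[NX3][CX3](=[NX2])[NX3]", 12.5),
    ("amidine", "base", "[NX3][CX3]=[NX2]", 11.5),
    ("imidazole", "base", "c1c[nH]cn1", 6.0),
    ("aniline", "base", "[NX3;H1,H2;!$(NC=O)][c]", 4.6),
    ("aliphatic_amine", "base", "[NX3;H0,H1,H2;!$(NC=[O,S,N]);!$(N[c,n]);!$(N=*);!$(N[S,P]=O)]", 10.5),
    ("pyridine", "base", "[nX2H0;$(n1ccccc1)]", 5.2),
]

_COMPILED = [(label, kind, Chem.MolFromSmarts(sm), pka) for label, kind, sm, pka in _PATTERN_TABLE]
assert all(p is not None for _, _, p, _ in _COMPILED)


def assign_pkas(
    c: Compound,
    overrides: Mapping[tuple[str, str], float] | None = None,
) -> list[IonizableGroup]:
    """Match the functional-group table against a compound.

    Each pattern match claims its atoms; later (lower-priority) patterns skip
    matches that touch claimed atoms. ``overrides`` maps (compound_id,
    group_label) to a replacement pKa, taking precedence over the table value;
    labels may carry a 1-based occurrence suffix (e.g. "carboxylic_acid_2") to
    address repeated groups. Groups are returned in atom-index order.
    """
    mol = c.mol()
    claimed: set[int] = set()
    groups: list[IonizableGroup] = []
    for label, kind, patt, pka in _COMPILED:
        for match in mol.GetSubstructMatches(patt):
            atoms = set(match)
            if atoms & claimed:
                continue
            claimed |= atoms
            groups.append(IonizableGroup(kind=kind, pka=pka, label=label, position=frozenset(atoms)))
    groups.sort(key=lambda g: min(g.position))
    if overrides:
        seen: dict[str, int] = {}
        out = []
        for g in groups:
            seen[g.label] = seen.get(g.label, 0) + 1
            for key in ((c.id, f"{g.label}_{seen[g.label]}"), (c.id, g.label)):
                if key in overrides:
                    g = IonizableGroup(kind=g.kind, pka=overrides[key], label=g.label, position=g.position)
                    break
            out.append(g)
        groups = out
    return groups


def load_pka_overrides(path: str | Path) -> dict[tuple[str, str], float]:
    """Read an override CSV with columns {compound_id, group_label, kind, pka}."""
    out: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[(row["compound_id"], row["group_label"])] = float(row["pka"])
    return out


@dataclass(frozen=True)
class ChargeRule:
    """Charge-group counting rule; exactly one of the two modes is active."""

    mode: str = "threshold"  # "threshold" | "window"
    acid_pka_max: float = 6.4
    base_pka_min: float = 8.4
    ph: float = 6.0
    min_charged_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "window"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.acid_pka_max <= 14.0 and 0.0 <= self.base_pka_min <= 14.0):
            raise ValueError("pKa thresholds must lie in [0, 14]")

    @staticmethod
    def threshold(acid_pka_max: float = 6.4, base_pka_min: float = 8.4) -> "ChargeRule":
        return ChargeRule(mode="threshold", acid_pka_max=acid_pka_max, base_pka_min=base_pka_min)

    @staticmethod
    def window(ph: float = 6.0, min_charged_fraction: float = 0.10) -> "ChargeRule":
        return ChargeRule(mode="window", ph=ph, min_charged_fraction=min_charged_fraction)


def charged_fraction(group: IonizableGroup, ph: float) -> float:
    """Henderson-Hasselbalch charged fraction of one group at a pH."""
    if group.kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (group.pka - ph))
    return 1.0 / (1.0 + 10.0 ** (ph - group.pka))


def count_charge_groups(groups: Iterable[IonizableGroup], rule: ChargeRule) -> tuple[int, int]:
    """(n_pos, n_neg) charge-group counts under the active rule."""
    n_pos = n_neg = 0
    for g in groups:
        if rule.mode == "threshold":
            counts = (g.pka < rule.acid_pka_max) if g.kind == "acid" else (g.pka > rule.base_pka_min)
        else:
            counts = charged_fraction(g, rule.ph) >= rule.min_charged_fraction
        if counts:
            if g.kind == "base":
                n_pos += 1
            else:
                n_neg += 1
    return n_pos, n_neg


def charge_at_ph(groups: Iterable[IonizableGroup], ph: float) -> tuple[float, float, int]:
    """(net_charge, abs_charge, major_species_charge) at a pH.

    Net charge is the expectation of the signed total charge, absolute charge
    the sum of per-group charged fractions, and the major-species charge sums
    per-group rounded states (fraction > 0.5 charged; ties round uncharged).
    """
    if not 0.0 <= ph <= 14.0:
        raise ValueError(f"pH {ph} outside [0, 14]")
    net = absq = 0.0
    major = 0
    for g in groups:
        frac = charged_fraction(g, ph)
        sign = 1 if g.kind == "base" else -1
        net += sign * frac
        absq += frac
        if frac > 0.5:
            major += sign
    return net, absq, major


@dataclass(frozen=True)
class ChargeProfile:
    """Full charge annotation of one compound at a pH under a counting rule."""

    groups: tuple[IonizableGroup, ...]
    n_pos: int
    n_neg: int
    net_charge: float
    abs_charge: float
    major_species_charge: int
    rule: ChargeRule
    ph: float

    @property
    def n_charge_groups(self) -> int:
        return self.n_pos + self.n_neg


def charge_profile(
    groups: Sequence[IonizableGroup], rule: ChargeRule | None = None, ph: float = 6.0
) -> ChargeProfile:
    """Convenience constructor combining counting and charge expectation."""
    rule = rule or ChargeRule.threshold()
    n_pos, n_neg = count_charge_groups(groups, rule)
    net, absq, major = charge_at_ph(groups, ph)
    return ChargeProfile(
        groups=tuple(groups), n_pos=n_pos, n_neg=n_neg,
        net_charge=net, abs_charge=absq, major_species_charge=major, rule=rule, ph=ph,
    )


def write_charge_report_csv(path: str | Path, rows: Sequence[tuple[str, ChargeProfile]]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ("id", "n_pos", "n_neg", "n_charge_groups", "net_charge", "abs_charge",
             "major_species_charge", "rule", "ph")
        )
        for cid, p in rows:
            w.writerow((cid, p.n_pos, p.n_neg, p.n_charge_groups,
                        f"{p.net_charge:.4f}", f"{p.abs_charge:.4f}",
                        p.major_species_charge, p.rule.mode, p.ph))
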