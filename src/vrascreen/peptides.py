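"""Amino-acid data, dipeptide enumeration and the dual-excipient filter.

The 20 canonical proteinogenic amino acids ship as a CSV table (one row per
ionizable group: backbone carboxyl, backbone amine, ionizable side chains)
with reference free-amino-acid pKa values. Dipeptides are enumerated as all
ordered pairs (sequence direction matters, so 20 amino acids give 400
dipeptides), built by textual peptide-bond condensation of the SMILES
templates with loss of one water.

Dipeptide ionization uses the independent-groups model with backbone shifts:
the free C-terminal carboxyl is assigned pKa 3.1 and the free N-terminal
amine pKa 8.2 (typical peptide backbone values), while side-chain groups
inherit their free-amino-acid pKas. The dual-excipient filter keeps
dipeptides that can buffer near the formulation pH (at least one pKa in
[5, 7]) and still carry at least three charge groups.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .chem import Compound
from .ionization import ChargeRule, IonizableGroup, count_charge_groups

N_TERMINAL_AMINE_PKA = 8.2
C_TERMINAL_CARBOXYL_PKA = 3.1


@dataclass(frozen=True)
class AminoAcid:
    """One canonical amino acid with its ionizable groups."""

    code: str
    name: str
    smiles: str
    backbone_carboxyl_pka: float
    backbone_amine_pka: float
    side_chain_groups: tuple[IonizableGroup, ...] = ()

    def ionizable_groups(self) -> list[IonizableGroup]:
        """Groups of the free amino acid (backbone + side chain)."""
        return [
            IonizableGroup(kind="acid", pka=self.backbone_carboxyl_pka, label="backbone_carboxyl"),
            IonizableGroup(kind="base", pka=self.backbone_amine_pka, label="backbone_amine"),
            *self.side_chain_groups,
        ]

    def compound(self) -> Compound:
        return Compound(id=self.code, smiles=self.smiles, name=self.name, source="literature")


def load_amino_acids(path: str | Path | None = None) -> list[AminoAcid]:
    """Load the packaged amino-acid table (or a user table in the same layout)."""
    if path is None:
        text = resources.files("vrascreen.data").joinpath("amino_acids.csv").read_text()
    else:
        text = Path(path).read_text()
    rows = list(csv.DictReader(text.splitlines()))
    by_code: dict[str, dict] = {}
    for row in rows:
        entry = by_code.setdefault(
            row["code"], {"name": row["name"], "smiles": row["smiles"], "groups": {}}
        )
        entry["groups"][row["group_label"]] = (row["kind"], float(row["pka"]))
    out = []
    for code, entry in by_code.items():
        groups = entry["groups"]
        side = tuple(
            IonizableGroup(kind=kind, pka=pka, label=label)
            for label, (kind, pka) in groups.items()
            if not label.startswith("backbone_")
        )
        out.append(
            AminoAcid(
                code=code,
                name=entry["name"],
                smiles=entry["smiles"],
                backbone_carboxyl_pka=groups["backbone_carboxyl"][1],
                backbone_amine_pka=groups["backbone_amine"][1],
                side_chain_groups=side,
            )
        )
    return out


@dataclass(frozen=True)
class Dipeptide:
    """A two-residue peptide (seq written N->C) with merged ionizable groups."""

    seq: str
    compound: Compound
    pkas: tuple[IonizableGroup, ...]

    def ionizable_groups(self) -> list[IonizableGroup]:
        return list(self.pkas)


def _condense(n_res: AminoAcid, c_res: AminoAcid) -> str:
    """Peptide-bond condensation by SMILES template concatenation.

    Every amino-acid SMILES in the table ends with the free alpha-carboxyl
    written exactly as "C(=O)O"; stripping the final hydroxyl oxygen leaves an
    open acyl carbon that bonds to the leading backbone nitrogen of the next
    residue, losing one water.
    """
    if not n_res.smiles.endswith("C(=O)O"):
        raise ValueError(f"{n_res.code}: SMILES template must end with C(=O)O")
    return n_res.smiles[:-1] + c_res.smiles


def enumerate_dipeptides(
    aas: Sequence[AminoAcid],
    *,
    n_terminal_amine_pka: float = N_TERMINAL_AMINE_PKA,
    c_terminal_carboxyl_pka: float = C_TERMINAL_CARBOXYL_PKA,
) -> list[Dipeptide]:
    """All |aas|^2 ordered dipeptides (AB and BA are distinct compounds)."""
    codes = [a.code for a in aas]
    if len(set(codes)) != len(codes):
        raise ValueError("duplicate amino-acid codes")
    out = []
    for a in aas:
        for b in aas:
            seq = a.code + b.code
            smiles = _condense(a, b)
            groups = (
                IonizableGroup(kind="base", pka=n_terminal_amine_pka, label="n_terminal_amine"),
                IonizableGroup(kind="acid", pka=c_terminal_carboxyl_pka, label="c_terminal_carboxyl"),
                *(
                    IonizableGroup(kind=g.kind, pka=g.pka, label=f"{pos}_{g.label}")
                    for pos, res in (("res1", a), ("res2", b))
                    for g in res.side_chain_groups
                ),
            )
            out.append(
                Dipeptide(
                    seq=seq,
                    compound=Compound(id=f"dip_{seq}", smiles=smiles, name=f"{a.name}-{b.name}", source="dipeptide"),
                    pkas=groups,
                )
            )
    return out


def buffering_filter(
    dps: Sequence[Dipeptide], pka_low: float = 5.0, pka_high: float = 7.0
) -> list[Dipeptide]:
    """Keep dipeptides with at least one pKa in [pka_low, pka_high] (inclusive),
    i.e. those with buffering capacity near the target pH."""
    if not pka_low < pka_high:
        raise ValueError("pka_low must be < pka_high")
    return [d for d in dps if any(pka_low <= g.pka <= pka_high for g in d.pkas)]


@dataclass(frozen=True)
class DualExcipientCandidate:
    dipeptide: Dipeptide
    n_pos: int
    n_neg: int

    @property
    def n_charge_groups(self) -> int:
        return self.n_pos + self.n_neg


def dual_excipient_candidates(
    dps: Sequence[Dipeptide],
    rule: ChargeRule | None = None,
    min_groups: int = 3,
    *,
    pka_low: float = 5.0,
    pka_high: float = 7.0,
) -> list[DualExcipientCandidate]:
    """Buffering filter followed by the charge-group count requirement.

    Returns the surviving dipeptides with their (n_pos, n_neg) counts under
    the active rule (window mode at pH 6.0 by default, so a pKa-6 imidazole
    counts as a charge group).
    """
    if min_groups < 0:
        raise ValueError("min_groups must be >= 0")
    rule = rule or ChargeRule.window(ph=6.0)
    out = []
    for d in buffering_filter(dps, pka_low, pka_high):
        n_pos, n_neg = count_charge_groups(d.pkas, rule)
        if n_pos + n_neg >= min_groups:
            out.append(DualExcipientCandidate(dipeptide=d, n_pos=n_pos, n_neg=n_neg))
    return out


def write_dipeptide_smi(path: str | Path, dps: Sequence[Dipeptide]) -> None:
    with open(path, "w") as fh:
        for d in dps:
            fh.write(f"{d.compound.smiles} {d.compound.id}\n")
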