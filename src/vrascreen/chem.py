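"""Compound representation, structure I/O and the molecular descriptor set.

Compounds are carried as SMILES plus a provenance tag; descriptors are the
conventional small-molecule panel used by physicochemical excipient filters:
molecular weight, SlogP (atom-contribution logP of the neutral species),
H-bond donor/acceptor counts, rotatable bonds, ring count, fraction of sp3
carbons, topological polar surface area, and an atomic-contribution
approximate solvent-accessible surface area (Labute ASA) so that no 3D
conformer is ever required.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, MolSurf, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger("vrascreen")

SOURCES = ("literature", "similarity_hit", "chemspace", "safe_library", "dipeptide", "synthetic")


class StructureError(ValueError):
    """Raised when a structure string cannot be parsed to a molecule."""


class EmptyLibraryError(ValueError):
    """Raised when a library file yields zero valid records."""


@dataclass(frozen=True)
class Compound:
    """A single library member: identifier + SMILES + provenance."""

    id: str
    smiles: str
    name: str | None = None
    source: str = "synthetic"

    def mol(self) -> Chem.Mol:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            raise StructureError(f"unparsable structure for {self.id!r}: {self.smiles!r}")
        return mol

    def canonical_smiles(self) -> str:
        return Chem.MolToSmiles(self.mol())


@dataclass(frozen=True)
class DescriptorSet:
    """Descriptor panel for one compound (units noted per field)."""

    mw: float  # Da, average atomic masses
    slogp: float  # unitless, neutral species
    hbd: int
    hba: int
    rot_bonds: int
    rings: int
    frac_csp3: float  # 0..1
    psa: float  # topological PSA, A^2
    sasa: float  # Labute approximate surface area, A^2
    psa_sasa: float  # psa / sasa, 0..1

    FIELDS = ("mw", "slogp", "hbd", "hba", "rot_bonds", "rings", "frac_csp3", "psa", "sasa", "psa_sasa")


def _neutralize(mol: Chem.Mol) -> Chem.Mol:
    """Return the uncharged parent species (protonation-state normalised)."""
    from rdkit.Chem.MolStandardize import rdMolStandardize

    uncharger = rdMolStandardize.Uncharger()
    return uncharger.uncharge(Chem.Mol(mol))


def compute_descriptors(c: Compound) -> DescriptorSet:
    """Compute the full descriptor panel for one compound.

    SlogP is evaluated on the neutral (uncharged) form of the molecule; PSA is
    the topological polar surface area; SASA is the Labute atomic-contribution
    approximate surface area, so no conformer generation is involved. Because
    PSA and SASA come from two different surface approximations, their ratio
    can marginally exceed 1 for densely polar molecules; it is clipped to
    [0, 1], where it acts as a bounded polarity fraction.
    """
    mol = c.mol()
    neutral = _neutralize(mol)
    psa = rdMolDescriptors.CalcTPSA(mol)
    sasa = MolSurf.LabuteASA(mol)
    return DescriptorSet(
        mw=Descriptors.MolWt(mol),
        slogp=Crippen.MolLogP(neutral),
        hbd=Lipinski.NumHDonors(mol),
        hba=Lipinski.NumHAcceptors(mol),
        rot_bonds=Lipinski.NumRotatableBonds(mol),
        rings=rdMolDescriptors.CalcNumRings(mol),
        frac_csp3=rdMolDescriptors.CalcFractionCSP3(mol),
        psa=psa,
        sasa=sasa,
        psa_sasa=min(psa / sasa, 1.0) if sasa > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def _parse_smi_lines(lines: Iterable[str]) -> Iterable[tuple[str, str, str | None]]:
    """Yield (smiles, id, name) triples from .smi text; '#' starts a comment."""
    for i, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        smiles = parts[0]
        cid = parts[1] if len(parts) > 1 else f"mol_{i}"
        name = " ".join(parts[2:]) or None
        yield smiles, cid, name


def read_library(
    path: str | Path,
    format: str | None = None,
    *,
    source: str = "literature",
    dedupe: bool = False,
) -> list[Compound]:
    """Read a compound library from .smi, .sdf or .csv.

    Invalid records are logged and skipped; the skip count is reported at INFO
    level. With ``dedupe=True`` later records whose canonical SMILES repeats an
    earlier one are dropped (stereo-aware canonical-structure equality).

    Raises ``EmptyLibraryError`` if no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".smi": "smi", ".sdf": "sdf", ".csv": "csv"}.get(path.suffix.lower(), "smi")
    if format not in ("smi", "sdf", "csv"):
        raise ValueError(f"unsupported format: {format!r}")

    records: list[tuple[str, str, str | None]] = []
    n_bad = 0
    if format == "smi":
        records = list(_parse_smi_lines(path.read_text().splitlines()))
    elif format == "csv":
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append((row["smiles"], row["id"], row.get("name") or None))
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        out: list[Compound] = []
        seen: set[str] = set()
        for i, mol in enumerate(supplier):
            if mol is None:
                n_bad += 1
                continue
            cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i + 1}"
            can = Chem.MolToSmiles(mol)
            if dedupe and can in seen:
                continue
            seen.add(can)
            out.append(Compound(id=cid, smiles=can, source=source))
        if n_bad:
            logger.info("read_library: skipped %d invalid records in %s", n_bad, path)
        if not out:
            raise EmptyLibraryError(f"no valid records in {path}")
        return out

    out = []
    seen = set()
    for smiles, cid, name in records:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None or mol.GetNumHeavyAtoms() == 0:
            n_bad += 1
            logger.debug("read_library: skipping invalid record %r", smiles)
            continue
        can = Chem.MolToSmiles(mol)
        if dedupe and can in seen:
            continue
        seen.add(can)
        out.append(Compound(id=cid, smiles=smiles, name=name, source=source))
    if n_bad:
        logger.info("read_library: skipped %d invalid records in %s", n_bad, path)
    if not out:
        raise EmptyLibraryError(f"no valid records in {path}")
    return out


def write_library(path: str | Path, compounds: Sequence[Compound]) -> None:
    """Write compounds as a .smi file (SMILES, id, optional name)."""
    with open(path, "w") as fh:
        for c in compounds:
            fields = [c.smiles, c.id] + ([c.name] if c.name else [])
            fh.write(" ".join(fields) + "\n")


def write_descriptor_csv(path: str | Path, compounds: Sequence[Compound]) -> None:
    """Descriptor table CSV: one row per compound, fixed column order."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("id",) + DescriptorSet.FIELDS)
        for c in compounds:
            d = compute_descriptors(c)
            writer.writerow([c.id] + [getattr(d, f) for f in DescriptorSet.FIELDS])
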