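"""Path-based 1024-bit fragment fingerprint, Tanimoto search and clustering.

The fingerprint enumerates all linear fragments of 1-7 atoms in a molecule
(single-atom C/N/O fragments ignored; a path that would close a ring stops
there and records the closure), collapses chemically identical fragments to a
canonical form, hashes each canonical fragment to an integer in [0, 1020] and
sets that bit in a 1024-bit vector. Similarity between two fingerprints is the
Tanimoto index T = c/(a+b-c) over set bits, and the search index uses the
popcount bound T <= min(a,b)/max(a,b) to prune candidate pairs without ever
changing the result of an exhaustive scan.

Fragment alphabet: an atom is encoded as (atomic number, aromatic flag), a
bond as its order 1/2/3 or 4 for aromatic. The canonical form of a fragment is
the lexicographically smaller of its forward and reversed encodings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from rdkit import Chem

from .chem import Compound

N_BITS = 1024
HASH_MOD = 1021  # largest prime <= 1023; bits 1021-1023 are never set
MAX_PATH_ATOMS = 7
_SINGLE_ATOM_IGNORED = {6, 7, 8}  # C, N, O


@dataclass(frozen=True)
class Fragment:
    """A canonical linear fragment: atom codes, bond codes, ring-closure flag."""

    atoms: tuple[tuple[int, bool], ...]
    bonds: tuple[int, ...]
    ring_closure: bool = False

    def __post_init__(self) -> None:
        if not 1 <= len(self.atoms) <= MAX_PATH_ATOMS:
            raise ValueError("fragment must have 1-7 atoms")
        if len(self.bonds) != len(self.atoms) - 1:
            raise ValueError("bond count must be atom count - 1")

    @staticmethod
    def canonical(
        atoms: Sequence[tuple[int, bool]], bonds: Sequence[int], ring_closure: bool = False
    ) -> "Fragment":
        fwd = (tuple(atoms), tuple(bonds))
        rev = (tuple(reversed(atoms)), tuple(reversed(bonds)))
        a, b = min(fwd, rev)
        return Fragment(atoms=a, bonds=b, ring_closure=ring_closure)

    def code(self) -> tuple[int, ...]:
        """Flat integer encoding used by the hash."""
        out: list[int] = [1 if self.ring_closure else 0]
        for z, arom in self.atoms:
            out.extend((z, 1 if arom else 0))
        for order in self.bonds:
            out.append(100 + order)
        return tuple(out)


_BOND_CODE = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: 4,
}


def _bond_order(bond: Chem.Bond) -> int:
    if bond.GetIsAromatic():
        return 4
    return _BOND_CODE.get(bond.GetBondType(), 1)


def enumerate_fragments(c: Compound | Chem.Mol) -> set[Fragment]:
    """Enumerate all canonical linear fragments of 1-7 atoms.

    Every simple path is walked by depth-first search from every atom; a step
    onto an atom already on the path ends the fragment with its ring-closure
    flag set. Single-atom fragments whose element is C, N or O are dropped.
    Forward and reverse traversals of one fragment collapse to a single
    canonical entry, so the result is a set.
    """
    mol = c.mol() if isinstance(c, Compound) else c
    atom_code = [(a.GetAtomicNum(), a.GetIsAromatic()) for a in mol.GetAtoms()]
    nbrs: list[list[tuple[int, int]]] = [[] for _ in range(mol.GetNumAtoms())]
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        order = _bond_order(bond)
        nbrs[i].append((j, order))
        nbrs[j].append((i, order))

    frags: set[Fragment] = set()

    def emit(path: list[int], bonds: list[int], closure: bool) -> None:
        atoms = [atom_code[i] for i in path]
        if len(atoms) == 1 and atoms[0][0] in _SINGLE_ATOM_IGNORED:
            return
        frags.add(Fragment.canonical(atoms, bonds, ring_closure=closure))

    def walk(path: list[int], bonds: list[int], on_path: set[int]) -> None:
        emit(path, bonds, closure=False)
        last = path[-1]
        for nxt, order in nbrs[last]:
            if nxt in on_path:
                # ring closure: stop and record the flagged fragment
                if len(path) >= 2 and nxt != path[-2]:
                    emit(path, bonds, closure=True)
                continue
            if len(path) == MAX_PATH_ATOMS:
                continue
            path.append(nxt)
            bonds.append(order)
            on_path.add(nxt)
            walk(path, bonds, on_path)
            on_path.discard(nxt)
            bonds.pop()
            path.pop()

    for start in range(mol.GetNumAtoms()):
        walk([start], [], {start})
    return frags


def hash_fragment(f: Fragment) -> int:
    """Deterministic polynomial rolling hash of the canonical code, in [0, 1020]."""
    h = 0
    for x in f.code():
        h = (h * 131 + x) % HASH_MOD
    return h


@dataclass(frozen=True)
class Fingerprint:
    """1024-bit fingerprint held as a Python integer bit field."""

    bits: int
    n_set: int

    @staticmethod
    def from_bits(bits: int) -> "Fingerprint":
        return Fingerprint(bits=bits, n_set=bits.bit_count())

    @staticmethod
    def from_on_bits(on_bits: Sequence[int]) -> "Fingerprint":
        bits = 0
        for b in on_bits:
            if not 0 <= b < N_BITS:
                raise ValueError(f"bit {b} out of range")
            bits |= 1 << b
        return Fingerprint.from_bits(bits)

    def on_bits(self) -> list[int]:
        return [i for i in range(N_BITS) if self.bits >> i & 1]

    def to_hex(self) -> str:
        return format(self.bits, "0256x")

    @staticmethod
    def from_hex(s: str) -> "Fingerprint":
        return Fingerprint.from_bits(int(s, 16))

    def to_array(self) -> np.ndarray:
        return np.array([(self.bits >> i) & 1 for i in range(N_BITS)], dtype=np.float64)


def fingerprint(c: Compound | Chem.Mol) -> Fingerprint:
    """Fingerprint a molecule: one bit per canonical fragment hash."""
    bits = 0
    for frag in enumerate_fragments(c):
        bits |= 1 << hash_fragment(frag)
    return Fingerprint.from_bits(bits)


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """Tanimoto index c/(a+b-c); two all-zero fingerprints compare as 1.0."""
    if fa.n_set == 0 and fb.n_set == 0:
        return 1.0
    c = (fa.bits & fb.bits).bit_count()
    denom = fa.n_set + fb.n_set - c
    return c / denom if denom else 0.0


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    hit_id: str
    tanimoto: float


class FingerprintIndex:
    """Popcount-bucketed search index over a fingerprint library.

    For a query with a set bits and threshold t, only library entries with
    popcount b in [ceil(a*t), floor(a/t)] can reach T >= t, since
    T <= min(a,b)/max(a,b). Pruning never changes the hit set relative to an
    exhaustive scan.
    """

    def __init__(self, compounds: Sequence[Compound]):
        self._entries = [(c.id, fingerprint(c)) for c in compounds]
        self._entries.sort(key=lambda e: e[1].n_set)
        self._popcounts = [e[1].n_set for e in self._entries]

    def search(self, query_id: str, qfp: Fingerprint, threshold: float, strict: bool = False) -> list[SimilarityHit]:
        import bisect

        a = qfp.n_set
        if a == 0 or threshold <= 0.0:
            lo, hi = 0, len(self._entries)
        else:
            lo = bisect.bisect_left(self._popcounts, math.ceil(a * threshold))
            hi = bisect.bisect_right(self._popcounts, math.floor(a / threshold))
        hits = []
        for hit_id, fp in self._entries[lo:hi]:
            t = tanimoto(qfp, fp)
            if (t > threshold) if strict else (t >= threshold):
                hits.append(SimilarityHit(query_id=query_id, hit_id=hit_id, tanimoto=t))
        return hits


def similarity_search(
    queries: Sequence[Compound],
    library: Sequence[Compound],
    threshold: float = 0.7,
    *,
    strict: bool = False,
    index: FingerprintIndex | None = None,
) -> list[SimilarityHit]:
    """All (query, library) pairs at or above the Tanimoto threshold.

    Non-strict (>=) comparison by default; ``strict=True`` switches to >.
    """
    if not queries:
        raise ValueError("empty query set")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if index is None:
        index = FingerprintIndex(library)
    hits: list[SimilarityHit] = []
    for q in queries:
        hits.extend(index.search(q.id, fingerprint(q), threshold, strict=strict))
    return hits


def write_hits_csv(path, hits: Sequence[SimilarityHit]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("query_id", "hit_id", "tanimoto"))
        for h in hits:
            w.writerow((h.query_id, h.hit_id, f"{h.tanimoto:.4f}"))


def write_fingerprint_csv(path, compounds: Sequence[Compound]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(("id", "fp_hex"))
        for c in compounds:
            w.writerow((c.id, fingerprint(c).to_hex()))


def cluster_and_pick(
    library: Sequence[Compound], k: int, per_cluster: int = 2, seed: int = 0
) -> list[Compound]:
    """k-means on fingerprint bit vectors; up to ``per_cluster`` picks nearest
    each centroid, ties broken by lowest library index."""
    from sklearn.cluster import KMeans

    if not 1 <= k <= len(library):
        raise ValueError(f"k={k} outside [1, {len(library)}]")
    X = np.stack([fingerprint(c).to_array() for c in library])
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, max_iter=100, random_state=seed)
    labels = km.fit_predict(X)
    dists = km.transform(X)
    picks: list[Compound] = []
    for cl in range(k):
        members = [i for i in range(len(library)) if labels[i] == cl]
        members.sort(key=lambda i: (dists[i, cl], i))
        picks.extend(library[i] for i in members[:per_cluster])
    return picks
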