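"""Fingerprint, Tanimoto and search-index behaviour, with brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem

from vrascreen.chem import Compound
from vrascreen.pathfp import (
    Fingerprint,
    Fragment,
    HASH_MOD,
    cluster_and_pick,
    enumerate_fragments,
    fingerprint,
    hash_fragment,
    similarity_search,
    tanimoto,
)
from vrascreen.simulate import SimConfig, generate_library


# ---------------------------------------------------------------------------
# Fragment enumeration
# ---------------------------------------------------------------------------

def test_single_atom_cno_fragments_ignored():
    for smi in ("C", "N", "O"):
        assert enumerate_fragments(Compound("x", smi)) == set()


def test_butane_has_three_unique_fragments():
    frags = enumerate_fragments(Compound("x", "CCCC"))
    assert len(frags) == 3  # C-C, C-C-C, C-C-C-C collapse over symmetric paths
    assert {len(f.atoms) for f in frags} == {2, 3, 4}


def test_fluoromethane_keeps_single_atom_fluorine():
    frags = enumerate_fragments(Compound("x", "CF"))
    labels = {tuple(f.atoms) for f in frags}
    assert ((9, False),) in labels  # lone F fragment survives
    assert len(frags) == 2  # F and C-F


def _brute_force_fragments(smiles: str) -> set[Fragment]:
    """Independent path enumerator: all simple paths via itertools over the
    adjacency structure, plus ring-closure detection at the path's last atom."""
    mol = Chem.MolFromSmiles(smiles)
    code = [(a.GetAtomicNum(), a.GetIsAromatic()) for a in mol.GetAtoms()]
    order = {}
    for b in mol.GetBonds():
        o = 4 if b.GetIsAromatic() else {"SINGLE": 1, "DOUBLE": 2, "TRIPLE": 3}.get(b.GetBondType().name, 1)
        order[frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))] = o
    n = mol.GetNumAtoms()
    frags: set[Fragment] = set()
    # all simple paths up to 7 atoms by breadth-first extension of partial paths
    paths = [(i,) for i in range(n)]
    all_paths = list(paths)
    for _ in range(6):
        nxt = []
        for p in paths:
            for j in range(n):
                if j not in p and frozenset((p[-1], j)) in order:
                    nxt.append(p + (j,))
        all_paths.extend(nxt)
        paths = nxt
    for p in all_paths:
        atoms = [code[i] for i in p]
        bonds = [order[frozenset((p[k], p[k + 1]))] for k in range(len(p) - 1)]
        if len(p) == 1 and atoms[0][0] in (6, 7, 8):
            continue
        frags.add(Fragment.canonical(atoms, bonds, ring_closure=False))
        if len(p) >= 3 and any(frozenset((p[-1], q)) in order for q in p[:-2]):
            frags.add(Fragment.canonical(atoms, bonds, ring_closure=True))
    return frags


@pytest.mark.parametrize(
    "smiles",
    [
        "CCCC", "CC(C)C", "c1ccccc1", "C1CC1", "C1CCC1C", "OC(=O)CN",
        "N[C@@H](Cc1c[nH]cn1)C(=O)O", "c1ccc2[nH]ccc2c1", "CC(=O)NC1CC1",
        "O=S(=O)(O)c1ccccc1", "C1CC2CCC1C2",
    ],
)
def test_fragment_enumeration_matches_brute_force(smiles):
    got = enumerate_fragments(Compound("x", smiles))
    assert got == _brute_force_fragments(smiles)


# ---------------------------------------------------------------------------
# Hashing
# ---------------------------------------------------------------------------

_atom = st.tuples(st.sampled_from([5, 6, 7, 8, 9, 15, 16, 17, 35]), st.booleans())


@settings(max_examples=200, derandomize=True)
@given(st.lists(_atom, min_size=1, max_size=7), st.data())
def test_hash_range_and_reversal_symmetry(atoms, data):
    bonds = data.draw(st.lists(st.sampled_from([1, 2, 3, 4]), min_size=len(atoms) - 1, max_size=len(atoms) - 1))
    closure = data.draw(st.booleans())
    f = Fragment.canonical(atoms, bonds, ring_closure=closure)
    r = Fragment.canonical(list(reversed(atoms)), list(reversed(bonds)), ring_closure=closure)
    assert f == r
    h = hash_fragment(f)
    assert 0 <= h <= HASH_MOD - 1 == 1020
    assert h == hash_fragment(f) == hash_fragment(r)


# ---------------------------------------------------------------------------
# Fingerprints and Tanimoto
# ---------------------------------------------------------------------------

def test_methane_fingerprint_is_all_zero():
    fp = fingerprint(Compound("x", "C"))
    assert fp.bits == 0 and fp.n_set == 0


def test_fingerprint_is_serialization_invariant():
    a = fingerprint(Compound("a", "CCO"))
    b = fingerprint(Compound("b", "OCC"))
    assert a == b


def test_high_bits_never_set(amino_acids):
    for aa in amino_acids:
        fp = fingerprint(aa.compound())
        assert fp.bits >> 1021 == 0
        assert fp.n_set == fp.bits.bit_count()


def test_butane_bit_count_bounded_by_fragment_count():
    assert fingerprint(Compound("x", "CCCC")).n_set <= 3


@pytest.mark.parametrize(
    "on_a,on_b,expected",
    [
        ([1, 2, 3], [1, 2, 3], 1.0),
        ([1, 2], [3, 4], 0.0),
        ([1, 2, 3], [2, 3, 4], 0.5),
        ([], [], 1.0),
        ([], [5], 0.0),
    ],
)
def test_tanimoto_values(on_a, on_b, expected):
    assert tanimoto(Fingerprint.from_on_bits(on_a), Fingerprint.from_on_bits(on_b)) == expected


@settings(max_examples=200, derandomize=True)
@given(
    st.sets(st.integers(0, 1023), max_size=40),
    st.sets(st.integers(0, 1023), max_size=40),
)
def test_tanimoto_symmetric_bounded_and_identity(sa, sb):
    fa, fb = Fingerprint.from_on_bits(sorted(sa)), Fingerprint.from_on_bits(sorted(sb))
    t = tanimoto(fa, fb)
    assert t == tanimoto(fb, fa)
    assert 0.0 <= t <= 1.0
    assert (t == 1.0) == (sa == sb)


def test_hex_round_trip(amino_acids):
    fp = fingerprint(amino_acids[0].compound())
    assert Fingerprint.from_hex(fp.to_hex()) == fp


# ---------------------------------------------------------------------------
# Similarity search vs exhaustive oracle
# ---------------------------------------------------------------------------

def _exhaustive(queries, library, threshold, strict=False):
    hits = set()
    for q in queries:
        fq = fingerprint(q)
        for c in library:
            t = tanimoto(fq, fingerprint(c))
            if (t > threshold) if strict else (t >= threshold):
                hits.add((q.id, c.id, round(t, 12)))
    return hits


def test_identical_query_hits_itself():
    lib = [Compound(f"L{i}", s) for i, s in enumerate(["CCO", "CCCO", "c1ccccc1O"])]
    hits = similarity_search([Compound("Q", "CCO")], lib, threshold=0.7)
    exact = [h for h in hits if h.hit_id == "L0"]
    assert exact and exact[0].tanimoto == 1.0


def test_threshold_one_without_match_is_empty_not_error():
    lib = [Compound("L0", "CCCCCCCC")]
    assert similarity_search([Compound("Q", "c1ccncc1")], lib, threshold=1.0) == []


def test_empty_query_set_is_error():
    with pytest.raises(ValueError):
        similarity_search([], [Compound("L0", "CCO")], 0.7)


@pytest.mark.parametrize("threshold", [0.3, 0.5, 0.7, 0.9, 1.0])
def test_indexed_search_equals_exhaustive_scan(threshold):
    lib = [sc.compound for sc in generate_library(SimConfig(seed=11, n_compounds=500))]
    queries = lib[::25]  # 20 queries drawn from the library itself
    got = {(h.query_id, h.hit_id, round(h.tanimoto, 12)) for h in similarity_search(queries, lib, threshold)}
    assert got == _exhaustive(queries, lib, threshold)


# ---------------------------------------------------------------------------
# Clustering / diverse picks
# ---------------------------------------------------------------------------

def test_cluster_and_pick_contracts(amino_acids):
    lib = [a.compound() for a in amino_acids][:10]
    assert len(cluster_and_pick(lib, k=1, per_cluster=2, seed=0)) == 2
    assert len(cluster_and_pick(lib, k=10, per_cluster=2, seed=0)) == 10
    with pytest.raises(ValueError):
        cluster_and_pick(lib, k=11, per_cluster=2, seed=0)


def test_cluster_and_pick_on_literature_scale_library():
    lib = [sc.compound for sc in generate_library(SimConfig(seed=5, n_compounds=121))]
    picks = cluster_and_pick(lib, k=33, per_cluster=2, seed=0)
    assert 33 <= len(picks) <= 66
    assert len({c.id for c in picks}) == len(picks)
    # deterministic given the seed
    again = cluster_and_pick(lib, k=33, per_cluster=2, seed=0)
    assert [c.id for c in again] == [c.id for c in picks]
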