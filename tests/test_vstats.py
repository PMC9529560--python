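"""Correlation, Mann-Whitney and rule-metric behaviour against closed forms."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from vrascreen.vstats import (
    analysis_summary,
    build_analysis_table,
    correlate_classifier,
    descriptor_panels,
    evaluate_rule,
    group_comparison,
    sweep_rule,
)


def _table(values, groups):
    return pd.DataFrame({"avg_rel_visc": values, "n_charge_groups": groups,
                         "is_vra": [int(v <= 0.8) for v in values]})


# ---------------------------------------------------------------------------
# Point-biserial correlation
# ---------------------------------------------------------------------------

def test_pearson_hand_computed_example():
    t = pd.DataFrame({"is_vra": [1, 1, 0, 0], "d": [3, 4, 1, 2]})
    r = correlate_classifier(t, ["d"])["d"]
    assert r == pytest.approx(2 / math.sqrt(5))


def test_perfectly_aligned_descriptor_gives_unit_correlation():
    t = pd.DataFrame({"is_vra": [1, 0, 1, 0], "d": [1.0, 0.0, 1.0, 0.0]})
    assert correlate_classifier(t, ["d"])["d"] == pytest.approx(1.0)


def test_constant_descriptor_is_undefined_not_zero():
    t = pd.DataFrame({"is_vra": [1, 0, 1], "d": [2.0, 2.0, 2.0]})
    assert correlate_classifier(t, ["d"])["d"] is None


def test_fewer_than_three_rows_rejected():
    with pytest.raises(ValueError):
        correlate_classifier(pd.DataFrame({"is_vra": [1, 0], "d": [1.0, 2.0]}), ["d"])


def test_pearson_equals_point_biserial_closed_form():
    rng = np.random.default_rng(0)
    for _ in range(20):
        y = rng.integers(0, 2, size=30)
        if y.min() == y.max():
            continue
        x = rng.normal(size=30) + y
        t = pd.DataFrame({"is_vra": y, "d": x})
        r = correlate_classifier(t, ["d"])["d"]
        # closed form: (M1 - M0)/s_n * sqrt(p*q), population sd
        m1, m0 = x[y == 1].mean(), x[y == 0].mean()
        p = y.mean()
        expected = (m1 - m0) / x.std() * math.sqrt(p * (1 - p))
        assert r == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_separated_groups_exact_p():
    t = _table([0.5, 0.6, 0.7, 0.9, 1.0, 1.1], [3, 3, 3, 1, 1, 2])
    res = group_comparison(t)
    assert res.method == "exact"
    assert res.u == 0.0  # every >=3 value below every <=2 value
    assert res.p == pytest.approx(0.1)  # 2/20 arrangements as extreme


def test_identical_groups_give_p_one():
    t = _table([0.5, 0.6, 0.7, 0.5, 0.6, 0.7], [3, 3, 3, 1, 1, 2])
    assert group_comparison(t).p == pytest.approx(1.0)


def test_empty_stratum_rejected():
    with pytest.raises(ValueError):
        group_comparison(_table([0.5, 0.6], [3, 4]))


def _brute_force_two_sided_p(hi, lo):
    """Full enumeration of the null distribution of U over all group splits."""
    pooled = np.concatenate([hi, lo])
    n1 = len(hi)

    def ustat(idx):
        g1 = pooled[list(idx)]
        g2 = np.delete(pooled, list(idx))
        return sum(np.sum(a > g2) + 0.5 * np.sum(a == g2) for a in g1)

    u_obs = ustat(range(n1))
    us = [ustat(c) for c in itertools.combinations(range(len(pooled)), n1)]
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


@pytest.mark.parametrize("n1,n2,seed", [(3, 3, 1), (4, 5, 2), (6, 4, 3), (8, 8, 4), (5, 8, 5)])
def test_exact_path_matches_full_enumeration(n1, n2, seed):
    rng = np.random.default_rng(seed)
    hi = rng.normal(0.7, 0.2, size=n1)
    lo = rng.normal(1.0, 0.2, size=n2)
    t = _table(np.concatenate([hi, lo]), [3] * n1 + [1] * n2)
    res = group_comparison(t)
    assert res.method == "exact"
    assert res.p == pytest.approx(_brute_force_two_sided_p(hi, lo), abs=1e-12)


def test_exact_and_asymptotic_agree_at_group_size_eight():
    # the continuity-corrected normal approximation tracks the exact null
    # closely at the 8/8 switchover point: worst-case |dp| stays ~0.01
    rng = np.random.default_rng(9)
    deltas = []
    for _ in range(10):
        vals = rng.normal(0.8, 0.2, size=16)
        t = _table(vals, [3] * 8 + [1] * 8)
        p_exact = group_comparison(t, method="exact").p
        p_asym = group_comparison(t, method="asymptotic").p
        deltas.append(abs(p_exact - p_asym))
    assert max(deltas) <= 0.02
    assert np.median(deltas) <= 0.01


# ---------------------------------------------------------------------------
# Rule evaluation
# ---------------------------------------------------------------------------

def test_perfectly_aligned_rule_scores_one():
    t = _table([0.5, 0.6, 1.0, 1.1], [3, 4, 1, 2])
    e = evaluate_rule(t, 3)
    assert e.sensitivity == e.specificity == e.balanced_accuracy == 1.0
    assert (e.tp, e.fp, e.tn, e.fn) == (2, 0, 2, 0)


def test_always_positive_predictor():
    t = _table([0.5, 0.6, 1.0, 1.1], [3, 4, 3, 4])
    e = evaluate_rule(t, 3)
    assert e.sensitivity == 1.0 and e.specificity == 0.0
    assert e.balanced_accuracy == 0.5


def test_counts_sum_and_permutation_invariance():
    rng = np.random.default_rng(2)
    vals = rng.uniform(0.4, 1.2, size=40)
    grp = rng.integers(0, 6, size=40)
    t = _table(vals, grp)
    e = evaluate_rule(t, 3)
    assert e.tp + e.fp + e.tn + e.fn == 40
    shuffled = t.sample(frac=1.0, random_state=0).reset_index(drop=True)
    assert evaluate_rule(shuffled, 3) == e
    assert set(sweep_rule(t)) == {1, 2, 3, 4, 5}


def test_empty_table_rejected():
    with pytest.raises(ValueError):
        evaluate_rule(_table([], []), 3)


# ---------------------------------------------------------------------------
# Panels and summary
# ---------------------------------------------------------------------------

def test_panels_render_for_single_row_and_carry_threshold(tmp_path):
    t = pd.DataFrame({
        "avg_rel_visc": [0.6], "is_vra": [1], "n_charge_groups": [3],
        "slogp": [-1.0], "mw": [150.0], "hbd": [2], "psa": [80.0], "psa_sasa": [0.5],
    })
    panels = descriptor_panels(t)
    assert panels.threshold == 0.8
    assert panels.filter_windows["mw"] == (100.0, 300.0)
    assert "rel_visc_vs_slogp" in panels.figures
    paths = panels.savefig(tmp_path / "plots")
    assert paths and all(p.endswith(".png") for p in paths)


def test_analysis_summary_structure(study):
    from vrascreen.viscosity import classify_vra

    _, library, measurements, _, fits = study
    records = classify_vra(measurements, fits)
    table = build_analysis_table(
        records,
        {sc.compound.id: sc.compound for sc in library},
        {sc.compound.id: sc.profile for sc in library},
    )
    summary = analysis_summary(table)
    assert {"correlations", "test", "rule_eval"} <= set(summary)
    assert 0.0 <= summary["test"]["p"] <= 1.0
    assert summary["rule_eval"][3]["tp"] + summary["rule_eval"][3]["fn"] == int(table["is_vra"].sum())
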