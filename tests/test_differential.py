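"""Statistical primitives against independent oracles, and group tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lrsplice import differential as dstats
from lrsplice.differential import (
    adjust_pvalues,
    classify_variability,
    fisher_exact_2x2,
    mann_whitney_u,
    pearson_r,
)


# -- Fisher exact -----------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided p by full hypergeometric enumeration with fixed margins."""
    n = a + b + c + d
    r, col = a + b, a + c
    lo, hi = max(0, r + col - n), min(r, col)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col, r)
    if not pmf.sum() > 0:  # degenerate margins admit a single table
        return 1.0
    obs = sps.hypergeom.pmf(a, n, col, r)
    return float(pmf[pmf <= obs * (1 + 1e-7)].sum())


def test_fisher_diagonal_table():
    """[[10,0],[0,10]]: p = 2 / C(20,10)."""
    p, odds = fisher_exact_2x2([[10, 0], [0, 10]])
    assert p == pytest.approx(2 / 184756, rel=1e-7)
    assert math.isinf(odds)


def test_fisher_symmetric_table():
    p, odds = fisher_exact_2x2([[5, 5], [5, 5]])
    assert p == pytest.approx(1.0)
    assert odds == pytest.approx(1.0)


def test_fisher_sample_odds_ratio():
    _, odds = fisher_exact_2x2([[9, 991], [1, 999]])
    assert odds == pytest.approx(9 * 999 / 991, rel=1e-9)


def test_fisher_rejects_bad_counts():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[1, -2], [3, 4]])
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0.5, 1], [2, 3]])


def test_fisher_matches_enumeration_small_tables():
    """Exhaustive agreement with the hypergeometric oracle, total <= 14."""
    for n in range(0, 15):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    p, _ = fisher_exact_2x2([[a, b], [c, d]])
                    assert p == pytest.approx(
                        fisher_oracle(a, b, c, d), rel=1e-7, abs=1e-12
                    )


# -- multiple testing -------------------------------------------------------

def bh_oracle(p, by=False):
    """Independent sort-based step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    c = np.sum(1.0 / np.arange(1, m + 1)) if by else 1.0
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * c * m / rank)
        adj[i] = val
        prev = val
    return np.minimum(adj, 1.0)


def test_bh_step_up_example():
    out = adjust_pvalues([0.01, 0.02, 0.03], "BH")
    assert np.allclose(out, [0.03, 0.03, 0.03])


def test_by_single_p_is_identity():
    assert adjust_pvalues([0.2], "BY")[0] == pytest.approx(0.2)


@pytest.mark.parametrize("method,by", [("BH", False), ("BY", True)])
def test_adjustment_matches_sort_oracle(method, by):
    rng = np.random.default_rng(1)
    p = rng.random(100)
    assert np.allclose(adjust_pvalues(p, method), bh_oracle(p, by=by))


def test_adjustment_rejects_out_of_range():
    with pytest.raises(ValueError):
        adjust_pvalues([0.5, 1.5], "BH")


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_adjusted_p_at_least_raw_and_monotone(p):
    adj = adjust_pvalues(p, "BH")
    assert np.all(adj >= np.asarray(p) - 1e-12)
    assert np.all(adj <= 1.0)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(adj[order]) >= -1e-12)


# -- Mann-Whitney -----------------------------------------------------------

def mw_enumeration_oracle(x, y):
    """Exact permutation p via direct pairwise comparison counts."""
    pooled = list(x) + list(y)
    nx = len(x)
    mu = nx * len(y) / 2

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(
            (xi > yi) + 0.5 * (xi == yi) for xi in xs for yi in ys
        )

    obs = abs(u_of(tuple(range(nx))) - mu)
    splits = list(itertools.combinations(range(len(pooled)), nx))
    hits = sum(1 for idx in splits if abs(u_of(idx) - mu) >= obs - 1e-12)
    return hits / len(splits)


def test_mw_complete_separation():
    u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0


def test_mw_identical_samples():
    with pytest.warns(UserWarning):
        _, p = mann_whitney_u([2, 2, 2], [2, 2, 2])
    assert p == 1.0


def test_mw_exact_matches_enumeration():
    """n_x = n_y = 6: exact p equals enumeration over all C(12,6) splits."""
    rng = np.random.default_rng(9)
    for rep in range(5):
        x = rng.integers(0, 8, size=6).astype(float)  # integers force ties
        y = rng.integers(0, 8, size=6).astype(float)
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)


def test_mw_large_sample_close_to_scipy():
    rng = np.random.default_rng(2)
    x, y = rng.normal(0, 1, 40), rng.normal(0.5, 1, 35)
    u, p = mann_whitney_u(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided")
    assert u == pytest.approx(float(ref.statistic))
    assert p == pytest.approx(float(ref.pvalue), rel=1e-6)


# -- Pearson ----------------------------------------------------------------

def test_pearson_exact_lines():
    x = np.arange(10.0)
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r2, _ = pearson_r(x, -x)
    assert r2 == pytest.approx(-1.0)


def test_pearson_matches_covariance_oracle():
    rng = np.random.default_rng(4)
    x, y = rng.normal(size=50), rng.normal(size=50)
    r, _ = pearson_r(x, y)
    oracle = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
    assert r == pytest.approx(oracle, abs=1e-12)


def test_pearson_zero_variance_errors():
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])


# -- differential events ----------------------------------------------------

def make_counts(rows):
    """rows: (event_id, cell_type, inc, exc)"""
    df = pd.DataFrame(rows, columns=["event_id", "cell_type", "inc", "exc"])
    df["etype"] = "SE"
    df["gene_id"] = "G"
    tot = df["inc"] + df["exc"]
    df["psi"] = df["inc"] / tot.where(tot > 0)
    return df


def test_differential_strong_effect_significant():
    counts = make_counts([
        ("E1", "A", 90, 10), ("E1", "B", 10, 90),
    ])
    res = dstats.test_differential(counts, [("A", ["A"], "B", ["B"])])
    row = res.iloc[0]
    assert row.delta_psi == pytest.approx(0.80)
    assert row.significant


def test_differential_identical_counts_not_significant():
    counts = make_counts([("E1", "A", 50, 50), ("E1", "B", 50, 50)])
    res = dstats.test_differential(counts, [("A", ["A"], "B", ["B"])])
    assert res.iloc[0].delta_psi == 0.0
    assert not res.iloc[0].significant


def test_differential_group_swap_negates_delta():
    counts = make_counts([
        ("E1", "A", 70, 30), ("E1", "B", 40, 60),
        ("E2", "A", 15, 85), ("E2", "B", 30, 70),
    ])
    fwd = dstats.test_differential(counts, [("A", ["A"], "B", ["B"])])
    rev = dstats.test_differential(counts, [("B", ["B"], "A", ["A"])])
    assert np.allclose(fwd["delta_psi"].to_numpy(),
                       -rev["delta_psi"].to_numpy())
    assert np.allclose(fwd["p"].to_numpy(), rev["p"].to_numpy())


def test_differential_min_reads_gate():
    counts = make_counts([("E1", "A", 4, 4), ("E1", "B", 50, 50)])
    res = dstats.test_differential(counts, [("A", ["A"], "B", ["B"])], min_reads=10)
    assert res.empty


def test_differential_unknown_cell_type_errors():
    counts = make_counts([("E1", "A", 10, 10), ("E1", "B", 10, 10)])
    with pytest.raises(ValueError, match="Zed"):
        dstats.test_differential(counts, [("A", ["A"], "Z", ["Zed"])])


def test_differential_power_at_planted_conditions():
    """delta PSI 0.30 at 500 reads/group is called in >= 90% of 200 reps."""
    rng = np.random.default_rng(0)
    called = 0
    for _ in range(200):
        inc_a = rng.binomial(500, 0.5)
        inc_b = rng.binomial(500, 0.2)
        counts = make_counts([
            ("E", "A", inc_a, 500 - inc_a), ("E", "B", inc_b, 500 - inc_b),
        ])
        res = dstats.test_differential(counts, [("A", ["A"], "B", ["B"])])
        called += bool(res.iloc[0].significant)
    assert called >= 0.90 * 200


def test_differential_null_type_i_control():
    """Under equal true PSI, BH-significant fraction <= 0.05 + 3 SE."""
    rng = np.random.default_rng(1)
    rows = []
    for i in range(200):
        inc_a = rng.binomial(100, 0.5)
        inc_b = rng.binomial(100, 0.5)
        rows += [(f"E{i}", "A", inc_a, 100 - inc_a),
                 (f"E{i}", "B", inc_b, 100 - inc_b)]
    res = dstats.test_differential(make_counts(rows), [("A", ["A"], "B", ["B"])])
    frac = res["significant"].mean()
    assert frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / 200)


# -- variability ------------------------------------------------------------

def test_variability_switch_like():
    counts = make_counts([
        ("E1", "A", 90, 10), ("E1", "B", 10, 90), ("E1", "C", 2, 3),
    ])
    res = classify_variability(counts, ["A", "B", "C"], min_reads=10)
    row = res.iloc[0]
    assert row.max_delta_psi == pytest.approx(0.8)
    assert row.variability == "high"
    assert row.n_cell_types == 2  # C undefined below min_reads


def test_variability_flat_is_low():
    counts = make_counts([
        ("E1", "A", 50, 50), ("E1", "B", 50, 50), ("E1", "C", 50, 50),
    ])
    res = classify_variability(counts, ["A", "B", "C"])
    assert res.iloc[0].variability == "low"
    assert res.iloc[0].max_delta_psi == 0.0


def test_variability_label_permutation_invariant():
    counts = make_counts([
        ("E1", "A", 80, 20), ("E1", "B", 30, 70), ("E1", "C", 55, 45),
    ])
    base = classify_variability(counts, ["A", "B", "C"]).iloc[0].max_delta_psi
    permuted = counts.copy()
    permuted["cell_type"] = permuted["cell_type"].map(
        {"A": "C", "B": "A", "C": "B"}
    )
    out = classify_variability(permuted, ["A", "B", "C"]).iloc[0].max_delta_psi
    assert out == pytest.approx(base)


def test_variability_skips_single_defined_cell_type():
    counts = make_counts([("E1", "A", 50, 50), ("E1", "B", 2, 2)])
    assert classify_variability(counts, ["A", "B"], min_reads=10).empty
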