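"""Statistical primitives and cell-type group comparisons.

Differentially spliced / retained events are called from pooled group
counts with a two-sided Fisher exact test at the decision rule
|delta| >= 0.05 and BH-adjusted p < 0.05, with at least 10 informative
reads per group.  Exon variability across cell types is classified by the
maximal pairwise PSI difference (switch-like at >= 0.75).
"""

from __future__ import annotations

import math
import warnings
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(p, sample_odds_ratio)`` where the odds ratio is the plain
    cross-product ad/bc (``inf`` when bc == 0 with ad > 0, ``nan`` when
    both products vanish).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = arr.ravel()
    _, p = sps.fisher_exact(arr.astype(np.int64), alternative="two-sided")
    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.inf if ad > 0 else math.nan
    else:
        odds = ad / bc
    return float(p), float(odds)


def adjust_pvalues(pvalues, method: str = "BH") -> np.ndarray:
    """Step-up FDR adjustment (BH, or BY with the harmonic-number factor)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown adjustment method: {method}")
    return multipletests(p, method=key)[1]


def _rankdata_mid(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns ``(U_x, p)``.

    U is computed from midrank sums.  For pooled sample sizes <= 12 the p
    value is the exact permutation probability of ``|U - n_x n_y / 2|`` at
    least as large as observed; larger samples use the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _rankdata_mid(pooled)
    u_x = float(ranks[:nx].sum() - nx * (nx + 1) / 2)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical in both samples; p = 1")
        return u_x, 1.0
    mu = nx * ny / 2.0
    if nx + ny <= 12:
        obs = abs(u_x - mu)
        n = nx + ny
        hits = total = 0
        rank_sum_all = ranks.sum()
        for idx in combinations(range(n), nx):
            rs = ranks[list(idx)].sum()
            u = rs - nx * (nx + 1) / 2
            total += 1
            if abs(u - mu) >= obs - 1e-12:
                hits += 1
        return u_x, hits / total
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return u_x, float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and its two-sided t-test p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Differential events
# ---------------------------------------------------------------------------

def _pool_group(
    counts: pd.DataFrame, cell_types: Sequence[str]
) -> pd.DataFrame:
    sub = counts[counts["cell_type"].isin(cell_types)]
    return sub.groupby("event_id", sort=True)[["inc", "exc"]].sum()


def test_differential(
    counts: pd.DataFrame,
    comparisons: Sequence[tuple[str, Sequence[str], str, Sequence[str]]],
    known_cell_types: Optional[Sequence[str]] = None,
    min_reads: int = 10,
    delta_cutoff: float = 0.05,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher tests of pooled group counts per event and comparison.

    ``comparisons`` is a list of ``(nameA, cell_types_A, nameB,
    cell_types_B)``.  Per comparison, events with at least ``min_reads``
    informative reads in both pooled groups are tested on
    ``[[incA, excA], [incB, excB]]``; BH adjustment is applied within the
    comparison; significant means |delta| >= ``delta_cutoff`` and adjusted
    p < ``alpha``.  Delta is PSI(A) - PSI(B).
    """
    if known_cell_types is None:
        known_cell_types = sorted(counts["cell_type"].unique())
    known = set(known_cell_types)
    meta = counts.drop_duplicates("event_id").set_index("event_id")[
        ["etype", "gene_id"]
    ]
    out_frames = []
    for name_a, group_a, name_b, group_b in comparisons:
        for ct in list(group_a) + list(group_b):
            if ct not in known:
                raise ValueError(f"unknown cell type in comparison: {ct}")
        if set(group_a) & set(group_b):
            raise ValueError("comparison groups must be disjoint")
        pa = _pool_group(counts, group_a)
        pb = _pool_group(counts, group_b)
        joined = pa.join(pb, lsuffix="_a", rsuffix="_b", how="inner")
        tot_a = joined["inc_a"] + joined["exc_a"]
        tot_b = joined["inc_b"] + joined["exc_b"]
        joined = joined[(tot_a >= min_reads) & (tot_b >= min_reads)]
        if joined.empty:
            continue
        psis_a = joined["inc_a"] / (joined["inc_a"] + joined["exc_a"])
        psis_b = joined["inc_b"] / (joined["inc_b"] + joined["exc_b"])
        pvals = [
            fisher_exact_2x2([[ia, ea], [ib, eb]])[0]
            for ia, ea, ib, eb in zip(
                joined["inc_a"], joined["exc_a"], joined["inc_b"],
                joined["exc_b"],
            )
        ]
        adj = adjust_pvalues(pvals, "BH")
        delta = psis_a - psis_b
        df = pd.DataFrame(
            {
                "event_id": joined.index,
                "comparison": f"{name_a}_vs_{name_b}",
                "group_a": name_a,
                "group_b": name_b,
                "inc_a": joined["inc_a"].to_numpy(),
                "exc_a": joined["exc_a"].to_numpy(),
                "inc_b": joined["inc_b"].to_numpy(),
                "exc_b": joined["exc_b"].to_numpy(),
                "psi_a": psis_a.to_numpy(),
                "psi_b": psis_b.to_numpy(),
                "delta_psi": delta.to_numpy(),
                "p": pvals,
                "adj_p": adj,
            }
        )
        df["significant"] = (df["delta_psi"].abs() >= delta_cutoff) & (
            df["adj_p"] < alpha
        )
        df = df.join(meta, on="event_id")
        out_frames.append(df)
    if not out_frames:
        return pd.DataFrame(
            columns=["event_id", "comparison", "group_a", "group_b", "inc_a",
                     "exc_a", "inc_b", "exc_b", "psi_a", "psi_b", "delta_psi",
                     "p", "adj_p", "significant", "etype", "gene_id"]
        )
    return pd.concat(out_frames, ignore_index=True)


def classify_variability(
    counts: pd.DataFrame,
    eligible_cell_types: Sequence[str],
    min_reads: int = 10,
    high_cutoff: float = 0.75,
    medium_cutoff: float = 0.25,
) -> pd.DataFrame:
    """Maximal pairwise PSI difference per event across eligible cell types.

    Events with defined PSI (>= ``min_reads`` informative reads) in fewer
    than two eligible cell types are skipped.  Groups: high (>= 0.75 by
    default, the switch-like regime), medium, low (< 0.25).
    """
    sub = counts[counts["cell_type"].isin(eligible_cell_types)].copy()
    tot = sub["inc"] + sub["exc"]
    sub["psi_def"] = np.where(tot >= min_reads, sub["inc"] / tot.where(tot > 0),
                              np.nan)
    rows = []
    for eid, grp in sub.groupby("event_id", sort=True):
        psis = grp.dropna(subset=["psi_def"])
        if len(psis) < 2:
            continue
        values = psis["psi_def"].to_numpy()
        max_delta = float(values.max() - values.min())
        if max_delta >= high_cutoff:
            label = "high"
        elif max_delta >= medium_cutoff:
            label = "medium"
        else:
            label = "low"
        rows.append(
            {
                "event_id": eid,
                "etype": grp["etype"].iloc[0],
                "gene_id": grp["gene_id"].iloc[0],
                "n_cell_types": len(psis),
                "max_delta_psi": max_delta,
                "variability": label,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["event_id", "etype", "gene_id", "n_cell_types",
                 "max_delta_psi", "variability"],
    )
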