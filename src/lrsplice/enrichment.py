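"""Contingency-based enrichment analyses.

Covers curated gene-set enrichment, overlap of differentially spliced
exons with disease-associated exon lists, de novo mutation (DNM) burden in
events and their flanking introns, and the concordance of splicing changes
between two matched comparisons.  All interval logic is 0-based half-open;
overlap means at least one shared base.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import Annotation, Interval, merge_intervals
from .differential import fisher_exact_2x2, pearson_r


@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    log2_or: float
    p: float
    row_labels: tuple[str, str]
    col_labels: tuple[str, str]

    def as_dict(self) -> dict:
        (a, b), (c, d) = self.table
        return {
            "n11": a, "n12": b, "n21": c, "n22": d,
            "odds_ratio": self.odds_ratio, "log2_or": self.log2_or,
            "p": self.p,
            "rows": "|".join(self.row_labels),
            "cols": "|".join(self.col_labels),
        }


def _result(a, b, c, d, rows, cols) -> EnrichmentResult:
    p, odds = fisher_exact_2x2([[a, b], [c, d]])
    if odds == 0:
        log2_or = -math.inf
    elif math.isinf(odds):
        log2_or = math.inf
    elif math.isnan(odds):
        log2_or = math.nan
    else:
        log2_or = math.log2(odds)
    return EnrichmentResult(((a, b), (c, d)), odds, log2_or, p, rows, cols)


def load_gene_sets(path: str) -> dict[str, frozenset[str]]:
    """Read a (set_name, gene_id) TSV into named, deduplicated gene sets."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"],
                     dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"empty gene-set file: {path}")
    return {
        str(name): frozenset(sub["gene"])
        for name, sub in df.groupby("set", sort=True)
    }


def gene_set_enrichment(
    foreground: Sequence[str],
    target: Sequence[str],
    universe: Sequence[str],
) -> EnrichmentResult:
    """Fisher test of a foreground gene list against a curated target set.

    The foreground must be a subset of the universe; the target is
    intersected with the universe before testing.
    """
    fg = frozenset(foreground)
    uni = frozenset(universe)
    offenders = sorted(fg - uni)
    if offenders:
        raise ValueError(
            "foreground genes absent from universe: " + ", ".join(offenders)
        )
    tg = frozenset(target) & uni
    rest = uni - fg
    a = len(fg & tg)
    b = len(fg - tg)
    c = len(rest & tg)
    d = len(rest - tg)
    return _result(
        a, b, c, d,
        ("foreground", "background"), ("in_target", "not_in_target"),
    )


def _overlaps_any(
    chrom: str, start: int, end: int,
    intervals_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]],
) -> bool:
    if chrom not in intervals_by_chrom:
        return False
    starts, ends = intervals_by_chrom[chrom]
    i = int(np.searchsorted(starts, end, side="left"))
    return bool(np.any(ends[:i] > start))


def _index_intervals(
    intervals: Sequence[tuple[str, int, int]]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[Interval]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    out = {}
    for chrom, ivs in by_chrom.items():
        merged = merge_intervals(ivs)
        out[chrom] = (
            np.array([s for s, _ in merged], dtype=np.int64),
            np.array([e for _, e in merged], dtype=np.int64),
        )
    return out


def exon_overlap_enrichment(
    dse_intervals: Sequence[tuple[str, int, int]],
    background_intervals: Sequence[tuple[str, int, int]],
    disease_exons: Sequence[tuple[str, int, int]],
) -> EnrichmentResult:
    """Overlap of significant vs background events with disease exon lists.

    Overlap is strand-agnostic, >= 1 bp on the same chromosome; the
    background should be the tested-but-not-significant events of the same
    comparison.
    """
    if not background_intervals:
        raise ValueError("empty background interval list")
    idx = _index_intervals(disease_exons)
    a = sum(1 for c, s, e in dse_intervals if _overlaps_any(c, s, e, idx))
    b = len(dse_intervals) - a
    c_ = sum(1 for c, s, e in background_intervals if _overlaps_any(c, s, e, idx))
    d = len(background_intervals) - c_
    return _result(
        a, b, c_, d, ("DSE", "background"), ("overlap", "no_overlap")
    )


def load_dnms(path: str) -> pd.DataFrame:
    """Read a DNM TSV (chrom, pos, ref, alt, group[, score]); pos 0-based."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DNM table missing columns: {sorted(missing)}")
    if (df["pos"] < 0).any():
        raise ValueError("negative DNM position")
    if df["group"].isna().any() or (df["group"] == "").any():
        raise ValueError("DNM records must carry a group label")
    if "score" not in df.columns:
        df["score"] = np.nan
    return df


def expand_regions(
    regions: Sequence[tuple[str, int, int]],
    flank: int,
    annotation: Optional[Annotation] = None,
) -> list[tuple[str, int, int]]:
    """Expand regions by ``flank`` bp per side into adjacent sequence.

    When an annotation is supplied, flanks are clipped at neighbouring
    annotated exons so they never extend past the adjacent exon boundary
    (the flank covers intronic sequence only).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    out = []
    for chrom, start, end in regions:
        lo = max(0, start - flank)
        hi = end + flank
        if annotation is not None and flank > 0:
            bounds = annotation.exon_boundaries(chrom)
            if bounds.size:
                left = bounds[bounds <= start]
                left = left[left < start]  # boundaries strictly upstream
                if left.size:
                    lo = max(lo, int(left.max()))
                right = bounds[bounds > end]
                if right.size:
                    hi = min(hi, int(right.min()))
        out.append((chrom, lo, hi))
    return out


def dnm_region_enrichment(
    dnms: pd.DataFrame,
    regions: Sequence[tuple[str, int, int]],
    flank: int = 0,
    annotation: Optional[Annotation] = None,
    groups: tuple[str, str] = ("proband", "sibling"),
) -> EnrichmentResult:
    """Burden of DNMs inside (expanded) regions, probands vs siblings.

    The 2x2 is {group} x {in regions, outside}; totals per group are all
    supplied DNMs of that group.  Containment is half-open: a variant at
    the region start is inside, one at the end coordinate is outside.
    """
    g1, g2 = groups
    for g in groups:
        if (dnms["group"] == g).sum() == 0:
            raise ValueError(f"group with zero DNMs: {g}")
    expanded = expand_regions(regions, flank, annotation)
    idx = _index_intervals(expanded)

    def inside_count(sub: pd.DataFrame) -> int:
        n = 0
        for chrom, pos in zip(sub["chrom"], sub["pos"]):
            n += _overlaps_any(str(chrom), int(pos), int(pos) + 1, idx)
        return n

    sub1 = dnms[dnms["group"] == g1]
    sub2 = dnms[dnms["group"] == g2]
    a = inside_count(sub1)
    b = len(sub1) - a
    c = inside_count(sub2)
    d = len(sub2) - c
    return _result(a, b, c, d, (g1, g2), ("in_regions", "outside"))


def filter_splice_dnms(
    dnms: pd.DataFrame,
    annotation: Annotation,
    score_cutoff: float = 0.2,
    junction_window: int = 400,
) -> tuple[pd.DataFrame, int]:
    """Keep variants with splice-effect score strictly above the cutoff and
    within ``junction_window`` bp of an annotated exon boundary.

    Returns the filtered table and the number of variants excluded for
    lacking a score.
    """
    has_score = dnms["score"].notna()
    n_unscored = int((~has_score).sum())
    sub = dnms[has_score]
    keep = []
    for row in sub.itertuples(index=False):
        if row.score <= score_cutoff:
            keep.append(False)
            continue
        dist = annotation.nearest_boundary_distance(str(row.chrom), int(row.pos))
        keep.append(dist is not None and dist <= junction_window)
    return sub[np.array(keep, dtype=bool)] if len(sub) else sub, n_unscored


def delta_psi_concordance(delta1, delta2) -> dict:
    """Pearson correlation and sign-concordance of matched delta-PSI pairs.

    Concordance is the fraction of pairs with equal sign; pairs where
    either delta is exactly zero are excluded from the concordance
    denominator.
    """
    d1 = np.asarray(delta1, dtype=float)
    d2 = np.asarray(delta2, dtype=float)
    if d1.size != d2.size:
        raise ValueError("matched delta vectors must have equal length")
    if d1.size < 3:
        raise ValueError("need at least 3 matched events")
    r, p = pearson_r(d1, d2)
    nz = (d1 != 0) & (d2 != 0)
    concordance = (
        float(np.mean(np.sign(d1[nz]) == np.sign(d2[nz]))) if nz.any() else np.nan
    )
    return {"r": r, "p": p, "concordance": concordance, "n": int(d1.size)}
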