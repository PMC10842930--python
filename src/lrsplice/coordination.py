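"""Exon-pair coordination from reads spanning two cassette exons.

For each eligible cassette-exon pair of a gene, reads with an unambiguous
inclusion/exclusion call at both exons are tallied into a 2x2 matrix
(in-in, in-out, out-in, out-out).  Association is tested by Fisher's exact
test on the raw counts; the reported odds ratio uses +1 pseudocounts,
OR = (in-in+1)(out-out+1) / ((in-out+1)(out-in+1)).  P values are adjusted
genome-wide by Benjamini-Yekutieli; pairs are called mutually inclusive at
log2(OR) >= 1 and FDR < 0.001, mutually exclusive at log2(OR) <= -1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_io import Annotation, ExonChain
from .differential import adjust_pvalues, fisher_exact_2x2
from .events import AMBIGUOUS, INCLUSION, SpliceEvent, assign_read

MUTUALLY_INCLUSIVE = "mutually_inclusive"
MUTUALLY_EXCLUSIVE = "mutually_exclusive"
NONE = "none"


def eligible_exons(
    events: Sequence[SpliceEvent],
    counts: pd.DataFrame,
    annotation: Annotation,
    min_reads: int = 20,
    psi_low: float = 0.05,
    psi_high: float = 0.95,
) -> list[SpliceEvent]:
    """Cassette exons eligible for coordination analysis.

    Keeps SE events with pooled inclusion+exclusion >= ``min_reads`` and
    pooled PSI strictly inside (``psi_low``, ``psi_high``); cassettes that
    overlap the gene's genomically first or last annotated exon are
    excluded (terminal exons).
    """
    pooled = counts.groupby("event_id")[["inc", "exc"]].sum()
    keep = []
    for ev in events:
        if ev.etype != "SE":
            continue
        if ev.event_id not in pooled.index:
            continue
        inc, exc = pooled.loc[ev.event_id]
        tot = inc + exc
        if tot < min_reads:
            continue
        psi = inc / tot
        if not (psi_low < psi < psi_high):
            continue
        exons = annotation.exon_union(ev.gene_id)
        first, last = exons[0], exons[-1]
        cs, ce = ev.cassette
        if cs < first[1] and ce > first[0]:
            continue
        if cs < last[1] and ce > last[0]:
            continue
        keep.append(ev)
    keep.sort(key=lambda e: (e.chrom, e.cassette))
    return keep


def pair_counts(
    exon_a: SpliceEvent,
    exon_b: SpliceEvent,
    chains: Iterable[ExonChain],
    min_overhang: int = 5,
) -> tuple[int, int, int, int]:
    """(in-in, in-out, out-in, out-out) counts over unambiguous spanning reads.

    Only chains with a non-ambiguous call at *both* exons contribute.
    """
    if exon_a.event_id == exon_b.event_id:
        raise ValueError("exon pair must be two distinct events")
    n11 = n10 = n01 = n00 = 0
    for chain in chains:
        ca = assign_read(exon_a, chain, min_overhang=min_overhang)
        if ca == AMBIGUOUS:
            continue
        cb = assign_read(exon_b, chain, min_overhang=min_overhang)
        if cb == AMBIGUOUS:
            continue
        if ca == INCLUSION:
            if cb == INCLUSION:
                n11 += 1
            else:
                n10 += 1
        else:
            if cb == INCLUSION:
                n01 += 1
            else:
                n00 += 1
    return n11, n10, n01, n00


def pseudocount_odds_ratio(n11: int, n10: int, n01: int, n00: int) -> float:
    """OR with +1 pseudocounts in every cell; always finite and positive."""
    return ((n11 + 1) * (n00 + 1)) / ((n10 + 1) * (n01 + 1))


def coordination_test(
    pairs: pd.DataFrame,
    or_cutoff_log: float = 1.0,
    fdr_alpha: float = 0.001,
    log_base: float = 2.0,
) -> pd.DataFrame:
    """Add OR, p, FDR (BY) and coordination class to a pair-count table.

    ``pairs`` needs columns n_in_in, n_in_out, n_out_in, n_out_out; rows
    with all four counts zero are dropped before testing.  P values come
    from Fisher's exact test on the raw counts; pseudocounts affect only
    the reported odds ratio.
    """
    df = pairs.copy()
    total = (
        df["n_in_in"] + df["n_in_out"] + df["n_out_in"] + df["n_out_out"]
    )
    df = df[total > 0].reset_index(drop=True)
    if df.empty:
        for col in ("odds_ratio", "log_or", "p", "fdr"):
            df[col] = []
        df["coordination"] = []
        return df
    ors, ps = [], []
    for n11, n10, n01, n00 in zip(
        df["n_in_in"], df["n_in_out"], df["n_out_in"], df["n_out_out"]
    ):
        ors.append(pseudocount_odds_ratio(n11, n10, n01, n00))
        p, _ = fisher_exact_2x2([[n11, n10], [n01, n00]])
        ps.append(p)
    df["odds_ratio"] = ors
    df["log_or"] = [math.log(o, log_base) for o in ors]
    df["p"] = ps
    df["fdr"] = adjust_pvalues(ps, "BY")
    cls = []
    for log_or, fdr in zip(df["log_or"], df["fdr"]):
        if fdr < fdr_alpha and log_or >= or_cutoff_log:
            cls.append(MUTUALLY_INCLUSIVE)
        elif fdr < fdr_alpha and log_or <= -or_cutoff_log:
            cls.append(MUTUALLY_EXCLUSIVE)
        else:
            cls.append(NONE)
    df["coordination"] = cls
    return df


def coordinate(
    events: Sequence[SpliceEvent],
    counts: pd.DataFrame,
    chains: Sequence[ExonChain],
    annotation: Annotation,
    min_reads: int = 20,
    min_overhang: int = 5,
    or_cutoff_log: float = 1.0,
    fdr_alpha: float = 0.001,
) -> pd.DataFrame:
    """Full coordination analysis: eligibility, pair counts, test.

    All cassette-exon pairs within a gene (exon A genomically upstream of
    exon B) with at least one unambiguously spanning read are tested.
    """
    eligible = eligible_exons(events, counts, annotation, min_reads=min_reads)
    by_gene: dict[str, list[SpliceEvent]] = {}
    for ev in eligible:
        by_gene.setdefault(ev.gene_id, []).append(ev)
    chains_by_chrom: dict[str, list[ExonChain]] = {}
    for ch in chains:
        chains_by_chrom.setdefault(ch.chrom, []).append(ch)

    rows = []
    for gid in sorted(by_gene):
        evs = sorted(by_gene[gid], key=lambda e: e.cassette)
        if len(evs) < 2:
            continue
        gene = None
        for i in range(len(evs)):
            for j in range(i + 1, len(evs)):
                ea, eb = evs[i], evs[j]
                lo = min(ea.span[0], eb.span[0])
                hi = max(ea.span[1], eb.span[1])
                pool = [
                    c for c in chains_by_chrom.get(ea.chrom, [])
                    if c.span[0] < hi and c.span[1] > lo
                ]
                n11, n10, n01, n00 = pair_counts(
                    ea, eb, pool, min_overhang=min_overhang
                )
                rows.append(
                    {
                        "gene_id": gid,
                        "exon_a": ea.event_id,
                        "exon_b": eb.event_id,
                        "cassette_a": f"{ea.cassette[0]}-{ea.cassette[1]}",
                        "cassette_b": f"{eb.cassette[0]}-{eb.cassette[1]}",
                        "n_in_in": n11,
                        "n_in_out": n10,
                        "n_out_in": n01,
                        "n_out_out": n00,
                    }
                )
    pairs = pd.DataFrame(
        rows,
        columns=["gene_id", "exon_a", "exon_b", "cassette_a", "cassette_b",
                 "n_in_in", "n_in_out", "n_out_in", "n_out_out"],
    )
    return coordination_test(
        pairs, or_cutoff_log=or_cutoff_log, fdr_alpha=fdr_alpha
    )
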