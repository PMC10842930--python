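"""Isoform catalog: collapse exon chains and classify against annotation.

Structural classes follow the long-read community convention:

* ``FSM``  — junction chain equals a reference transcript's full chain
* ``ISM``  — contiguous, proper sub-chain of a reference transcript
* ``NIC``  — only known donors/acceptors, in an unannotated combination
* ``NNC``  — at least one unannotated donor or acceptor
* ``antisense`` / ``genic`` / ``intergenic`` / ``fusion`` as edge classes
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional

import pandas as pd

from .core_io import (
    Annotation,
    ExonChain,
    Interval,
    Junction,
    overlap_length,
)

CLASSES = (
    "FSM", "ISM", "NIC", "NNC", "antisense", "genic", "intergenic", "fusion",
)


@dataclass
class IsoformRecord:
    isoform_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    read_ids: tuple[str, ...]
    read_count: int
    gene_id: Optional[str] = None
    structural_class: Optional[str] = None

    @property
    def junctions(self) -> tuple[Junction, ...]:
        b = self.blocks
        return tuple((b[i][1], b[i + 1][0]) for i in range(len(b) - 1))

    @property
    def span(self) -> Interval:
        return self.blocks[0][0], self.blocks[-1][1]


def collapse_reads(
    chains: Iterable[ExonChain],
    min_support: int = 2,
    known_chroms: Optional[set[str]] = None,
) -> list[IsoformRecord]:
    """Collapse exon chains into a non-redundant isoform catalog.

    Multi-exon chains merge when their junction chains (and chrom/strand)
    are identical; the representative spans the union of member ends.
    Mono-exon chains merge when their blocks overlap.  Isoforms supported
    by fewer than ``min_support`` reads are dropped.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    multi: dict[tuple, list[ExonChain]] = {}
    mono: dict[tuple[str, str], list[ExonChain]] = {}
    for chain in chains:
        if known_chroms is not None and chain.chrom not in known_chroms:
            raise ValueError(f"chain on unknown chromosome: {chain.chrom}")
        if len(chain.blocks) > 1:
            key = (chain.chrom, chain.strand, chain.junctions)
            multi.setdefault(key, []).append(chain)
        else:
            mono.setdefault((chain.chrom, chain.strand), []).append(chain)

    records: list[IsoformRecord] = []
    for (chrom, strand, junctions) in sorted(multi):
        members = multi[(chrom, strand, junctions)]
        if len(members) < min_support:
            continue
        start = min(c.blocks[0][0] for c in members)
        end = max(c.blocks[-1][1] for c in members)
        lefts = [start] + [j[1] for j in junctions]
        rights = [j[0] for j in junctions] + [end]
        blocks = tuple(zip(lefts, rights))
        records.append(
            IsoformRecord(
                isoform_id="",
                chrom=chrom,
                strand=strand,
                blocks=blocks,
                read_ids=tuple(sorted(c.read_id for c in members)),
                read_count=len(members),
            )
        )

    # mono-exon: cluster overlapping blocks per chrom/strand
    for (chrom, strand) in sorted(mono):
        members = sorted(mono[(chrom, strand)], key=lambda c: c.blocks[0])
        cluster: list[ExonChain] = []
        cluster_end = None
        def flush():
            if len(cluster) >= min_support:
                s = min(c.blocks[0][0] for c in cluster)
                e = max(c.blocks[0][1] for c in cluster)
                records.append(
                    IsoformRecord(
                        isoform_id="",
                        chrom=chrom,
                        strand=strand,
                        blocks=((s, e),),
                        read_ids=tuple(sorted(c.read_id for c in cluster)),
                        read_count=len(cluster),
                    )
                )
        for c in members:
            s, e = c.blocks[0]
            if cluster and s < cluster_end:
                cluster.append(c)
                cluster_end = max(cluster_end, e)
            else:
                flush()
                cluster = [c]
                cluster_end = e
        flush()

    records.sort(key=lambda r: (r.chrom, r.span, r.strand, r.junctions))
    for i, rec in enumerate(records):
        rec.isoform_id = f"ISO.{i + 1:06d}"
    return records


def _is_contiguous_subchain(sub: tuple, full: tuple) -> bool:
    k = len(sub)
    if k == 0 or k >= len(full):
        return False
    return any(full[i:i + k] == sub for i in range(len(full) - k + 1))


def classify_isoform(
    iso: IsoformRecord, annotation: Annotation
) -> tuple[str, Optional[str]]:
    """Structural class and assigned gene for one isoform.

    Precedence: fusion > gene assignment (FSM/ISM/NIC/NNC) > antisense >
    genic > intergenic.  Gene assignment is by maximal exonic overlap,
    ties broken by smaller gene span then gene id.
    """
    start, end = iso.span
    if iso.chrom not in annotation.chroms:
        warnings.warn(f"isoform chrom absent from annotation: {iso.chrom}")
        return "intergenic", None
    candidates = annotation.genes_overlapping(iso.chrom, start, end)
    blocks = list(iso.blocks)

    same, opposite = [], []
    for g in candidates:
        ov = overlap_length(blocks, annotation.exon_union(g.gene_id))
        if ov > 0:
            (same if g.strand == iso.strand else opposite).append((g, ov))

    # fusion: exonic overlap with >=2 same-strand genes with disjoint spans
    if len(same) >= 2:
        for i in range(len(same)):
            for j in range(i + 1, len(same)):
                gi, gj = same[i][0], same[j][0]
                if gi.end <= gj.start or gj.end <= gi.start:
                    best = max(
                        same,
                        key=lambda t: (t[1], -(t[0].end - t[0].start), t[0].gene_id),
                    )[0]
                    return "fusion", best.gene_id

    if same:
        gene = min(
            same,
            key=lambda t: (-t[1], t[0].end - t[0].start, t[0].gene_id),
        )[0]
        gid = gene.gene_id
        junctions = iso.junctions
        if len(junctions) == 0:
            s, e = iso.blocks[0]
            for tr in annotation.gene_transcripts(gid):
                if any(es <= s and e <= ee for es, ee in tr.exons):
                    return "ISM", gid
            return "genic", gid
        for tr in annotation.gene_transcripts(gid):
            if tr.junctions == junctions:
                return "FSM", gid
        for tr in annotation.gene_transcripts(gid):
            if _is_contiguous_subchain(junctions, tr.junctions):
                return "ISM", gid
        donors = annotation.donor_sites(gid)
        acceptors = annotation.acceptor_sites(gid)
        if iso.strand == "+":
            iso_donors = {l for l, r in junctions}
            iso_acceptors = {r for l, r in junctions}
        else:
            iso_donors = {r for l, r in junctions}
            iso_acceptors = {l for l, r in junctions}
        if iso_donors <= donors and iso_acceptors <= acceptors:
            return "NIC", gid
        return "NNC", gid

    if opposite:
        best = min(
            opposite,
            key=lambda t: (-t[1], t[0].end - t[0].start, t[0].gene_id),
        )[0]
        return "antisense", best.gene_id

    if candidates:
        # inside a gene span but overlapping no exon
        return "genic", candidates[0].gene_id
    return "intergenic", None


def classify_catalog(
    catalog: list[IsoformRecord], annotation: Annotation
) -> list[IsoformRecord]:
    """Classify every isoform in place (returns the same list)."""
    for iso in catalog:
        cls, gid = classify_isoform(iso, annotation)
        iso.structural_class = cls
        iso.gene_id = gid
    return catalog


def catalog_summary(catalog: list[IsoformRecord]) -> dict:
    """Per-class counts/fractions and per-gene isoform counts."""
    if not catalog:
        raise ValueError("empty catalog")
    classes = pd.Series([iso.structural_class for iso in catalog])
    counts = classes.value_counts().reindex(CLASSES, fill_value=0)
    genes = pd.Series(
        [iso.gene_id for iso in catalog if iso.gene_id is not None]
    )
    per_gene = genes.value_counts() if not genes.empty else pd.Series(dtype=int)
    multi_frac = float((per_gene > 1).mean()) if not per_gene.empty else 0.0
    return {
        "class_counts": counts,
        "class_fractions": counts / len(catalog),
        "gene_isoform_counts": per_gene,
        "multi_isoform_gene_fraction": multi_frac,
        "n_isoforms": len(catalog),
    }


def write_catalog(catalog: list[IsoformRecord], path: str) -> None:
    rows = []
    for iso in catalog:
        rows.append(
            {
                "isoform_id": iso.isoform_id,
                "gene_id": iso.gene_id if iso.gene_id else "NA",
                "class": iso.structural_class,
                "chrom": iso.chrom,
                "strand": iso.strand,
                "blocks": ",".join(f"{s}-{e}" for s, e in iso.blocks),
                "read_count": iso.read_count,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "isoform_id", "gene_id", "class", "chrom", "strand", "blocks",
            "read_count",
        ],
    ).to_csv(path, sep="\t", index=False)
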