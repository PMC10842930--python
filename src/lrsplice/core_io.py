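"""Genomic data model and format I/O.

All coordinates inside the package are 0-based half-open ``[start, end)``.
GTF input/output converts at the boundary (GTF is 1-based closed).

A *junction* is stored as the genomic interval of the spliced-out intron,
``(left, right)`` with ``left < right``: ``left`` is the half-open end of the
upstream exon and ``right`` the start of the downstream exon.  Donor and
acceptor are strand-dependent views of the same pair: on the plus strand the
donor coordinate is ``left`` and the acceptor ``right``; on the minus strand
the roles swap.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

Interval = tuple[int, int]
Junction = tuple[int, int]


class GtfParseError(ValueError):
    pass


def to_zero_based(start_1based: int, end_1based: int) -> Interval:
    """Convert a 1-based closed interval to 0-based half-open."""
    return start_1based - 1, end_1based


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based closed."""
    return start + 1, end


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of possibly overlapping intervals, returned sorted."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def overlap_length(a: Sequence[Interval], b: Sequence[Interval]) -> int:
    """Total overlap in bp between two sorted, disjoint interval lists."""
    i = j = 0
    total = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]  # sorted by genomic position, non-overlapping

    @property
    def junctions(self) -> tuple[Junction, ...]:
        ex = self.exons
        return tuple((ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1))

    @property
    def introns(self) -> tuple[Interval, ...]:
        return self.junctions

    @property
    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_ids: tuple[str, ...]


class Annotation:
    """Genes, transcripts and exons with derived splice-site indices.

    Per-gene donor/acceptor/junction/intron sets are the union over the
    gene's transcripts; donor and acceptor coordinates are strand-aware.
    """

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: dict[str, Transcript] = {}
        by_gene: dict[str, list[Transcript]] = {}
        for tr in transcripts:
            if len(tr.exons) == 0:
                raise GtfParseError(f"transcript with zero exons: {tr.transcript_id}")
            if list(tr.exons) != sorted(tr.exons):
                raise GtfParseError(f"unsorted exons in transcript {tr.transcript_id}")
            for (s1, e1), (s2, e2) in zip(tr.exons, tr.exons[1:]):
                if s2 < e1:
                    raise GtfParseError(
                        f"overlapping exons in transcript {tr.transcript_id}"
                    )
            self.transcripts[tr.transcript_id] = tr
            by_gene.setdefault(tr.gene_id, []).append(tr)

        self.genes: dict[str, Gene] = {}
        self._donors: dict[str, frozenset[int]] = {}
        self._acceptors: dict[str, frozenset[int]] = {}
        self._junctions: dict[str, frozenset[Junction]] = {}
        self._exons: dict[str, list[Interval]] = {}
        for gid in sorted(by_gene):
            trs = by_gene[gid]
            chrom = trs[0].chrom
            strand = trs[0].strand
            start = min(tr.span[0] for tr in trs)
            end = max(tr.span[1] for tr in trs)
            self.genes[gid] = Gene(
                gid, chrom, strand, start, end,
                tuple(sorted(tr.transcript_id for tr in trs)),
            )
            donors, acceptors, junctions = set(), set(), set()
            for tr in trs:
                for l, r in tr.junctions:
                    junctions.add((l, r))
                    if strand == "+":
                        donors.add(l)
                        acceptors.add(r)
                    else:
                        donors.add(r)
                        acceptors.add(l)
            self._donors[gid] = frozenset(donors)
            self._acceptors[gid] = frozenset(acceptors)
            self._junctions[gid] = frozenset(junctions)
            self._exons[gid] = merge_intervals(
                ex for tr in trs for ex in tr.exons
            )

        # per-chrom gene index for overlap queries
        self._chrom_genes: dict[str, list[Gene]] = {}
        for g in self.genes.values():
            self._chrom_genes.setdefault(g.chrom, []).append(g)
        self._chrom_starts: dict[str, list[int]] = {}
        for chrom, gs in self._chrom_genes.items():
            gs.sort(key=lambda g: (g.start, g.end, g.gene_id))
            self._chrom_starts[chrom] = [g.start for g in gs]

        # all exon boundaries per chrom (for DNM distance queries etc.)
        self._boundaries: dict[str, np.ndarray] = {}
        bounds: dict[str, set[int]] = {}
        for gid, exons in self._exons.items():
            chrom = self.genes[gid].chrom
            bset = bounds.setdefault(chrom, set())
            for s, e in exons:
                bset.add(s)
                bset.add(e)
        for chrom, bset in bounds.items():
            self._boundaries[chrom] = np.array(sorted(bset), dtype=np.int64)

    # -- derived indices -------------------------------------------------
    def donor_sites(self, gene_id: str) -> frozenset[int]:
        return self._donors[gene_id]

    def acceptor_sites(self, gene_id: str) -> frozenset[int]:
        return self._acceptors[gene_id]

    def junctions(self, gene_id: str) -> frozenset[Junction]:
        return self._junctions[gene_id]

    def introns(self, gene_id: str) -> frozenset[Interval]:
        return self._junctions[gene_id]

    def exon_union(self, gene_id: str) -> list[Interval]:
        """Merged exonic intervals of the gene."""
        return self._exons[gene_id]

    def gene_transcripts(self, gene_id: str) -> list[Transcript]:
        return [self.transcripts[t] for t in self.genes[gene_id].transcript_ids]

    @property
    def chroms(self) -> set[str]:
        return set(self._chrom_genes)

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose span overlaps [start, end) on ``chrom``."""
        gs = self._chrom_genes.get(chrom)
        if not gs:
            return []
        hi = bisect_left(self._chrom_starts[chrom], end)
        return [g for g in gs[:hi] if g.end > start]

    def exon_boundaries(self, chrom: str) -> np.ndarray:
        return self._boundaries.get(chrom, np.empty(0, dtype=np.int64))

    def nearest_boundary_distance(self, chrom: str, pos: int) -> Optional[int]:
        b = self.exon_boundaries(chrom)
        if b.size == 0:
            return None
        i = int(np.searchsorted(b, pos))
        cands = b[max(0, i - 1): i + 1]
        return int(np.min(np.abs(cands - pos)))


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _validate_gtf_lines(path: str) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfParseError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(
                    f"malformed GTF line {lineno}: non-integer coordinates"
                ) from None


def parse_gtf(path: str) -> Annotation:
    """Parse a GTF file into an :class:`Annotation`.

    GTF coordinates (1-based closed) are converted to 0-based half-open.
    A transcript feature with no exon children is rejected by id; a
    malformed line raises :class:`GtfParseError` naming its line number.
    """
    import gffutils

    _validate_gtf_lines(str(path))
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    exons_by_tx: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for ex in db.features_of_type("exon"):
        txid = ex.attributes["transcript_id"][0]
        gid = ex.attributes["gene_id"][0]
        exons_by_tx.setdefault(txid, []).append(ex)
        meta[txid] = (gid, ex.seqid, ex.strand)
    declared = {
        f.attributes["transcript_id"][0]
        for f in db.features_of_type("transcript")
    }
    empty = sorted(declared - set(exons_by_tx))
    if empty:
        raise GtfParseError(f"transcript with zero exons: {', '.join(empty)}")

    transcripts = []
    for txid in sorted(exons_by_tx):
        gid, chrom, strand = meta[txid]
        ivs = sorted(to_zero_based(ex.start, ex.end) for ex in exons_by_tx[txid])
        transcripts.append(Transcript(txid, gid, chrom, strand, tuple(ivs)))
    return Annotation(transcripts)


def write_gtf(annotation: Annotation, path: str, source: str = "lrsplice") -> None:
    """Write an Annotation back to GTF (1-based closed at the boundary)."""
    with open(path, "w") as fh:
        for gid in sorted(annotation.genes):
            g = annotation.genes[gid]
            s1, e1 = to_one_based(g.start, g.end)
            attrs = f'gene_id "{gid}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for txid in g.transcript_ids:
                tr = annotation.transcripts[txid]
                ts, te = to_one_based(*tr.span)
                attrs = f'gene_id "{gid}"; transcript_id "{txid}";'
                fh.write(
                    f"{g.chrom}\t{source}\ttranscript\t{ts}\t{te}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
                for s, e in tr.exons:
                    s1, e1 = to_one_based(s, e)
                    fh.write(
                        f"{g.chrom}\t{source}\texon\t{s1}\t{e1}\t.\t"
                        f"{g.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# Exon chains from alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExonChain:
    """One aligned long read as ordered genomic blocks plus junctions."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[Interval, ...]
    cell_barcode: Optional[str] = None

    def __post_init__(self):
        for (s1, e1), (s2, e2) in zip(self.blocks, self.blocks[1:]):
            if s2 <= e1:
                raise ValueError(f"blocks not disjoint/sorted in {self.read_id}")

    @property
    def junctions(self) -> tuple[Junction, ...]:
        b = self.blocks
        return tuple((b[i][1], b[i + 1][0]) for i in range(len(b) - 1))

    @property
    def junction_set(self) -> frozenset[Junction]:
        return frozenset(self.junctions)

    @property
    def span(self) -> Interval:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def reference_length(self) -> int:
        return self.span[1] - self.span[0]


# CIGAR ops that consume the reference within an exonic block
_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X
_SKIP_OP = 3  # N


def blocks_from_cigar(pos: int, cigartuples) -> tuple[Interval, ...]:
    """Genomic blocks from a 0-based alignment start and CIGAR tuples.

    M/=/X/D extend the current block, N opens a new one, I/S/H/P are
    ignored for the reference projection.
    """
    blocks: list[Interval] = []
    start = cur = pos
    for op, length in cigartuples:
        if op in _BLOCK_OPS:
            cur += length
        elif op == _SKIP_OP:
            if cur > start:
                blocks.append((start, cur))
            cur += length
            start = cur
    if cur > start:
        blocks.append((start, cur))
    return tuple(blocks)


def read_alignments(
    path: str,
    barcode_tag: str = "CB",
    stats: Optional[dict] = None,
) -> Iterator[ExonChain]:
    """Stream primary alignments from SAM/BAM as :class:`ExonChain`.

    Secondary/supplementary records are skipped; unmapped or CIGAR-less
    records are skipped and counted in ``stats`` when a dict is supplied
    (keys ``unmapped``, ``no_cigar``, ``secondary``, ``parsed``).
    Strand is taken from the XS tag when present, else from the flag.
    """
    import pysam

    if stats is None:
        stats = {}
    stats.setdefault("unmapped", 0)
    stats.setdefault("no_cigar", 0)
    stats.setdefault("secondary", 0)
    stats.setdefault("parsed", 0)
    save = pysam.set_verbosity(0)
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        pysam.set_verbosity(save)
        for rec in af:
            if rec.is_secondary or rec.is_supplementary:
                stats["secondary"] += 1
                continue
            if rec.is_unmapped:
                stats["unmapped"] += 1
                continue
            if not rec.cigartuples:
                stats["no_cigar"] += 1
                continue
            blocks = blocks_from_cigar(rec.reference_start, rec.cigartuples)
            if rec.has_tag("XS"):
                strand = rec.get_tag("XS")
            else:
                strand = "-" if rec.is_reverse else "+"
            barcode = rec.get_tag(barcode_tag) if rec.has_tag(barcode_tag) else None
            stats["parsed"] += 1
            yield ExonChain(
                read_id=rec.query_name,
                chrom=rec.reference_name,
                strand=strand,
                blocks=blocks,
                cell_barcode=barcode,
            )


# ---------------------------------------------------------------------------
# Cell map
# ---------------------------------------------------------------------------

@dataclass
class CellTypeMap:
    """Barcode -> cell type, with an optional coarser class level."""

    barcode_to_type: dict[str, str]
    barcode_to_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if any(not v for v in self.barcode_to_type.values()):
            raise ValueError("empty cell-type label in cell map")

    def type_of(self, barcode: str) -> Optional[str]:
        return self.barcode_to_type.get(barcode)

    def class_of(self, barcode: str) -> Optional[str]:
        return self.barcode_to_class.get(barcode)

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.barcode_to_type.values()))

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.barcode_to_class.values()))

    def type_to_class(self) -> dict[str, str]:
        """Mapping from cell-type label to its class (hierarchy lookup)."""
        out: dict[str, str] = {}
        for bc, ct in self.barcode_to_type.items():
            cls = self.barcode_to_class.get(bc)
            if cls is not None:
                prev = out.setdefault(ct, cls)
                if prev != cls:
                    raise ValueError(
                        f"cell type {ct!r} maps to multiple classes "
                        f"({prev!r}, {cls!r})"
                    )
        return out

    def types_in_class(self, cls: str) -> list[str]:
        return sorted(
            ct for ct, c in self.type_to_class().items() if c == cls
        )


def load_cell_map(path: str) -> CellTypeMap:
    """Load a barcode->cell-type TSV (2 or 3 columns, no header).

    Columns: barcode, cell type, optional class. Duplicate barcodes and
    empty files are errors.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.empty:
        raise ValueError(f"empty cell map file: {path}")
    if df.shape[1] < 2:
        raise ValueError("cell map needs at least 2 columns (barcode, cell type)")
    dup = df[df.duplicated(0, keep=False)][0].unique()
    if len(dup):
        raise ValueError(f"duplicate barcodes in cell map: {', '.join(sorted(dup))}")
    b2t = dict(zip(df[0], df[1]))
    b2c = dict(zip(df[0], df[2])) if df.shape[1] >= 3 else {}
    return CellTypeMap(b2t, b2c)


# ---------------------------------------------------------------------------
# Per-base score tracks
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Sparse per-base numeric values per chromosome (e.g. conservation)."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # chrom -> (starts, ends, values), intervals sorted and non-overlapping
        self._data = data
        for chrom, (s, e, v) in data.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite score values on {chrom}")

    @classmethod
    def from_bedgraph(cls, path: str) -> "ScoreTrack":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64,
                   "value": np.float64},
        )
        data = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            data[str(chrom)] = (
                sub["start"].to_numpy(),
                sub["end"].to_numpy(),
                sub["value"].to_numpy(),
            )
        return cls(data)

    def mean(self, chrom: str, start: int, end: int) -> tuple[Optional[float], float]:
        """Mean value over covered bases in [start, end) and covered fraction.

        Returns ``(None, 0.0)`` when no base of the interval is covered.
        """
        if end <= start:
            raise ValueError("empty interval")
        if chrom not in self._data:
            return None, 0.0
        starts, ends, values = self._data[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        total = 0.0
        covered = 0
        for i in range(lo, hi):
            a = max(start, int(starts[i]))
            b = min(end, int(ends[i]))
            if a < b:
                total += values[i] * (b - a)
                covered += b - a
        if covered == 0:
            return None, 0.0
        return total / covered, covered / (end - start)
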