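"""Alternative-splicing events (SE, A5SS, A3SS, IR) and PSI/PIR counting.

Events are discovered from the isoform catalog so that single-read noise
below the support threshold cannot create events.  Reads are assigned per
event as inclusion / exclusion / ambiguous; PSI (PIR for intron retention)
is inclusion / (inclusion + exclusion), left undefined below a read floor.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core_io import Annotation, CellTypeMap, ExonChain, Interval, Junction
from .catalog import IsoformRecord

EVENT_TYPES = ("SE", "A5SS", "A3SS", "IR")

INCLUSION = "inclusion"
EXCLUSION = "exclusion"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class SpliceEvent:
    event_id: str
    etype: str  # SE, A5SS, A3SS, IR
    gene_id: str
    chrom: str
    strand: str
    # SE: two flanking inclusion junctions; A5SS/A3SS: one; IR: empty
    inc_junctions: tuple[Junction, ...]
    # SE: skip junction; A5SS/A3SS: competing junction; IR: intron junction
    exc_junction: Junction
    cassette: Optional[Interval] = None  # SE only
    intron: Optional[Interval] = None  # IR only

    @property
    def span(self) -> Interval:
        coords = [c for j in self.inc_junctions for c in j]
        coords += list(self.exc_junction)
        return min(coords), max(coords)


def _se_id(chrom, cassette, exc):
    return f"SE:{chrom}:{cassette[0]}-{cassette[1]}:{exc[0]}-{exc[1]}"


def discover_events(
    catalog: list[IsoformRecord],
    annotation: Annotation,
) -> list[SpliceEvent]:
    """Discover SE/A5SS/A3SS/IR events from a gene-assigned catalog.

    SE: an internal exon with observed flanking junctions and an observed
    direct (skipping) junction.  A5SS/A3SS: two observed junctions sharing
    one boundary.  IR: an annotated-or-observed junction whose intron is
    fully covered by a single block of some isoform.
    """
    by_gene: dict[str, list[IsoformRecord]] = {}
    for iso in catalog:
        if iso.gene_id is not None and iso.gene_id in annotation.genes:
            by_gene.setdefault(iso.gene_id, []).append(iso)

    events: dict[str, SpliceEvent] = {}
    for gid in sorted(by_gene):
        isos = by_gene[gid]
        gene = annotation.genes[gid]
        chrom, strand = gene.chrom, gene.strand
        observed: set[Junction] = set()
        contexts: set[tuple[Junction, Junction]] = set()
        for iso in isos:
            js = iso.junctions
            observed.update(js)
            for i in range(len(js) - 1):
                contexts.add((js[i], js[i + 1]))

        # SE
        se_pairs: set[frozenset[Junction]] = set()
        for (a, b), (c, d) in sorted(contexts):
            if (a, d) in observed:
                ev = SpliceEvent(
                    event_id=_se_id(chrom, (b, c), (a, d)),
                    etype="SE",
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    inc_junctions=((a, b), (c, d)),
                    exc_junction=(a, d),
                    cassette=(b, c),
                )
                events[ev.event_id] = ev
                # these junction pairs are explained by skipping, not by an
                # alternative 5'/3' boundary of one exon
                se_pairs.add(frozenset(((a, b), (a, d))))
                se_pairs.add(frozenset(((c, d), (a, d))))

        # A5SS / A3SS: junction pairs sharing exactly one boundary
        obs = sorted(observed)
        by_left: dict[int, list[Junction]] = {}
        by_right: dict[int, list[Junction]] = {}
        for j in obs:
            by_left.setdefault(j[0], []).append(j)
            by_right.setdefault(j[1], []).append(j)
        for l, group in sorted(by_left.items()):
            if len(group) < 2:
                continue
            for i in range(len(group)):
                for k in range(i + 1, len(group)):
                    if frozenset((group[i], group[k])) in se_pairs:
                        continue
                    j1, j2 = sorted((group[i], group[k]), key=lambda j: j[1])
                    # shared left boundary: on + it is the donor, so the
                    # alternative boundary is the acceptor (A3SS); on - the
                    # shared boundary is the acceptor, so A5SS.
                    etype = "A3SS" if strand == "+" else "A5SS"
                    inc, exc = j1, j2  # shorter intron = inclusion form
                    eid = (f"{etype}:{chrom}:{inc[0]}-{inc[1]}"
                           f":{exc[0]}-{exc[1]}")
                    events[eid] = SpliceEvent(
                        event_id=eid, etype=etype, gene_id=gid, chrom=chrom,
                        strand=strand, inc_junctions=(inc,), exc_junction=exc,
                    )
        for r, group in sorted(by_right.items()):
            if len(group) < 2:
                continue
            for i in range(len(group)):
                for k in range(i + 1, len(group)):
                    if frozenset((group[i], group[k])) in se_pairs:
                        continue
                    j1, j2 = sorted(
                        (group[i], group[k]), key=lambda j: -j[0]
                    )
                    etype = "A5SS" if strand == "+" else "A3SS"
                    inc, exc = j1, j2  # j1 has larger left = shorter intron
                    eid = (f"{etype}:{chrom}:{inc[0]}-{inc[1]}"
                           f":{exc[0]}-{exc[1]}")
                    events[eid] = SpliceEvent(
                        event_id=eid, etype=etype, gene_id=gid, chrom=chrom,
                        strand=strand, inc_junctions=(inc,), exc_junction=exc,
                    )

        # IR: any annotated or observed junction fully covered by one block
        ir_candidates = sorted(observed | set(annotation.junctions(gid)))
        for (l, r) in ir_candidates:
            covered = any(
                s < l and e > r
                for iso in isos
                for (s, e) in iso.blocks
            )
            if covered:
                eid = f"IR:{chrom}:{l}-{r}"
                events[eid] = SpliceEvent(
                    event_id=eid, etype="IR", gene_id=gid, chrom=chrom,
                    strand=strand, inc_junctions=(), exc_junction=(l, r),
                    intron=(l, r),
                )

    return [events[k] for k in sorted(events)]


def assign_read(
    event: SpliceEvent, chain: ExonChain, min_overhang: int = 5
) -> str:
    """Assign one exon chain to inclusion / exclusion / ambiguous.

    IR inclusion (retention) requires a single block covering the whole
    intron plus ``min_overhang`` bases on both sides; this also prevents a
    chain's terminal block from calling retention unless it clears both
    intron boundaries.
    """
    if chain.chrom != event.chrom:
        return AMBIGUOUS
    junctions = chain.junction_set
    if event.etype == "IR":
        l, r = event.intron
        if (l, r) in junctions:
            return EXCLUSION
        for s, e in chain.blocks:
            if s <= l - min_overhang and e >= r + min_overhang:
                return INCLUSION
        return AMBIGUOUS
    if all(j in junctions for j in event.inc_junctions):
        return INCLUSION
    if event.exc_junction in junctions:
        return EXCLUSION
    return AMBIGUOUS


class _EventIndex:
    """Per-chrom interval index over event spans."""

    def __init__(self, events: Iterable[SpliceEvent]):
        self._by_chrom: dict[str, list[SpliceEvent]] = {}
        for ev in events:
            self._by_chrom.setdefault(ev.chrom, []).append(ev)
        self._starts: dict[str, list[int]] = {}
        self._maxend: dict[str, list[int]] = {}
        for chrom, evs in self._by_chrom.items():
            evs.sort(key=lambda e: e.span)
            self._starts[chrom] = [e.span[0] for e in evs]
            running = []
            m = -1
            for e in evs:
                m = max(m, e.span[1])
                running.append(m)
            self._maxend[chrom] = running

    def overlapping(self, chrom: str, start: int, end: int) -> list[SpliceEvent]:
        evs = self._by_chrom.get(chrom)
        if not evs:
            return []
        hi = bisect_left(self._starts[chrom], end)
        out = []
        for i in range(hi - 1, -1, -1):
            if self._maxend[chrom][i] <= start:
                break
            ev = evs[i]
            if ev.span[1] > start:
                out.append(ev)
        out.reverse()
        return out


def quantify(
    events: list[SpliceEvent],
    chains: Iterable[ExonChain],
    cell_map: CellTypeMap,
    min_reads: int = 10,
    min_overhang: int = 5,
) -> pd.DataFrame:
    """Per event x cell type inclusion/exclusion counts and PSI (PIR).

    Reads without a barcode, or with a barcode absent from the cell map,
    are excluded.  PSI is NaN where inclusion+exclusion < ``min_reads``.
    Every cell type present in the map yields a row per event (zeros when
    no read of that type was seen).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    index = _EventIndex(events)
    cell_types = cell_map.cell_types
    counts: dict[tuple[str, str], list[int]] = {
        (ev.event_id, ct): [0, 0] for ev in events for ct in cell_types
    }
    for chain in chains:
        if chain.cell_barcode is None:
            continue
        ct = cell_map.type_of(chain.cell_barcode)
        if ct is None:
            continue
        s, e = chain.span
        for ev in index.overlapping(chain.chrom, s, e):
            call = assign_read(ev, chain, min_overhang=min_overhang)
            if call == INCLUSION:
                counts[(ev.event_id, ct)][0] += 1
            elif call == EXCLUSION:
                counts[(ev.event_id, ct)][1] += 1

    etype = {ev.event_id: ev.etype for ev in events}
    gene = {ev.event_id: ev.gene_id for ev in events}
    rows = []
    for ev in events:
        for ct in cell_types:
            inc, exc = counts[(ev.event_id, ct)]
            tot = inc + exc
            psi = inc / tot if tot >= min_reads else np.nan
            rows.append((ev.event_id, etype[ev.event_id], gene[ev.event_id],
                         ct, inc, exc, psi))
    return pd.DataFrame(
        rows,
        columns=["event_id", "etype", "gene_id", "cell_type", "inc", "exc",
                 "psi"],
    )


def pooled_counts(counts: pd.DataFrame, min_reads: int = 1) -> pd.DataFrame:
    """Pool counts over all cell types; PSI NaN below ``min_reads``."""
    pooled = (
        counts.groupby(["event_id", "etype", "gene_id"], as_index=False)[
            ["inc", "exc"]
        ].sum()
    )
    tot = pooled["inc"] + pooled["exc"]
    pooled["psi"] = np.where(tot >= min_reads, pooled["inc"] / tot.where(tot > 0),
                             np.nan)
    return pooled


def write_events(events: list[SpliceEvent], path: str) -> None:
    rows = []
    for ev in events:
        rows.append({
            "event_id": ev.event_id,
            "etype": ev.etype,
            "gene_id": ev.gene_id,
            "chrom": ev.chrom,
            "strand": ev.strand,
            "start": ev.span[0],
            "end": ev.span[1],
            "cassette_start": ev.cassette[0] if ev.cassette else -1,
            "cassette_end": ev.cassette[1] if ev.cassette else -1,
            "intron_start": ev.intron[0] if ev.intron else -1,
            "intron_end": ev.intron[1] if ev.intron else -1,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
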