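"""End-to-end orchestration: catalog -> events -> quantify -> differential
-> coordination -> intron features, with every stage's table written to an
output directory and logged with row counts.

Re-running with an identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pyfaidx

from . import catalog as cat
from . import coordination as coord
from . import differential as diff
from . import events as ev
from . import intron_features as feat
from .core_io import ScoreTrack, load_cell_map, parse_gtf, read_alignments


@dataclass
class RunConfig:
    """Inputs and thresholds for a full pipeline run.

    Thresholds default to the published decision rules: 10 informative
    reads for PSI, 20 for coordination eligibility, |dPSI| >= 0.05,
    adjusted p < 0.05, coordination |log2 OR| >= 1 at FDR < 0.001.
    """

    sam: str = ""
    gtf: str = ""
    fasta: str = ""
    cell_map: str = ""
    outdir: str = "lrsplice_out"
    conservation: Optional[str] = None  # bedGraph, optional
    barcode_tag: str = "CB"
    min_support: int = 2
    min_reads: int = 10
    min_overhang: int = 5
    delta_cutoff: float = 0.05
    alpha: float = 0.05
    coord_min_reads: int = 20
    coord_log2_or: float = 1.0
    coord_fdr: float = 0.001
    # comparisons as (nameA, [cell types], nameB, [cell types]); when empty,
    # one comparison per pair of classes in the cell map hierarchy is used
    comparisons: list = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _log(stage: str, t0: float, detail: str) -> None:
    print(f"[lrsplice] {stage}: {detail} ({time.perf_counter() - t0:.1f}s)",
          file=sys.stderr)


def default_comparisons(cell_map) -> list:
    """One comparison per unordered pair of hierarchy classes."""
    classes = cell_map.classes
    comps = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            a, b = classes[i], classes[j]
            comps.append(
                (a, cell_map.types_in_class(a), b, cell_map.types_in_class(b))
            )
    return comps


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns the in-memory results keyed by stage."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    t0 = time.perf_counter()
    annotation = parse_gtf(cfg.gtf)
    cell_map = load_cell_map(cfg.cell_map)
    stats: dict = {}
    chains = list(
        read_alignments(cfg.sam, barcode_tag=cfg.barcode_tag, stats=stats)
    )
    _log("load", t0, f"{len(chains)} chains, {len(annotation.genes)} genes, "
         f"skipped {stats.get('unmapped', 0)} unmapped")

    t0 = time.perf_counter()
    catalog = cat.collapse_reads(chains, min_support=cfg.min_support)
    cat.classify_catalog(catalog, annotation)
    cat.write_catalog(catalog, str(out / "catalog.tsv"))
    results["catalog"] = catalog
    _log("catalog", t0, f"{len(catalog)} isoforms")

    t0 = time.perf_counter()
    events = ev.discover_events(catalog, annotation)
    ev.write_events(events, str(out / "events.tsv"))
    results["events"] = events
    _log("events", t0, f"{len(events)} events")

    t0 = time.perf_counter()
    counts = ev.quantify(
        events, chains, cell_map,
        min_reads=cfg.min_reads, min_overhang=cfg.min_overhang,
    )
    counts.to_csv(out / "counts.tsv", sep="\t", index=False)
    results["counts"] = counts
    _log("quantify", t0, f"{len(counts)} event x cell-type rows")

    t0 = time.perf_counter()
    comparisons = cfg.comparisons or default_comparisons(cell_map)
    dsr = diff.test_differential(
        counts, comparisons,
        known_cell_types=cell_map.cell_types,
        min_reads=cfg.min_reads,
        delta_cutoff=cfg.delta_cutoff, alpha=cfg.alpha,
    )
    dsr.to_csv(out / "differential.tsv", sep="\t", index=False)
    results["differential"] = dsr
    var = diff.classify_variability(
        counts, cell_map.cell_types, min_reads=cfg.min_reads
    )
    var.to_csv(out / "variability.tsv", sep="\t", index=False)
    results["variability"] = var
    _log("differential", t0,
         f"{len(dsr)} tests, {int(dsr['significant'].sum()) if len(dsr) else 0}"
         " significant")

    t0 = time.perf_counter()
    pairs = coord.coordinate(
        events, counts, chains, annotation,
        min_reads=cfg.coord_min_reads, min_overhang=cfg.min_overhang,
        or_cutoff_log=cfg.coord_log2_or, fdr_alpha=cfg.coord_fdr,
    )
    pairs.to_csv(out / "coordination.tsv", sep="\t", index=False)
    results["coordination"] = pairs
    _log("coordination", t0, f"{len(pairs)} pairs")

    t0 = time.perf_counter()
    genome = pyfaidx.Fasta(cfg.fasta)
    pwm = feat.train_pwm(annotation, genome)
    track = (
        ScoreTrack.from_bedgraph(cfg.conservation)
        if cfg.conservation else None
    )
    intron_table = intron_groups_from_differential(dsr, events)
    features = feat.compute_intron_features(intron_table, genome, pwm, track)
    features.to_csv(out / "intron_features.tsv", sep="\t", index=False)
    results["intron_features"] = features
    comps = compare_intron_groups(features)
    comps.to_csv(out / "intron_comparisons.tsv", sep="\t", index=False)
    results["intron_comparisons"] = comps
    _log("features", t0, f"{len(features)} introns")

    return results


def intron_groups_from_differential(
    dsr: pd.DataFrame, events: Sequence[ev.SpliceEvent]
) -> pd.DataFrame:
    """Intron table for feature analysis, grouped by retention direction.

    IR events from the first comparison are grouped as ``higher_in_A`` /
    ``higher_in_B`` (significant, by sign of delta PIR) or
    ``not_differential``.
    """
    ir_events = {e.event_id: e for e in events if e.etype == "IR"}
    rows = []
    sub = dsr[dsr["etype"] == "IR"] if len(dsr) else dsr
    if len(sub):
        # group by the comparison with the deepest IR coverage
        best = sub["comparison"].value_counts().idxmax()
        sub = sub[sub["comparison"] == best]
    for row in sub.itertuples(index=False):
        e = ir_events.get(row.event_id)
        if e is None:
            continue
        if row.significant:
            group = "higher_in_A" if row.delta_psi > 0 else "higher_in_B"
        else:
            group = "not_differential"
        rows.append(
            {"chrom": e.chrom, "start": e.intron[0], "end": e.intron[1],
             "strand": e.strand, "group": group, "event_id": e.event_id}
        )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "group", "event_id"]
    )


def compare_intron_groups(features: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney comparisons of intron features between retention groups."""
    rows = []
    if "group" not in features.columns or features.empty:
        return pd.DataFrame(rows)
    feature_cols = [
        c for c in ("length", "gc", "donor_score", "acceptor_score",
                    "mean_conservation")
        if c in features.columns
    ]
    groups = sorted(features["group"].unique())
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ga, gb = groups[i], groups[j]
            for fc in feature_cols:
                try:
                    rows.append(
                        feat.compare_groups(features, fc, ga, gb)
                    )
                except ValueError:
                    continue
    return pd.DataFrame(rows)
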