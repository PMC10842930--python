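"""Synthetic barcoded long-read dataset with planted splicing structure.

The generator emits a random multi-chromosome genome with canonical GT-AG
genes on both strands, a GTF annotating every noise-free isoform structure
it can produce, a coordinate-sorted SAM of error-free exon-chain reads
(cell barcode in a configurable tag), a barcode-to-cell-type map, and
truth tables for every planted parameter:

* differentially spliced cassette exons (per-cell-type true PSI),
* null cassette exons (equal PSI everywhere),
* coordinated exon pairs with a target joint inclusion odds ratio,
* differentially retained introns with biased GC / length / donor strength,
* 5'-truncated reads (ISM-like), novel-junction reads (NNC-like), and a
  fixed fraction of reads emitted without a barcode.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import Annotation, Interval, Transcript, write_gtf

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

DONOR_EXON_CONSENSUS = "CAG"  # last 3 exonic bases before the donor
DONOR_INTRON_CONSENSUS = "GTAAGT"  # first 6 intronic bases (GT fixed)
ACCEPTOR_EXON_CONSENSUS = "GTT"  # first 3 exonic bases after the acceptor


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset (defaults are the study)."""

    seed: int = 0
    # genome geometry
    n_chroms: int = 4
    exons_per_gene: tuple[int, int] = (5, 8)
    exon_length: tuple[int, int] = (80, 250)
    intron_length: tuple[int, int] = (150, 600)
    intergenic_gap: int = 1000
    base_gc: float = 0.45
    exon_gc: float = 0.50
    donor_strength: float = 0.90
    weak_donor_strength: float = 0.45
    acceptor_strength: float = 0.85
    # cell types: name -> (proportion, class)
    cell_types: dict[str, tuple[float, str]] = field(
        default_factory=lambda: {
            "ExN": (0.25, "neuron"),
            "InN": (0.20, "neuron"),
            "NPC": (0.25, "progenitor"),
            "DivNPC": (0.20, "progenitor"),
            "OPC": (0.10, "glia"),
        }
    )
    barcodes_per_type: int = 60
    barcode_length: int = 16
    # planted differential cassette exons (group A = neurons, B = progenitors)
    n_dse_genes: int = 12
    dse_psi_neuron: float = 0.50
    dse_psi_progenitor: float = 0.20
    dse_psi_other: float = 0.35
    reads_per_dse_gene: int = 2400
    # null cassette exons
    n_null_genes: int = 30
    null_psi: float = 0.50
    reads_per_null_gene: int = 320
    # coordinated exon pairs
    n_pair_genes: int = 8
    pair_theta: float = 16.0
    pair_marginal: float = 0.50
    reads_per_pair_gene: int = 360
    n_indep_pair_genes: int = 12
    reads_per_indep_pair_gene: int = 360
    # retained introns
    n_ir_genes: int = 12
    ir_pir_neuron: float = 0.40
    ir_pir_progenitor: float = 0.05
    ir_pir_other: float = 0.15
    reads_per_ir_gene: int = 420
    ir_intron_gc: float = 0.58
    ir_intron_length: tuple[int, int] = (80, 220)
    ir_weak_donor: bool = True
    # plain genes
    n_background_genes: int = 26
    reads_per_background_gene: int = 100
    # read noise
    truncation_prob: float = 0.25
    novel_junction_rate: float = 0.02
    unassigned_fraction: float = 0.45
    barcode_tag: str = "CB"

    def __post_init__(self):
        props = [p for p, _ in self.cell_types.values()]
        if not math.isclose(sum(props), 1.0, abs_tol=1e-9):
            raise ValueError("cell-type proportions must sum to 1")
        for p in (
            self.truncation_prob, self.novel_junction_rate,
            self.unassigned_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.pair_theta <= 0:
            raise ValueError("pair_theta must be > 0")
        for lo, hi in (self.exons_per_gene, self.exon_length,
                       self.intron_length, self.ir_intron_length):
            if lo > hi or lo <= 0:
                raise ValueError("infeasible length range")

    @property
    def neuron_types(self) -> list[str]:
        return [n for n, (_, c) in self.cell_types.items() if c == "neuron"]

    @property
    def progenitor_types(self) -> list[str]:
        return [n for n, (_, c) in self.cell_types.items() if c == "progenitor"]

    @property
    def n_genes(self) -> int:
        return (self.n_dse_genes + self.n_null_genes + self.n_pair_genes
                + self.n_indep_pair_genes + self.n_ir_genes
                + self.n_background_genes)


def small_config(seed: int = 0) -> SimConfig:
    """Scaled-down conditions for quick smoke/determinism runs."""
    return SimConfig(
        seed=seed,
        n_dse_genes=4, reads_per_dse_gene=600,
        n_null_genes=6, reads_per_null_gene=200,
        n_pair_genes=3, reads_per_pair_gene=300,
        n_indep_pair_genes=3, reads_per_indep_pair_gene=300,
        n_ir_genes=4, reads_per_ir_gene=260,
        n_background_genes=6, reads_per_background_gene=60,
    )


def feature_study_config(seed: int = 0) -> SimConfig:
    """Conditions for the intron-feature recovery study (annotation only)."""
    return SimConfig(
        seed=seed,
        n_dse_genes=0, n_null_genes=0, n_pair_genes=0, n_indep_pair_genes=0,
        n_ir_genes=15, reads_per_ir_gene=0,
        n_background_genes=25, reads_per_background_gene=0,
    )


def noiseless_config(seed: int = 0) -> SimConfig:
    """Error-free reads drawn from annotated transcripts only."""
    cfg = small_config(seed)
    return replace(cfg, truncation_prob=0.0, novel_junction_rate=0.0)


# ---------------------------------------------------------------------------
# joint inclusion copula
# ---------------------------------------------------------------------------

def joint_inclusion_p11(p_a: float, p_b: float, theta: float) -> float:
    """Joint inclusion probability with marginals ``p_a, p_b`` and odds
    ratio ``theta``: solves p11(1-pA-pB+p11) = theta (pA-p11)(pB-p11)
    inside the Frechet bounds."""
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise ValueError("marginals must lie strictly in (0, 1)")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if math.isclose(theta, 1.0):
        return p_a * p_b
    a = 1.0 - theta
    b = (1.0 - p_a - p_b) + theta * (p_a + p_b)
    c = -theta * p_a * p_b
    disc = b * b - 4 * a * c
    assert disc >= 0, "no real root for joint inclusion probability"
    r1 = (-b + math.sqrt(disc)) / (2 * a)
    r2 = (-b - math.sqrt(disc)) / (2 * a)
    lo = max(0.0, p_a + p_b - 1.0)
    hi = min(p_a, p_b)
    for r in (r1, r2):
        if lo - 1e-12 <= r <= hi + 1e-12:
            return min(max(r, lo), hi)
    raise AssertionError("no joint probability root inside Frechet bounds")


def sample_joint_inclusion(
    p_a: float, p_b: float, theta: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` (in_a, in_b) indicator pairs at the target odds ratio."""
    p11 = joint_inclusion_p11(p_a, p_b, theta)
    p10 = p_a - p11
    p01 = p_b - p11
    p00 = 1.0 - p11 - p10 - p01
    cats = rng.choice(4, size=n, p=[p11, p10, p01, p00])
    out = np.empty((n, 2), dtype=bool)
    out[:, 0] = (cats == 0) | (cats == 1)
    out[:, 1] = (cats == 0) | (cats == 2)
    return out


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

@dataclass
class GenePlan:
    gene_id: str
    role: str  # dse | null | pair | indep_pair | ir | background
    chrom: str
    strand: str
    exons: tuple[Interval, ...]  # genomic order
    transcripts: dict[str, tuple[Interval, ...]]
    cassettes: tuple[int, ...] = ()  # genomic exon indices
    ir_intron: Optional[int] = None  # genomic intron index
    psi: Optional[dict[str, float]] = None
    pir: Optional[dict[str, float]] = None
    theta: Optional[float] = None
    reads: int = 0


@dataclass
class SimBuild:
    config: SimConfig
    sequences: dict[str, str]
    annotation: Annotation
    plans: list[GenePlan]
    intron_groups: pd.DataFrame  # all introns with planted feature group


def _random_seq(rng, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _consensus_seq(rng, consensus: str, strength: float,
                   fixed: frozenset[int] = frozenset()) -> str:
    out = []
    for i, base in enumerate(consensus):
        if i in fixed or rng.random() < strength:
            out.append(base)
        else:
            out.append(str(_BASES[rng.integers(4)]))
    return "".join(out)


def _intron_seq(rng, length: int, gc: float, donor_strength: float,
                acceptor_strength: float) -> str:
    """Canonical GT..AG intron with imprinted donor/acceptor windows."""
    assert length >= 30
    donor = "GT" + _consensus_seq(rng, DONOR_INTRON_CONSENSUS[2:], donor_strength)
    tract = []
    for _ in range(18):
        if rng.random() < acceptor_strength:
            tract.append("C" if rng.random() < 0.5 else "T")
        else:
            tract.append(str(_BASES[rng.integers(4)]))
    acceptor = "".join(tract) + "AG"
    body = _random_seq(rng, length - len(donor) - len(acceptor), gc)
    return donor + body + acceptor


def build_genome_and_annotation(cfg: SimConfig) -> SimBuild:
    """Deterministically build the genome, annotation and gene plans."""
    rng = np.random.default_rng(cfg.seed)
    roles = (
        ["dse"] * cfg.n_dse_genes
        + ["null"] * cfg.n_null_genes
        + ["pair"] * cfg.n_pair_genes
        + ["indep_pair"] * cfg.n_indep_pair_genes
        + ["ir"] * cfg.n_ir_genes
        + ["background"] * cfg.n_background_genes
    )
    cell_names = list(cfg.cell_types)
    neurons = set(cfg.neuron_types)
    progenitors = set(cfg.progenitor_types)

    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_seqs: dict[str, list[str]] = {c: [] for c in chrom_names}
    cursors: dict[str, int] = {c: 0 for c in chrom_names}
    for chrom in chrom_names:
        pad = _random_seq(rng, cfg.intergenic_gap, cfg.base_gc)
        chrom_seqs[chrom].append(pad)
        cursors[chrom] += len(pad)

    plans: list[GenePlan] = []
    intron_rows = []
    for gi, role in enumerate(roles):
        gene_id = f"G{gi + 1:04d}"
        chrom = chrom_names[gi % cfg.n_chroms]
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = cfg.exons_per_gene
        min_exons = 6 if role in ("pair", "indep_pair") else 4
        n_exons = int(rng.integers(max(lo, min_exons), hi + 1))
        exon_lens = rng.integers(
            cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_exons - 1
        )
        intron_gc = [cfg.base_gc] * (n_exons - 1)
        intron_donor = [cfg.donor_strength] * (n_exons - 1)
        planted_intron: Optional[int] = None
        if role == "ir":
            # planted retained intron: shorter, GC-richer, weaker donor
            planted_intron = int(rng.integers(1, n_exons - 2))
            intron_lens[planted_intron] = rng.integers(
                cfg.ir_intron_length[0], cfg.ir_intron_length[1] + 1
            )
            intron_gc[planted_intron] = cfg.ir_intron_gc
            if cfg.ir_weak_donor:
                intron_donor[planted_intron] = cfg.weak_donor_strength

        # transcription-space assembly
        exon_seqs = [
            _random_seq(rng, int(n), cfg.exon_gc) for n in exon_lens
        ]
        intron_seqs = [
            _intron_seq(rng, int(intron_lens[i]), intron_gc[i],
                        intron_donor[i], cfg.acceptor_strength)
            for i in range(n_exons - 1)
        ]
        # imprint exonic halves of the splice-site windows
        for i in range(n_exons - 1):
            don_ex = _consensus_seq(
                rng, DONOR_EXON_CONSENSUS, intron_donor[i]
            )
            exon_seqs[i] = exon_seqs[i][:-3] + don_ex
            acc_ex = _consensus_seq(
                rng, ACCEPTOR_EXON_CONSENSUS, cfg.acceptor_strength
            )
            exon_seqs[i + 1] = acc_ex + exon_seqs[i + 1][3:]

        t_parts, t_exons, pos = [], [], 0
        for i in range(n_exons):
            t_parts.append(exon_seqs[i])
            t_exons.append((pos, pos + len(exon_seqs[i])))
            pos += len(exon_seqs[i])
            if i < n_exons - 1:
                t_parts.append(intron_seqs[i])
                pos += len(intron_seqs[i])
        t_seq = "".join(t_parts)
        gene_len = len(t_seq)
        gene_start = cursors[chrom]
        if strand == "+":
            g_seq = t_seq
            g_exons = [(gene_start + s, gene_start + e) for s, e in t_exons]
        else:
            g_seq = _revcomp(t_seq)
            g_exons = [
                (gene_start + gene_len - e, gene_start + gene_len - s)
                for s, e in t_exons
            ]
            g_exons.reverse()
        g_exons = tuple(g_exons)
        chrom_seqs[chrom].append(g_seq)
        cursors[chrom] += gene_len
        pad = _random_seq(rng, cfg.intergenic_gap, cfg.base_gc)
        chrom_seqs[chrom].append(pad)
        cursors[chrom] += len(pad)

        # genomic index of the planted intron (introns are between
        # genomically consecutive exons)
        ir_genomic = None
        if planted_intron is not None:
            ir_genomic = (
                planted_intron if strand == "+"
                else n_exons - 2 - planted_intron
            )

        # role structure: cassettes as genomic exon indices
        internal = list(range(1, n_exons - 1))
        cassettes: tuple[int, ...] = ()
        if role in ("dse", "null"):
            cassettes = (int(rng.choice(internal)),)
        elif role in ("pair", "indep_pair"):
            # non-adjacent cassettes keep every combination isoform's
            # flanking junctions unambiguous for both exons
            candidates = [
                (i, j)
                for i in internal for j in internal
                if j >= i + 2
            ]
            pick = candidates[int(rng.integers(len(candidates)))]
            cassettes = (pick[0], pick[1])

        transcripts: dict[str, tuple[Interval, ...]] = {"full": g_exons}
        if role in ("dse", "null"):
            (c,) = cassettes
            transcripts["skip"] = tuple(
                e for i, e in enumerate(g_exons) if i != c
            )
        elif role in ("pair", "indep_pair"):
            ca, cb = cassettes
            transcripts["skip_a"] = tuple(
                e for i, e in enumerate(g_exons) if i != ca
            )
            transcripts["skip_b"] = tuple(
                e for i, e in enumerate(g_exons) if i != cb
            )
            transcripts["skip_ab"] = tuple(
                e for i, e in enumerate(g_exons) if i not in (ca, cb)
            )
        elif role == "ir":
            k = ir_genomic
            merged = (g_exons[k][0], g_exons[k + 1][1])
            transcripts["retained"] = (
                g_exons[:k] + (merged,) + g_exons[k + 2:]
            )

        psi = pir = None
        theta = None
        if role == "dse":
            psi = {
                ct: (cfg.dse_psi_neuron if ct in neurons
                     else cfg.dse_psi_progenitor if ct in progenitors
                     else cfg.dse_psi_other)
                for ct in cell_names
            }
        elif role == "null":
            psi = {ct: cfg.null_psi for ct in cell_names}
        elif role in ("pair", "indep_pair"):
            psi = {ct: cfg.pair_marginal for ct in cell_names}
            theta = cfg.pair_theta if role == "pair" else 1.0
        elif role == "ir":
            pir = {
                ct: (cfg.ir_pir_neuron if ct in neurons
                     else cfg.ir_pir_progenitor if ct in progenitors
                     else cfg.ir_pir_other)
                for ct in cell_names
            }

        reads = {
            "dse": cfg.reads_per_dse_gene,
            "null": cfg.reads_per_null_gene,
            "pair": cfg.reads_per_pair_gene,
            "indep_pair": cfg.reads_per_indep_pair_gene,
            "ir": cfg.reads_per_ir_gene,
            "background": cfg.reads_per_background_gene,
        }[role]

        plans.append(
            GenePlan(
                gene_id=gene_id, role=role, chrom=chrom, strand=strand,
                exons=g_exons, transcripts=transcripts, cassettes=cassettes,
                ir_intron=ir_genomic, psi=psi, pir=pir, theta=theta,
                reads=reads,
            )
        )
        for i in range(n_exons - 1):
            l = g_exons[i][1]
            r = g_exons[i + 1][0]
            group = (
                "retained_in_neuron"
                if ir_genomic is not None and i == ir_genomic
                else "control"
            )
            intron_rows.append(
                {"gene_id": gene_id, "chrom": chrom, "start": l, "end": r,
                 "strand": strand, "group": group}
            )

    sequences = {c: "".join(parts) for c, parts in chrom_seqs.items()}
    tx_objects = []
    for plan in plans:
        for name in sorted(plan.transcripts):
            tx_objects.append(
                Transcript(
                    transcript_id=f"{plan.gene_id}.{name}",
                    gene_id=plan.gene_id,
                    chrom=plan.chrom,
                    strand=plan.strand,
                    exons=plan.transcripts[name],
                )
            )
    annotation = Annotation(tx_objects)
    intron_groups = pd.DataFrame(
        intron_rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "group"],
    )
    return SimBuild(cfg, sequences, annotation, plans, intron_groups)


# ---------------------------------------------------------------------------
# read generation
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Planted parameters and expected calls for every simulated event."""

    dse: pd.DataFrame
    pairs: pd.DataFrame
    ir: pd.DataFrame
    intron_groups: pd.DataFrame

    def write(self, outdir: str) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.dse.to_csv(out / "truth_dse.tsv", sep="\t", index=False)
        self.pairs.to_csv(out / "truth_pairs.tsv", sep="\t", index=False)
        self.ir.to_csv(out / "truth_ir.tsv", sep="\t", index=False)
        self.intron_groups.to_csv(
            out / "truth_introns.tsv", sep="\t", index=False
        )


def _se_truth_coords(plan: GenePlan, cassette_idx: int):
    """Cassette interval and flanking skip junction in genomic coords."""
    exons = plan.exons
    b, c = exons[cassette_idx]
    a = exons[cassette_idx - 1][1]
    d = exons[cassette_idx + 1][0]
    return (b, c), (a, d)


def _truncate_blocks(blocks: list[Interval], strand: str, k: int) -> list[Interval]:
    """Drop ``k`` blocks from the read's 5' end (strand-aware)."""
    return blocks[k:] if strand == "+" else blocks[: len(blocks) - k]


def generate_reads(cfg: SimConfig, build: SimBuild):
    """Sample reads for every gene plan.

    Returns ``(records, barcode_map, truth)`` where records is a list of
    ``(qname, chrom, strand, blocks, barcode)`` tuples ready for SAM
    serialization.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    cell_names = list(cfg.cell_types)
    props = np.array([cfg.cell_types[n][0] for n in cell_names])

    barcodes: dict[str, list[str]] = {}
    seen: set[str] = set()
    bc_rows = []
    for ct in cell_names:
        pool = []
        while len(pool) < cfg.barcodes_per_type:
            bc = "".join(_BASES[rng.integers(4, size=cfg.barcode_length)])
            if bc not in seen:
                seen.add(bc)
                pool.append(bc)
                bc_rows.append((bc, ct, cfg.cell_types[ct][1]))
        barcodes[ct] = pool
    barcode_map = pd.DataFrame(bc_rows, columns=["barcode", "cell_type", "class"])

    records = []
    dse_rows, pair_rows, ir_rows = [], [], []
    counter = 0
    for plan in build.plans:
        gene_sites = set()
        for s, e in plan.exons:
            gene_sites.add(s)
            gene_sites.add(e)
        p11 = None
        if plan.theta is not None:
            p11 = joint_inclusion_p11(
                cfg.pair_marginal, cfg.pair_marginal, plan.theta
            )
            p10 = cfg.pair_marginal - p11
            p01 = cfg.pair_marginal - p11
            p00 = 1.0 - p11 - p10 - p01
        cts = rng.choice(len(cell_names), size=plan.reads, p=props)
        for ct_idx in cts:
            ct = cell_names[ct_idx]
            if plan.role in ("dse", "null"):
                tx = "full" if rng.random() < plan.psi[ct] else "skip"
            elif plan.role in ("pair", "indep_pair"):
                cat = rng.choice(4, p=[p11, p10, p01, p00])
                tx = ("full", "skip_b", "skip_a", "skip_ab")[cat]
            elif plan.role == "ir":
                tx = "retained" if rng.random() < plan.pir[ct] else "full"
            else:
                tx = "full"
            blocks = list(plan.transcripts[tx])
            if (
                cfg.truncation_prob > 0
                and len(blocks) > 1
                and rng.random() < cfg.truncation_prob
            ):
                k = int(rng.integers(1, len(blocks)))
                blocks = _truncate_blocks(blocks, plan.strand, k)
            if (
                cfg.novel_junction_rate > 0
                and len(blocks) > 1
                and rng.random() < cfg.novel_junction_rate
            ):
                j = int(rng.integers(0, len(blocks) - 1))
                delta = int(rng.integers(4, 13))
                if plan.strand == "+":
                    s, e = blocks[j]
                    if e - delta - s > 20 and (e - delta) not in gene_sites:
                        blocks[j] = (s, e - delta)
                else:
                    s, e = blocks[j + 1]
                    if e - (s + delta) > 20 and (s + delta) not in gene_sites:
                        blocks[j + 1] = (s + delta, e)
            if rng.random() < cfg.unassigned_fraction:
                barcode = None
            else:
                barcode = barcodes[ct][int(rng.integers(len(barcodes[ct])))]
            counter += 1
            records.append(
                (f"r{counter:07d}", plan.chrom, plan.strand,
                 tuple(blocks), barcode)
            )

        # truth rows
        if plan.role in ("dse", "null"):
            (b, c), (a, d) = _se_truth_coords(plan, plan.cassettes[0])
            row = {
                "gene_id": plan.gene_id, "role": plan.role,
                "chrom": plan.chrom, "strand": plan.strand,
                "cassette_start": b, "cassette_end": c,
                "skip_left": a, "skip_right": d,
                "event_id": f"SE:{plan.chrom}:{b}-{c}:{a}-{d}",
                "expected_significant": plan.role == "dse",
            }
            for ct in cell_names:
                row[f"psi_{ct}"] = plan.psi[ct]
            dse_rows.append(row)
        elif plan.role in ("pair", "indep_pair"):
            (ba, ca), (aa, da) = _se_truth_coords(plan, plan.cassettes[0])
            (bb, cb), (ab, db) = _se_truth_coords(plan, plan.cassettes[1])
            pair_rows.append(
                {
                    "gene_id": plan.gene_id, "role": plan.role,
                    "chrom": plan.chrom, "strand": plan.strand,
                    "event_a": f"SE:{plan.chrom}:{ba}-{ca}:{aa}-{da}",
                    "event_b": f"SE:{plan.chrom}:{bb}-{cb}:{ab}-{db}",
                    "theta": plan.theta,
                    "expected_class": (
                        "mutually_inclusive" if plan.theta > 1 else "none"
                    ),
                }
            )
        elif plan.role == "ir":
            k = plan.ir_intron
            l = plan.exons[k][1]
            r = plan.exons[k + 1][0]
            row = {
                "gene_id": plan.gene_id, "chrom": plan.chrom,
                "strand": plan.strand, "intron_start": l, "intron_end": r,
                "event_id": f"IR:{plan.chrom}:{l}-{r}",
                "gc_target": cfg.ir_intron_gc,
                "weak_donor": cfg.ir_weak_donor,
                "expected_significant": True,
            }
            for ct in cell_names:
                row[f"pir_{ct}"] = plan.pir[ct]
            ir_rows.append(row)

    truth = TruthSet(
        dse=pd.DataFrame(dse_rows),
        pairs=pd.DataFrame(pair_rows),
        ir=pd.DataFrame(ir_rows),
        intron_groups=build.intron_groups,
    )
    return records, barcode_map, truth


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sequences:
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_sam(
    records,
    sequences: dict[str, str],
    path: str,
    barcode_tag: str = "CB",
) -> None:
    """Write read records as a coordinate-sorted SAM with known CIGARs."""
    import pysam

    chroms = list(sequences)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(sequences[c])} for c in chroms],
    }
    chrom_index = {c: i for i, c in enumerate(chroms)}
    ordered = sorted(
        records, key=lambda r: (chrom_index[r[1]], r[3][0][0], r[0])
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for qname, chrom, strand, blocks, barcode in ordered:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = qname
            rec.flag = 16 if strand == "-" else 0
            rec.reference_id = chrom_index[chrom]
            rec.reference_start = blocks[0][0]
            rec.mapping_quality = 60
            cigar = []
            for i, (s, e) in enumerate(blocks):
                if i > 0:
                    cigar.append((3, s - blocks[i - 1][1]))
                cigar.append((0, e - s))
            rec.cigartuples = cigar
            rec.query_sequence = "".join(
                sequences[chrom][s:e] for s, e in blocks
            )
            tags = [("XS", strand)]
            if barcode is not None:
                tags.append((barcode_tag, barcode))
            rec.set_tags(tags)
            out.write(rec)


@dataclass
class SimOutput:
    fasta: str
    gtf: str
    sam: str
    cell_map: str
    truth: TruthSet
    build: SimBuild


def simulate_dataset(cfg: SimConfig, outdir: str) -> SimOutput:
    """Build the genome, sample reads, and write all outputs to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    build = build_genome_and_annotation(cfg)
    records, barcode_map, truth = generate_reads(cfg, build)
    fasta = str(out / "genome.fa")
    gtf = str(out / "annotation.gtf")
    sam = str(out / "reads.sam")
    cell_map = str(out / "cell_map.tsv")
    write_fasta(build.sequences, fasta)
    write_gtf(build.annotation, gtf)
    write_sam(records, build.sequences, sam, barcode_tag=cfg.barcode_tag)
    barcode_map.to_csv(cell_map, sep="\t", index=False, header=False)
    truth.write(str(out / "truth"))
    return SimOutput(fasta, gtf, sam, cell_map, truth, build)
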