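"""Intron characterization: length, GC, conservation, splice-site strength.

Splice-site strength is a position-weight-matrix log-odds score (bits)
over the standard windows: donor -3..+6 (9 nt, 3 exonic + 6 intronic) and
acceptor -20..+3 (23 nt, 20 intronic + 3 exonic).  The PWM is trained from
annotated junctions with +1 pseudocounts against genome-wide background
mononucleotide frequencies; any scorer with the same window contract can
be plugged in instead (e.g. true maximum-entropy tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import Annotation, Interval, ScoreTrack
from .differential import mann_whitney_u

DONOR_LEN = 9  # exon -3..-1 + intron +1..+6
ACCEPTOR_LEN = 23  # intron -20..-1 + exon +1..+3
_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> Optional[float]:
    """(G+C) / non-N length; ``None`` for an all-N sequence."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    n_valid = sum(seq.count(b) for b in _BASES)
    if n_valid == 0:
        return None
    return (seq.count("G") + seq.count("C")) / n_valid


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Extract [start, end) from a pyfaidx.Fasta or a plain dict of strings."""
    if isinstance(genome, Mapping):
        return genome[chrom][start:end].upper()
    return str(genome[chrom][start:end]).upper()


def donor_window(genome, chrom: str, intron: Interval, strand: str) -> str:
    """9-nt donor window in transcription orientation."""
    l, r = intron
    if strand == "+":
        return fetch(genome, chrom, l - 3, l + 6)
    return reverse_complement(fetch(genome, chrom, r - 6, r + 3))


def acceptor_window(genome, chrom: str, intron: Interval, strand: str) -> str:
    """23-nt acceptor window in transcription orientation."""
    l, r = intron
    if strand == "+":
        return fetch(genome, chrom, r - 20, r + 3)
    return reverse_complement(fetch(genome, chrom, l - 3, l + 20))


@dataclass
class SpliceSitePwm:
    """Per-position nucleotide probabilities for donor/acceptor windows."""

    donor: np.ndarray  # (9, 4)
    acceptor: np.ndarray  # (23, 4)
    background: np.ndarray  # (4,)

    def __post_init__(self):
        for mat, n in ((self.donor, DONOR_LEN), (self.acceptor, ACCEPTOR_LEN)):
            if mat.shape != (n, 4):
                raise ValueError("PWM matrix has wrong shape")
            if not np.allclose(mat.sum(axis=1), 1.0):
                raise ValueError("PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must sum to 1")


def _count_matrix(windows: Sequence[str], length: int) -> np.ndarray:
    counts = np.ones((length, 4), dtype=float)  # +1 pseudocount
    for w in windows:
        for i, base in enumerate(w.upper()):
            j = _BASE_INDEX.get(base)
            if j is not None:
                counts[i, j] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def train_pwm(
    annotation: Annotation, genome, min_sites: int = 50
) -> SpliceSitePwm:
    """Train donor/acceptor PWMs from every annotated junction.

    Fails if fewer than ``min_sites`` junctions provide full windows.
    Background is the genome-wide mononucleotide frequency.
    """
    donors, acceptors = [], []
    for gid in sorted(annotation.genes):
        gene = annotation.genes[gid]
        for intron in sorted(annotation.junctions(gid)):
            try:
                d = donor_window(genome, gene.chrom, intron, gene.strand)
                a = acceptor_window(genome, gene.chrom, intron, gene.strand)
            except (KeyError, IndexError):
                continue
            if len(d) == DONOR_LEN and len(a) == ACCEPTOR_LEN:
                donors.append(d)
                acceptors.append(a)
    if len(donors) < min_sites:
        raise ValueError(
            f"too few annotated splice sites to train PWM: {len(donors)} "
            f"< {min_sites}"
        )
    bg = np.zeros(4)
    if isinstance(genome, Mapping):
        chrom_names = sorted(genome)
    else:
        chrom_names = sorted(genome.keys())
    for chrom in chrom_names:
        seq = fetch(genome, chrom, 0, len(genome[chrom]))
        for i, b in enumerate(_BASES):
            bg[i] += seq.count(b)
    bg /= bg.sum()
    return SpliceSitePwm(
        donor=_count_matrix(donors, DONOR_LEN),
        acceptor=_count_matrix(acceptors, ACCEPTOR_LEN),
        background=bg,
    )


def score_site(pwm: SpliceSitePwm, window_seq: str) -> float:
    """Log2-odds score in bits; the window side is inferred from length.

    N bases contribute 0 bits.
    """
    seq = window_seq.upper()
    if len(seq) == DONOR_LEN:
        mat = pwm.donor
    elif len(seq) == ACCEPTOR_LEN:
        mat = pwm.acceptor
    else:
        raise ValueError(
            f"window length {len(seq)} matches neither donor ({DONOR_LEN}) "
            f"nor acceptor ({ACCEPTOR_LEN})"
        )
    score = 0.0
    for i, base in enumerate(seq):
        j = _BASE_INDEX.get(base)
        if j is None:
            continue
        score += np.log2(mat[i, j] / pwm.background[j])
    return float(score)


def mean_conservation(
    track: ScoreTrack, chrom: str, interval: Interval
) -> tuple[Optional[float], float]:
    """Mean track value over covered bases and the covered fraction."""
    return track.mean(chrom, interval[0], interval[1])


def compute_intron_features(
    introns: pd.DataFrame,
    genome,
    pwm: SpliceSitePwm,
    track: Optional[ScoreTrack] = None,
) -> pd.DataFrame:
    """Feature table for introns given as (chrom, start, end, strand[, group]).

    Adds length, GC fraction, donor/acceptor strength (bits) and, when a
    track is supplied, mean conservation with its covered fraction.
    """
    rows = []
    for rec in introns.itertuples(index=False):
        chrom, start, end, strand = rec.chrom, int(rec.start), int(rec.end), rec.strand
        seq = fetch(genome, chrom, start, end)
        d = donor_window(genome, chrom, (start, end), strand)
        a = acceptor_window(genome, chrom, (start, end), strand)
        row = {
            "chrom": chrom,
            "start": start,
            "end": end,
            "strand": strand,
            "length": end - start,
            "gc": gc_content(seq),
            "donor_score": score_site(pwm, d) if len(d) == DONOR_LEN else np.nan,
            "acceptor_score": (
                score_site(pwm, a) if len(a) == ACCEPTOR_LEN else np.nan
            ),
        }
        if track is not None:
            mean, frac = mean_conservation(track, chrom, (start, end))
            row["mean_conservation"] = np.nan if mean is None else mean
            row["covered_fraction"] = frac
        if hasattr(rec, "group"):
            row["group"] = rec.group
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    features: pd.DataFrame,
    feature_name: str,
    group_a: str,
    group_b: str,
    group_col: str = "group",
) -> dict:
    """Two-sided Mann-Whitney comparison of one feature between two groups."""
    xa = features.loc[features[group_col] == group_a, feature_name].dropna()
    xb = features.loc[features[group_col] == group_b, feature_name].dropna()
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty group in feature comparison")
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("need at least 3 introns per group")
    u, p = mann_whitney_u(xa.to_numpy(), xb.to_numpy())
    return {
        "feature": feature_name,
        "group_a": group_a,
        "group_b": group_b,
        "n_a": int(len(xa)),
        "n_b": int(len(xb)),
        "median_a": float(xa.median()),
        "median_b": float(xb.median()),
        "U": u,
        "p": p,
    }
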