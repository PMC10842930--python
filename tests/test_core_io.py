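"""Coordinate conventions, GTF/SAM parsing, cell maps and score tracks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lrsplice.core_io import (
    Annotation,
    ExonChain,
    GtfParseError,
    ScoreTrack,
    Transcript,
    blocks_from_cigar,
    load_cell_map,
    parse_gtf,
    read_alignments,
    to_one_based,
    to_zero_based,
    write_gtf,
)

GTF_ONE_GENE = """\
chrT\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "G1";
chrT\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chrT\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chrT\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
"""


def test_gtf_coordinates_become_half_open(tmp_path):
    """1-based closed exons 101-200 / 301-400 give junction (200, 300)."""
    path = tmp_path / "one.gtf"
    path.write_text(GTF_ONE_GENE)
    ann = parse_gtf(str(path))
    tr = ann.transcripts["T1"]
    assert tr.exons == ((100, 200), (300, 400))
    assert tr.junctions == ((200, 300),)
    assert ann.donor_sites("G1") == {200}
    assert ann.acceptor_sites("G1") == {300}


def test_coordinate_conversion_involution():
    for s, e in [(0, 1), (99, 200), (12345, 67890)]:
        assert to_zero_based(*to_one_based(s, e)) == (s, e)


def test_gene_site_sets_are_transcript_union(toy_annotation):
    """Gene donors/acceptors are the union over its transcripts."""
    ann = toy_annotation
    assert ann.donor_sites("GENE1") == {200, 400, 600}
    assert ann.acceptor_sites("GENE1") == {300, 500, 700}
    assert (200, 500) in ann.junctions("GENE1")  # skip form from GENE1.skip
    # minus-strand gene: donor is the right boundary of each intron
    assert ann.donor_sites("GENE2") == {2300, 2500}
    assert ann.acceptor_sites("GENE2") == {2150, 2400}


def test_gtf_out_of_order_exons_are_sorted(tmp_path):
    lines = GTF_ONE_GENE.splitlines()
    lines[2], lines[3] = lines[3], lines[2]  # swap the two exon lines
    path = tmp_path / "perm.gtf"
    path.write_text("\n".join(lines) + "\n")
    ann = parse_gtf(str(path))
    assert ann.transcripts["T1"].exons == ((100, 200), (300, 400))


def test_malformed_gtf_names_line_number(tmp_path):
    path = tmp_path / "bad.gtf"
    path.write_text(GTF_ONE_GENE + "chrT\tonly_three\tfields\n")
    with pytest.raises(GtfParseError, match="line 5"):
        parse_gtf(str(path))


def test_transcript_without_exons_rejected(tmp_path):
    path = tmp_path / "empty_tx.gtf"
    path.write_text(
        GTF_ONE_GENE
        + 'chrT\tsrc\ttranscript\t500\t600\t.\t+\t.\t'
        'gene_id "G1"; transcript_id "T_EMPTY";\n'
    )
    with pytest.raises(GtfParseError, match="T_EMPTY"):
        parse_gtf(str(path))


def test_gtf_round_trip_preserves_sites(toy_annotation, tmp_path):
    path = tmp_path / "rt.gtf"
    write_gtf(toy_annotation, str(path))
    back = parse_gtf(str(path))
    for gid in toy_annotation.genes:
        assert back.junctions(gid) == toy_annotation.junctions(gid)
        assert back.donor_sites(gid) == toy_annotation.donor_sites(gid)
        assert back.acceptor_sites(gid) == toy_annotation.acceptor_sites(gid)


# -- CIGAR -> blocks --------------------------------------------------------

@pytest.mark.parametrize(
    "pos,cigar,expected",
    [
        # 100M200N100M at 1-based pos 1001 (= reference_start 1000)
        (1000, [(0, 100), (3, 200), (0, 100)], ((1000, 1100), (1300, 1400))),
        # deletions extend the reference span of a single block
        (0, [(0, 50), (2, 10), (0, 50)], ((0, 110),)),
        # soft clips and insertions do not consume reference
        (10, [(4, 5), (0, 20), (1, 3), (0, 10)], ((10, 40),)),
    ],
)
def test_blocks_from_cigar(pos, cigar, expected):
    assert blocks_from_cigar(pos, cigar) == expected


@settings(max_examples=100, derandomize=True)
@given(
    pos=st.integers(min_value=0, max_value=10_000),
    ops=st.lists(
        st.tuples(st.sampled_from([0, 1, 2, 3, 4, 7, 8]),
                  st.integers(min_value=1, max_value=500)),
        min_size=1, max_size=12,
    ),
)
def test_reference_span_matches_cigar_arithmetic(pos, ops):
    """Reconstructed span equals POS + total reference-consuming length."""
    # normalize: must start/end with an aligned block for a valid chain
    ops = [(0, 10)] + ops + [(0, 10)]
    blocks = blocks_from_cigar(pos, ops)
    ref_len = sum(n for op, n in ops if op in (0, 2, 3, 7, 8))
    assert blocks[0][0] == pos
    assert blocks[-1][1] == pos + ref_len
    # blocks disjoint and sorted; junction count = blocks - 1
    chain = ExonChain("q", "c", "+", blocks)
    assert len(chain.junctions) == len(blocks) - 1


SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chrT\tLN:100000\n"


def _sam_line(qname, flag, pos_1based, cigar, tags=""):
    return (f"{qname}\t{flag}\tchrT\t{pos_1based}\t60\t{cigar}\t*\t0\t0\t"
            f"*\t*{tags}\n")


def test_read_alignments_counts_skips(tmp_path):
    """8 mapped + 2 unmapped records give 8 chains and skip count 2."""
    path = tmp_path / "mix.sam"
    lines = [SAM_HEADER]
    for i in range(8):
        tag = "\tCB:Z:AAAA" if i % 2 == 0 else ""
        lines.append(_sam_line(f"r{i}", 0, 1001 + i, "100M200N100M", tag))
    for i in range(2):
        lines.append(f"u{i}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
    path.write_text("".join(lines))
    stats = {}
    chains = list(read_alignments(str(path), stats=stats))
    assert len(chains) == 8
    assert stats["unmapped"] == 2
    assert chains[0].blocks == ((1000, 1100), (1300, 1400))
    assert chains[0].cell_barcode == "AAAA"
    assert chains[1].cell_barcode is None


def test_exon_chain_invariants():
    with pytest.raises(ValueError):
        ExonChain("bad", "c", "+", ((0, 100), (50, 200)))


# -- cell map ---------------------------------------------------------------

def test_load_cell_map_basic(tmp_path):
    path = tmp_path / "map.tsv"
    path.write_text("AC\tExN\tneuron\nGT\tNPC\tprogenitor\nTT\tOPC\tglia\n")
    cmap = load_cell_map(str(path))
    assert len(cmap.barcode_to_type) == 3
    assert cmap.type_of("AC") == "ExN"
    assert cmap.class_of("GT") == "progenitor"
    assert cmap.types_in_class("neuron") == ["ExN"]
    assert cmap.type_to_class()["OPC"] == "glia"


def test_load_cell_map_duplicate_barcode(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text("AC\tExN\nAC\tNPC\n")
    with pytest.raises(ValueError, match="AC"):
        load_cell_map(str(path))


def test_load_cell_map_empty_file(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text("")
    with pytest.raises(Exception):
        load_cell_map(str(path))


# -- score track ------------------------------------------------------------

def test_score_track_means(tmp_path):
    path = tmp_path / "track.bedgraph"
    path.write_text(
        "chrT\t0\t100\t0.8\n"
        "chrT\t100\t150\t1.0\n"
        "chrT\t200\t250\t0.0\n"
    )
    track = ScoreTrack.from_bedgraph(str(path))
    mean, frac = track.mean("chrT", 0, 100)
    assert mean == pytest.approx(0.8)
    assert frac == 1.0
    # half covered at 1.0, half at 0.0 -> 0.5
    mean, frac = track.mean("chrT", 100, 250)
    assert mean == pytest.approx(50 * 1.0 / 100)
    assert frac == pytest.approx(100 / 150)
    # uncovered interval
    mean, frac = track.mean("chrT", 300, 400)
    assert mean is None and frac == 0.0


def test_score_track_sparse_oracle(tmp_path):
    """Interval-mean equals a direct per-base sum."""
    rng = np.random.default_rng(5)
    rows, base_vals = [], {}
    pos = 0
    for _ in range(30):
        pos += int(rng.integers(1, 20))
        length = int(rng.integers(1, 15))
        val = float(np.round(rng.random(), 3))
        rows.append(f"chrT\t{pos}\t{pos + length}\t{val}")
        for p in range(pos, pos + length):
            base_vals[p] = val
        pos += length
    path = tmp_path / "sparse.bedgraph"
    path.write_text("\n".join(rows) + "\n")
    track = ScoreTrack.from_bedgraph(str(path))
    for start, end in [(0, 50), (37, 201), (100, 400), (0, pos)]:
        covered = [base_vals[p] for p in range(start, end) if p in base_vals]
        mean, frac = track.mean("chrT", start, end)
        if covered:
            assert mean == pytest.approx(np.mean(covered))
            assert frac == pytest.approx(len(covered) / (end - start))
        else:
            assert mean is None
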