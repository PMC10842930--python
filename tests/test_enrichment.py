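"""Gene-set, disease-exon and DNM enrichment; delta-PSI concordance."""

import math

import numpy as np
import pandas as pd
import pytest

from lrsplice.core_io import Annotation, Transcript
from lrsplice.enrichment import (
    delta_psi_concordance,
    dnm_region_enrichment,
    exon_overlap_enrichment,
    expand_regions,
    filter_splice_dnms,
    gene_set_enrichment,
    load_gene_sets,
)


# -- gene sets --------------------------------------------------------------

def test_gene_set_full_overlap_infinite_or():
    genes = [f"g{i}" for i in range(100)]
    res = gene_set_enrichment(genes[:10], genes[:10], genes)
    assert math.isinf(res.odds_ratio)
    assert res.table[0] == (10, 0)


def test_gene_set_disjoint_zero_or():
    genes = [f"g{i}" for i in range(100)]
    res = gene_set_enrichment(genes[:10], genes[50:60], genes)
    assert res.odds_ratio == 0.0


def test_gene_set_cross_product_oracle():
    """fg=20 of 200, target=50, overlap=10: table (10,10,40,140), OR 3.5."""
    universe = [f"g{i}" for i in range(200)]
    fg = universe[:20]
    target = universe[:10] + universe[20:60]
    res = gene_set_enrichment(fg, target, universe)
    assert res.table == ((10, 10), (40, 140))
    assert res.odds_ratio == pytest.approx(10 * 140 / (10 * 40))
    assert res.log2_or == pytest.approx(math.log2(3.5))


def test_gene_set_foreground_outside_universe_errors():
    with pytest.raises(ValueError, match="gX"):
        gene_set_enrichment(["g1", "gX"], ["g1"], ["g1", "g2"])


def test_gene_set_order_invariance():
    universe = [f"g{i}" for i in range(50)]
    fg, tg = universe[:10], universe[5:20]
    a = gene_set_enrichment(fg, tg, universe)
    rng = np.random.default_rng(0)
    b = gene_set_enrichment(
        list(rng.permutation(fg)), list(rng.permutation(tg)),
        list(rng.permutation(universe)),
    )
    assert a.table == b.table and a.p == b.p


def test_load_gene_sets_dedup(tmp_path):
    path = tmp_path / "sets.tsv"
    path.write_text("S1\tg1\nS1\tg1\nS1\tg2\nS2\tg3\n")
    sets = load_gene_sets(str(path))
    assert sets["S1"] == {"g1", "g2"}
    assert sets["S2"] == {"g3"}


# -- exon overlap -----------------------------------------------------------

def test_exon_overlap_planted_table():
    """10 DSEs / 90 background with overlaps 6 and 9: OR = 13.5."""
    disease = [("c1", i * 1000, i * 1000 + 100) for i in range(50)]
    dse = [("c1", i * 1000 + 50, i * 1000 + 150) for i in range(6)]
    dse += [("c2", i * 1000, i * 1000 + 100) for i in range(4)]
    bg = [("c1", i * 1000 + 50, i * 1000 + 150) for i in range(6, 15)]
    bg += [("c2", i * 1000, i * 1000 + 100) for i in range(10, 91)]
    res = exon_overlap_enrichment(dse, bg, disease)
    assert res.table == ((6, 4), (9, 81))
    assert res.odds_ratio == pytest.approx(13.5)


def test_exon_overlap_requires_background():
    with pytest.raises(ValueError):
        exon_overlap_enrichment([("c1", 0, 10)], [], [("c1", 0, 10)])


def test_exon_overlap_one_bp_rule():
    disease = [("c1", 100, 200)]
    touching = [("c1", 199, 300)]  # one shared base
    adjacent = [("c1", 200, 300)]  # half-open: no shared base
    res = exon_overlap_enrichment(touching, adjacent, disease)
    assert res.table == ((1, 0), (0, 1))


# -- DNMs -------------------------------------------------------------------

def _dnms(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "group"])
    df["ref"], df["alt"], df["score"] = "A", "C", np.nan
    return df


def test_dnm_half_open_containment():
    regions = [("c1", 100, 200)]
    dnms = _dnms([
        ("c1", 100, "proband"),   # at start: inside
        ("c1", 200, "proband"),   # at end coordinate: outside
        ("c1", 150, "sibling"),
    ])
    res = dnm_region_enrichment(dnms, regions)
    assert res.table == ((1, 1), (1, 0))


def test_dnm_cross_product_oracle():
    """9/1000 vs 1/1000 inside: OR about 9.07, log2 about 3.18."""
    regions = [("c1", 0, 1000)]
    rows = [("c1", 5 + i, "proband") for i in range(9)]
    rows += [("c2", 5 + i, "proband") for i in range(991)]
    rows += [("c1", 500, "sibling")]
    rows += [("c2", 600 + i, "sibling") for i in range(999)]
    res = dnm_region_enrichment(_dnms(rows), regions)
    assert res.table == ((9, 991), (1, 999))
    assert res.odds_ratio == pytest.approx(9 * 999 / 991, rel=1e-9)
    assert res.log2_or == pytest.approx(math.log2(9 * 999 / 991), abs=1e-3)


def test_dnm_totals_conserved():
    rng = np.random.default_rng(3)
    rows = [("c1", int(p), g)
            for p, g in zip(rng.integers(0, 5000, 300),
                            rng.choice(["proband", "sibling"], 300))]
    dnms = _dnms(rows)
    res = dnm_region_enrichment(dnms, [("c1", 1000, 2000)])
    (a, b), (c, d) = res.table
    assert a + b == (dnms["group"] == "proband").sum()
    assert c + d == (dnms["group"] == "sibling").sum()


def test_dnm_empty_group_errors():
    with pytest.raises(ValueError, match="sibling"):
        dnm_region_enrichment(
            _dnms([("c1", 5, "proband")]), [("c1", 0, 10)]
        )


def test_dnm_permutation_destroys_enrichment():
    """Random group relabeling gives mean log2(OR) within +-0.2 of 0."""
    rng = np.random.default_rng(4)
    # planted: probands concentrated inside the region
    rows = [("c1", int(rng.integers(100, 200)), "proband") for _ in range(40)]
    rows += [("c1", int(rng.integers(1000, 9000)), "proband")
             for _ in range(60)]
    rows += [("c1", int(rng.integers(100, 200)), "sibling") for _ in range(5)]
    rows += [("c1", int(rng.integers(1000, 9000)), "sibling")
             for _ in range(95)]
    dnms = _dnms(rows)
    regions = [("c1", 100, 200)]
    planted = dnm_region_enrichment(dnms, regions).log2_or
    assert planted > 1.0
    log_ors = []
    labels = dnms["group"].to_numpy().copy()
    for _ in range(200):
        perm = dnms.copy()
        perm["group"] = rng.permutation(labels)
        log_ors.append(dnm_region_enrichment(perm, regions).log2_or)
    finite = [v for v in log_ors if math.isfinite(v)]
    assert abs(np.mean(finite)) <= 0.2


# -- flank expansion and splice-DNM filter ----------------------------------

@pytest.fixture
def flank_annotation():
    tx = Transcript(
        "T", "G", "c1", "+", ((1000, 1200), (2000, 2100), (3000, 3200)),
    )
    return Annotation([tx])


def test_expand_regions_clipped_at_neighbor_exons(flank_annotation):
    # cassette exon 2000-2100; 300-bp flanks would reach 1700/2400 but the
    # neighbouring exon boundaries are 1200 and 3000 (no clipping needed)
    out = expand_regions([("c1", 2000, 2100)], 300, flank_annotation)
    assert out == [("c1", 1700, 2400)]
    # a 900-bp flank crosses both neighbours and is clipped there
    out = expand_regions([("c1", 2000, 2100)], 900, flank_annotation)
    assert out == [("c1", 1200, 3000)]


def test_filter_splice_dnms_rules(flank_annotation):
    rows = []
    # 4 satisfying: score > 0.2 and within 400 bp of an exon boundary
    for i, pos in enumerate((1200, 1599, 2050, 2900)):
        rows.append(("c1", pos, "proband", 0.5))
    rows.append(("c1", 1200, "proband", 0.2))    # score not strictly > 0.2
    rows.append(("c1", 3601, "proband", 0.9))    # 401 bp from boundary 3200
    rows.append(("c1", 5000, "proband", 0.9))    # far from any boundary
    rows.append(("c1", 1200, "proband", np.nan))  # unscored: counted
    rows.append(("c1", 1200, "proband", 0.1))
    rows.append(("c1", 9000, "proband", 0.05))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "group", "score"])
    df["ref"], df["alt"] = "A", "C"
    kept, n_unscored = filter_splice_dnms(df, flank_annotation)
    assert len(kept) == 4
    assert n_unscored == 1
    assert set(kept["pos"]) == {1200, 1599, 2050, 2900}


# -- concordance ------------------------------------------------------------

def test_concordance_exact_lines():
    d1 = np.array([0.3, -0.2, 0.5, -0.4])
    res = delta_psi_concordance(d1, -d1)
    assert res["r"] == pytest.approx(-1.0)
    assert res["concordance"] == 0.0
    res2 = delta_psi_concordance(d1, d1)
    assert res2["r"] == pytest.approx(1.0)
    assert res2["concordance"] == 1.0


def test_concordance_matches_reported_fraction():
    """160 concordant of 165 matched pairs is 97.0%."""
    rng = np.random.default_rng(5)
    d1 = rng.uniform(0.05, 0.5, size=165) * rng.choice([-1, 1], size=165)
    d2 = d1 + rng.normal(0, 0.02, size=165)
    d2[:5] = -d1[:5]  # five discordant pairs
    d2[5:] = np.sign(d1[5:]) * np.abs(d2[5:])
    res = delta_psi_concordance(d1, d2)
    assert res["concordance"] == pytest.approx(160 / 165, abs=1e-9)
    assert res["n"] == 165


def test_concordance_length_mismatch_errors():
    with pytest.raises(ValueError):
        delta_psi_concordance([0.1, 0.2], [0.1, 0.2, 0.3])
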