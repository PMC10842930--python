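import pytest

from lrsplice.core_io import Annotation, Transcript
from lrsplice.pipeline import RunConfig, run_pipeline
from lrsplice.simulate import SimConfig, simulate_dataset, small_config


@pytest.fixture(scope="session")
def toy_annotation():
    """Two-gene annotation: GENE1 (+, cassette exon 2) and GENE2 (-)."""
    t1 = Transcript(
        "GENE1.full", "GENE1", "chrT", "+",
        ((100, 200), (300, 400), (500, 600), (700, 800)),
    )
    t2 = Transcript(
        "GENE1.skip", "GENE1", "chrT", "+",
        ((100, 200), (500, 600), (700, 800)),
    )
    t3 = Transcript(
        "GENE2.full", "GENE2", "chrT", "-",
        ((2000, 2150), (2300, 2400), (2500, 2650)),
    )
    return Annotation([t1, t2, t3])


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim_small")
    return simulate_dataset(small_config(seed=1), str(outdir))


@pytest.fixture(scope="session")
def small_pipeline(small_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipe_small")
    cfg = RunConfig(
        sam=small_sim.sam, gtf=small_sim.gtf, fasta=small_sim.fasta,
        cell_map=small_sim.cell_map, outdir=str(outdir),
    )
    return cfg, run_pipeline(cfg)


@pytest.fixture(scope="session")
def default_sim(tmp_path_factory):
    """The study-condition simulation used by planted-truth recovery tests."""
    outdir = tmp_path_factory.mktemp("sim_default")
    return simulate_dataset(SimConfig(seed=0), str(outdir))


@pytest.fixture(scope="session")
def default_pipeline(default_sim, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipe_default")
    cfg = RunConfig(
        sam=default_sim.sam, gtf=default_sim.gtf, fasta=default_sim.fasta,
        cell_map=default_sim.cell_map, outdir=str(outdir),
    )
    return cfg, run_pipeline(cfg)
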