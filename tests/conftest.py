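"""Session-scoped synthetic scenarios shared across the suite.

Everything is generated at test time from seeded configurations; no data
files ship with the package.
"""

from dataclasses import dataclass

import pytest

from riboforge import fixtures, ribo_io
from riboforge.pipeline import PipelineResult, run_pipeline


@dataclass
class ScenarioFiles:
    scenario: fixtures.Scenario
    manifest: fixtures.TruthManifest
    genome_path: str
    gtf_path: str
    chx_path: str
    ltm_path: str
    ref_path: str
    chx_text: str
    ltm_text: str


def _materialize(cfg, tmpdir, chx_depth, ltm_depth, seed) -> ScenarioFiles:
    sc = fixtures.build_scenario(cfg)
    fasta, gtf, manifest = fixtures.generate_reference(cfg)
    chx = fixtures.simulate_alignments(sc, "CHX", chx_depth, seed + 1)
    ltm = fixtures.simulate_alignments(sc, "LTM", ltm_depth, seed + 2)
    paths = {}
    for name, text in (("genome.fa", fasta), ("annotation.gtf", gtf),
                       ("chx.sam", chx), ("ltm.sam", ltm),
                       ("reference.fa", fixtures.reference_proteome_fasta(sc))):
        p = tmpdir / name
        p.write_text(text)
        paths[name] = str(p)
    return ScenarioFiles(scenario=sc, manifest=manifest,
                         genome_path=paths["genome.fa"],
                         gtf_path=paths["annotation.gtf"],
                         chx_path=paths["chx.sam"], ltm_path=paths["ltm.sam"],
                         ref_path=paths["reference.fa"],
                         chx_text=chx, ltm_text=ltm)


@pytest.fixture(scope="session")
def class_files(tmp_path_factory) -> ScenarioFiles:
    """Classification scenario: one planted proteoform of every category."""
    cfg = fixtures.classification_config(seed=7)
    return _materialize(cfg, tmp_path_factory.mktemp("class"),
                        chx_depth=2000, ltm_depth=200, seed=700)


@pytest.fixture(scope="session")
def class_result(class_files) -> PipelineResult:
    genome = ribo_io.read_genome_fasta(class_files.genome_path)
    tx = ribo_io.read_gtf(class_files.gtf_path)
    return run_pipeline(genome, tx, class_files.chx_path, class_files.ltm_path)


@pytest.fixture(scope="session")
def tis_files(tmp_path_factory) -> ScenarioFiles:
    """50 planted TISs of mixed classes and near-cognate start codons."""
    cfg = fixtures.tis_config(seed=3, n_tis=50)
    return _materialize(cfg, tmp_path_factory.mktemp("tis"),
                        chx_depth=1000, ltm_depth=100, seed=300)


@pytest.fixture(scope="session")
def tis_result(tis_files) -> PipelineResult:
    genome = ribo_io.read_genome_fasta(tis_files.genome_path)
    tx = ribo_io.read_gtf(tis_files.gtf_path)
    return run_pipeline(genome, tx, tis_files.chx_path, tis_files.ltm_path)
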