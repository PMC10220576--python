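import pytest

from mirphase.formats import RunConfig
from mirphase.pipeline import PipelineInputs, run_all
from mirphase.simulate import ADAPTER, simulate_study

TOY_SEED = 0  # the study's fixed default seed


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def toy_study(tmp_path_factory):
    """The default synthetic toy study (seeded, generated once per session)."""
    d = tmp_path_factory.mktemp("toy")
    manifest = simulate_study(d, seed=TOY_SEED, preset="default")
    return d, manifest


@pytest.fixture(scope="session")
def toy_pipeline(toy_study):
    """Full pipeline run on the default toy study."""
    d, manifest = toy_study
    cfg = RunConfig(adapter=ADAPTER, seed=TOY_SEED)
    inputs = PipelineInputs(
        design_path=d / "design.tsv",
        reference_path=d / "reference_mirnas.fa",
        genome_path=d / "genome.fa",
        transcripts_path=d / "transcripts.fa",
        ct_path=d / "ct_table.csv",
    )
    run_manifest = run_all(cfg, inputs, d / "run")
    return d, manifest, run_manifest


@pytest.fixture(scope="session")
def tiny_study(tmp_path_factory):
    d = tmp_path_factory.mktemp("tiny")
    manifest = simulate_study(d, seed=TOY_SEED, preset="tiny")
    return d, manifest
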