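import pytest

from opterm.pipeline import RunConfig, run_pipeline
from opterm.simulate import SimulationConfig, simulate_dataset


def make_config(**overrides) -> SimulationConfig:
    """A small, fast simulation config; overrides applied on top."""
    base = dict(
        seed=1,
        n_operons_by_type={"I": 2, "II": 2, "III": 2, "IV": 2},
        noise="none",
        end_jitter_sd=0.0,
        n_replicates=2,
        gene_length=(500, 800),
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def noise_free_dataset():
    """Small deterministic dataset: (truth, evidence), noise-free."""
    config = make_config()
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def noise_free_run(tmp_path_factory):
    """Full pipeline run on the small noise-free simulation."""
    out = tmp_path_factory.mktemp("noise_free_run")
    config = RunConfig(out_dir=str(out), seed=1, simulation=make_config())
    summary = run_pipeline(config)
    return out, summary
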