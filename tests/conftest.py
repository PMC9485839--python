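import pytest

from sedyn.pipeline import PipelineConfig, run


@pytest.fixture(scope="session")
def noiseless_run(tmp_path_factory):
    """Full pipeline on noiseless synthetic data (every stage exercised)."""
    out = tmp_path_factory.mktemp("noiseless")
    cfg = PipelineConfig(out_dir=str(out), seed=11, sim_replicate_noise_sd=0.0)
    return run(cfg)


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """Full pipeline at the default replicate noise (sigma = 0.3)."""
    out = tmp_path_factory.mktemp("noisy")
    cfg = PipelineConfig(out_dir=str(out), seed=11, sim_replicate_noise_sd=0.3)
    return run(cfg)
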