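import pytest

from taxovoi import (PipelineConfig, SyntheticConfig, generate_archive,
                     run_pipeline)


@pytest.fixture(scope="session")
def default_archive():
    """Full-size synthetic archive (12 eligible orders, fixed seed)."""
    return generate_archive(SyntheticConfig(master_seed=11))


@pytest.fixture(scope="session")
def tiny_archive():
    """Two-order archive, fast enough for per-test reuse."""
    return generate_archive(SyntheticConfig(
        n_orders=2, n_background_orders=1, unobserved_species=3,
        master_seed=7))


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full default pipeline run (simulate -> ... -> report)."""
    outdir = tmp_path_factory.mktemp("pipeline")
    config = PipelineConfig(outdir=str(outdir),
                            synthetic=SyntheticConfig(master_seed=1),
                            master_seed=1)
    return run_pipeline(config)
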