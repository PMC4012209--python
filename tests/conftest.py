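import pytest
from hypothesis import settings

from caslink.pipeline import PipelineConfig, run_pipeline

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")
from caslink.synthetic import SimulationConfig, generate_collection


@pytest.fixture(scope="session")
def small_config():
    """A compact default-shaped collection used across modules."""
    return SimulationConfig(
        seed=7,
        n_genera=4,
        species_per_genus=(1, 2),
        genes_per_replicon=(60, 80),
        protein_length=(80, 150),
    )


@pytest.fixture(scope="session")
def small_collection(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("collection")
    gt = generate_collection(small_config, out)
    return out, gt


@pytest.fixture(scope="session")
def pipeline_run(small_collection, small_config, tmp_path_factory):
    from caslink.neighborhood import NeighborhoodParams

    cdir, gt = small_collection
    out = tmp_path_factory.mktemp("analysis")
    config = PipelineConfig(
        input_dir=cdir,
        output_dir=out,
        neighborhood=NeighborhoodParams(window_k=small_config.window_k),
    )
    report = run_pipeline(config)
    return config, report, gt
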