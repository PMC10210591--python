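import pytest
from hypothesis import HealthCheck, settings

from gliascan import EpitopeCatalog, PipelineParams, SynthConfig, run_pipeline
from gliascan.synthetic_data import generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog() -> EpitopeCatalog:
    return EpitopeCatalog.default()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Error-free desk-scale dataset shared by recovery tests."""
    config = SynthConfig(
        seed=7,
        n_genotypes_per_class={
            "bread_wheat": 2,
            "bread_wheat_translocation": 2,
            "durum": 1,
            "tritordeum": 1,
        },
        panel_size=12,
        reads_per_sample=4000,
        per_base_error=0.0,
    )
    truth, sheet = generate_dataset(config, tmp_path_factory.mktemp("synth_small"))
    return config, truth, sheet


@pytest.fixture(scope="session")
def small_pipeline(small_dataset):
    config, truth, sheet = small_dataset
    result = run_pipeline(sheet, PipelineParams())
    return config, truth, result
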