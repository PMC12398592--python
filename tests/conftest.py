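import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def glyc_generator():
    from udekit.data import GlycolysisDataGenerator

    return GlycolysisDataGenerator()


@pytest.fixture(scope="session")
def small_ann_spec():
    from udekit.nn import ANNSpec

    return ANNSpec(n_inputs=7, n_outputs=1, n_hidden_layers=1, width=5, activation="tanh")


@pytest.fixture(scope="session")
def glyc_ude(small_ann_spec):
    from udekit.models import build_glycolysis_ude

    return build_glycolysis_ude(small_ann_spec)


@pytest.fixture(scope="session")
def dataset_16pts(glyc_generator):
    from udekit.data import DataSetting

    ds, truth = glyc_generator.generate(DataSetting(16, 5.0, seed=7))
    return ds, truth
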