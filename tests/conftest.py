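import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def toy_annotation():
    from ribolens.synthetic import build_toy_annotation

    return build_toy_annotation(n_genes_per_event_type=2, n_apa_genes=2, seed=1)


@pytest.fixture(scope="session")
def small_experiment():
    """A small paired count experiment with planted abundance genes."""
    from ribolens.synthetic import StudyDesign, simulate_experiment

    design = StudyDesign()
    return simulate_experiment(
        design,
        n_genes=600,
        mode_config={"abundance": (40, 1.5)},
        seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def two_group_samples():
    """Sample sheet for two age groups of 6 samples each, single fraction."""
    rows = []
    for age, n in ((3, 6), (20, 6)):
        for i in range(n):
            rows.append(
                {
                    "sample_id": f"s{age}_{i}",
                    "subject_id": f"m{age}_{i}",
                    "age_months": age,
                    "fraction": "total",
                    "batch": "b0",
                }
            )
    return pd.DataFrame(rows).set_index("sample_id", drop=False)
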