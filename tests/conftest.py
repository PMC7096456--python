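import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("det", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("det")

# Published validation-set Mahalanobis distances for two pesticide
# formulation datasets (deltamethrin and emamectin benzoate), each measured
# by an NIR and an MIR calibration, plus the reported 3x-group-mean
# thresholds. Used as a worked fixture for the weight-assignment rule.
DELTAMETHRIN_MD = np.array(
    [
        [2.731, 2.454],
        [2.157, 1.904],
        [2.213, 2.112],
        [3.441, 3.017],
        [2.886, 3.489],
        [2.183, 2.661],
        [3.758, 2.961],
        [1.523, 2.310],
        [2.920, 1.700],
        [3.700, 3.808],
        [2.624, 2.925],
        [1.900, 1.254],
        [2.135, 1.843],
        [2.477, 1.797],
        [2.423, 1.870],
    ]
)
DELTAMETHRIN_THRESHOLDS = np.array([8.239, 7.517])

EMAMECTIN_MD = np.array(
    [
        [5.463, 4.092],
        [3.267, 2.244],
        [7.631, 1.206],
        [3.468, 1.633],
        [8.283, 1.692],
        [2.229, 2.155],
        [3.055, 1.953],
        [1.899, 1.892],
        [4.962, 1.723],
        [1.914, 1.829],
        [3.183, 0.883],
        [2.947, 1.531],
        [3.459, 1.785],
        [3.086, 1.411],
        [2.613, 1.922],
    ]
)
EMAMECTIN_THRESHOLDS = np.array([9.154, 5.705])


@pytest.fixture(scope="session")
def published_md_fixtures():
    return {
        "deltamethrin": (DELTAMETHRIN_MD, DELTAMETHRIN_THRESHOLDS),
        "emamectin": (EMAMECTIN_MD, EMAMECTIN_THRESHOLDS),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def benchmark_run():
    """One full pipeline run on the default synthetic benchmark (seed 1)."""
    from mdwfuse import default_benchmark, generate_dataset, rank_split, run_mdw_pipeline

    tables, ref, labels = generate_dataset(default_benchmark(seed=1))
    plan = rank_split(ref.concentration, 15 / 78, sample_ids=ref.sample_ids)
    pairs = [
        (t.subset(plan.calibration_ids), t.subset(plan.validation_ids)) for t in tables
    ]
    result = run_mdw_pipeline(
        pairs, ref.subset(plan.calibration_ids), ref.subset(plan.validation_ids)
    )
    return result, plan, labels
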