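import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import methrel as mr

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_manifest():
    return mr.generate_manifest(
        600, type2_fraction=0.84, n_neighbor_pairs=60, n_control_pairs=40,
        n_negative_controls=60, seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_manifest):
    return mr.simulate_truth(small_manifest, n_subjects=40, n_replicate_pairs=15, seed=12)


@pytest.fixture(scope="session")
def small_dataset(small_truth, small_manifest):
    return mr.simulate_intensities(small_truth, small_manifest, seed=13)


@pytest.fixture(scope="session")
def noise_free_dataset(small_truth, small_manifest):
    return mr.simulate_intensities(
        small_truth, small_manifest, mr.TechConfig().noise_free(), seed=13
    )


@pytest.fixture(scope="session")
def small_models(small_manifest, small_truth):
    return mr.make_weight_tables(
        small_manifest,
        small_truth,
        [
            {"name": "AgeLinear", "n_probes": 60, "target": "age"},
            {"name": "SynthClock", "n_probes": 50, "target": "age", "transform": "horvath_age"},
            {"name": "AgingScore", "n_probes": 80, "target": "latent_score"},
            {"name": "Random", "n_probes": 30, "target": "random"},
        ],
        seed=14,
    )


@pytest.fixture(scope="session")
def small_bundle():
    """One small end-to-end experiment shared by workflow-level tests."""
    cfg = mr.ExperimentConfig(
        seed=21,
        n_probes=800,
        n_neighbor_pairs=80,
        n_subjects=180,
        n_replicate_pairs=30,
        grid={
            "bg": ["none", "oob"],
            "dye": ["none", "relic"],
            "norm": ["none", "q1"],
            "probe": ["none", "rcp"],
        },
        predictors=[
            {"name": "SynthClock", "n_probes": 120, "target": "age", "transform": "horvath_age"},
            {"name": "AgeLinear", "n_probes": 80, "target": "age"},
            {"name": "AgingScore", "n_probes": 100, "target": "latent_score"},
            {"name": "Random", "n_probes": 60, "target": "random"},
        ],
    )
    return mr.run_experiment(cfg)


def icc_oracle(y: np.ndarray) -> dict:
    """Plain sums-of-squares ICC oracle, written independently of the package.

    Loops over cells, accumulates raw sums of squares, and applies the six
    classical variance-ratio formulas directly.
    """
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row)
    ss_cols = n * sum((c - grand) ** 2 for c in col)
    ss_err = sum(
        (y[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_within = sum((y[i, j] - row[i]) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = ss_within / (n * (k - 1))
    return {
        (1, 1): (msr - msw) / (msr + (k - 1) * msw),
        (2, 1): (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n),
        (3, 1): (msr - mse) / (msr + (k - 1) * mse),
        (1, "k"): (msr - msw) / msr,
        (2, "k"): (msr - mse) / (msr + (msc - mse) / n),
        (3, "k"): (msr - mse) / msr,
    }
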