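import numpy as np
import pandas as pd
import pytest

from dctmle import AnalyticDataset, DGPConfig, LearnerSpec, RunSettings, generate_dataset


@pytest.fixture
def tiny_csv(tmp_path):
    """4-row CSV with one numeric and one categorical covariate."""
    path = tmp_path / "tiny.csv"
    pd.DataFrame(
        {
            "y": [10.0, 2.0, 7.0, 5.0],
            "a": [1, 0, 1, 0],
            "age": [50.0, 61.0, 44.0, 70.0],
            "sex": ["m", "f", "f", "m"],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture
def small_dataset():
    """200-row confounded continuous-outcome dataset."""
    dataset, _ = generate_dataset(DGPConfig(n=200, true_ate=1.0, seed=42))
    return dataset


@pytest.fixture
def glm_settings():
    """Cheap single-GLM settings for smoke runs."""
    return RunSettings(
        num_cf=2,
        cv_folds=3,
        learners_exposure=(LearnerSpec("glm"),),
        seed=7,
    )


def make_linear_dataset(n: int, seed: int, ate: float = 2.0) -> AnalyticDataset:
    """Linear-in-covariates DGP where a plain GLM is correctly specified."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    pi = 1.0 / (1.0 + np.exp(-(0.6 * x[:, 0] - 0.4 * x[:, 1])))
    a = rng.binomial(1, pi)
    y = ate * a + x[:, 0] + 0.5 * x[:, 1] - 0.7 * x[:, 2] + rng.normal(0, 1, n)
    return AnalyticDataset(
        outcome=y,
        exposure=a,
        covariates=pd.DataFrame(x, columns=["x1", "x2", "x3"]),
        outcome_kind="continuous",
    )
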