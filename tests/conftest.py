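import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ergrisk import ERG_FEATURES, PredictionSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(features: np.ndarray, labels: np.ndarray, rng=None) -> pd.DataFrame:
    """Wrap a (n, k<=8) feature block into a valid feature table.

    Unused ERG columns are filled with noise so every table satisfies the
    full-column contract.
    """
    rng = rng or np.random.default_rng(0)
    n, k = features.shape
    data = {"id": [f"T{i:04d}" for i in range(n)],
            "group": np.where(labels == 1, "SMI", "control")}
    for j, name in enumerate(ERG_FEATURES):
        if j < k:
            data[name] = features[:, j]
        else:
            data[name] = rng.normal(0, 1, n)
    data["age"] = rng.normal(40, 10, n)
    data["sex"] = rng.choice(["male", "female"], n)
    data["pupil"] = rng.normal(3.8, 1.0, n)
    return pd.DataFrame(data)


def pred_from(labels, probs) -> PredictionSet:
    return PredictionSet(y_true=np.asarray(labels), p=np.asarray(probs))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def informative_pred(rng) -> PredictionSet:
    """Two-Gaussian score mixture: 200 cases at 0.65, 200 controls at 0.35."""
    pos = np.clip(rng.normal(0.65, 0.12, 200), 0.01, 0.99)
    neg = np.clip(rng.normal(0.35, 0.12, 200), 0.01, 0.99)
    return PredictionSet(
        y_true=np.concatenate([np.ones(200, int), np.zeros(200, int)]),
        p=np.concatenate([pos, neg]),
    )
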