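import numpy as np
import pandas as pd
import pytest

from retrotime import (
    CountsMatrix,
    SampleSheet,
    normalize,
    simulate_repeat_dataset,
)
from retrotime.synthetic_data import SyntheticSpec


@pytest.fixture(scope="session")
def study_samples() -> SampleSheet:
    """The study design: controls at 6/30/120 h, starved at 6/15/30/72/120 h."""
    rows = [
        ("ctrl_6h", "control", 6.0), ("ctrl_30h", "control", 30.0),
        ("ctrl_120h", "control", 120.0),
        ("starv_6h", "starved", 6.0), ("starv_15h", "starved", 15.0),
        ("starv_30h", "starved", 30.0), ("starv_72h", "starved", 72.0),
        ("starv_120h", "starved", 120.0),
    ]
    frame = pd.DataFrame(rows, columns=["sample", "series", "time_h"])
    return SampleSheet(frame.set_index("sample"))


@pytest.fixture(scope="session")
def small_dataset():
    """500-subfamily synthetic dataset with the default planted structure."""
    return simulate_repeat_dataset(SyntheticSpec(seed=1, n_subfamilies=500))


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    return normalize(small_dataset.counts,
                     groups=list(small_dataset.samples.frame["series"]))


def nb_counts(rng: np.random.Generator, mu, d: float, size=None) -> np.ndarray:
    """NB draw with variance mu + d*mu^2 (Poisson at d=0)."""
    mu = np.asarray(mu, dtype=float)
    if d == 0:
        return rng.poisson(mu, size=size)
    theta = 1.0 / d
    return rng.negative_binomial(theta, theta / (theta + mu), size=size)


def make_counts(matrix: np.ndarray, samples=None, lengths=None,
                level="subfamily") -> CountsMatrix:
    matrix = np.asarray(matrix)
    n, m = matrix.shape
    samples = samples or [f"s{j}" for j in range(m)]
    index = pd.Index([f"f{i:04d}" for i in range(n)], name="feature")
    counts = pd.DataFrame(matrix, index=index, columns=samples)
    if lengths is None:
        lengths = pd.Series(1000, index=index)
    else:
        lengths = pd.Series(lengths, index=index)
    return CountsMatrix(counts=counts, lengths=lengths, level=level)
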