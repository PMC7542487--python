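import numpy as np
import pytest

from srmkl import SplitPlan, SynthConfig, generate, make_splits


def random_psd(rng: np.random.Generator, n: int) -> np.ndarray:
    """A random symmetric PSD matrix with O(1) entries."""
    A = rng.standard_normal((n, n + 2))
    return A @ A.T / (n + 2)


def random_labels(rng: np.random.Generator, n: int) -> np.ndarray:
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    y[0], y[1] = 1.0, -1.0  # guarantee both classes
    return y


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240611)


@pytest.fixture
def stylized_split():
    """Moderately styled train/test pair with every style in both halves."""
    ds = generate(SynthConfig(n_groups=3, per_group=30, dim=4, class_sep=2.0,
                              style_strength=1.0, noise_sd=1.0, seed=42))
    return make_splits(ds, SplitPlan(0.5), seed=7)


@pytest.fixture
def separable_holdout():
    """Well-separated data with style group 3 held out of training."""
    ds = generate(SynthConfig(n_groups=3, per_group=20, dim=4, class_sep=6.0,
                              style_strength=0.3, noise_sd=1.0, seed=3))
    return make_splits(ds, SplitPlan(0.5, frozenset({3})), seed=7)
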