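import numpy as np
import pytest

from mielm import EpochSet, SynthConfig, generate_mi_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_epochs():
    """A small, clearly separable 2-class set for fast pipeline-level tests."""
    return generate_mi_dataset(
        SynthConfig(n_trials_per_class=20, n_channels=10, erd_depth=0.6, seed=99)
    )


def make_two_cov_epochs(var_a, var_b, n_per_class=40, n_samples=200, seed=0):
    """Trials of independent Gaussian channels with class-specific variances.

    The class-average covariances converge to diag(var_a) and diag(var_b),
    the classic construction for checking spatial-filter optimality.
    """
    gen = np.random.default_rng(seed)
    var_a = np.asarray(var_a, dtype=float)
    var_b = np.asarray(var_b, dtype=float)
    n_ch = var_a.size
    data, labels = [], []
    for cls, var in ((1, var_a), (2, var_b)):
        for _ in range(n_per_class):
            data.append(gen.standard_normal((n_ch, n_samples)) * np.sqrt(var)[:, None])
            labels.append(cls)
    return EpochSet(
        data=np.stack(data),
        labels=np.array(labels),
        fs=250.0,
        channel_names=[f"ch{i}" for i in range(n_ch)],
        class_names=["a", "b"],
    )
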