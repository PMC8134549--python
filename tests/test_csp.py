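import numpy as np
import pytest

from mielm import CSPModel, DataError, UsageError, csp_features, fit_csp
from mielm.csp import _trial_covariances

from conftest import make_two_cov_epochs


def class_covariances(epochs, channels):
    covs = _trial_covariances(epochs.data[:, channels, :])
    return {
        int(c): covs[epochs.labels == c].mean(axis=0) for c in np.unique(epochs.labels)
    }


def variance_ratio(w, c_a, c_b):
    return (w @ c_a @ w) / (w @ (c_a + c_b) @ w)


class TestFitCsp:
    def test_axis_aligned_optimum(self):
        """diag(4,1) vs diag(1,4): the optimal filters are the coordinate axes."""
        ep = make_two_cov_epochs([4.0, 1.0], [1.0, 4.0], n_per_class=80, n_samples=500)
        model = fit_csp(ep, [0, 1], m=1)
        first = model.filters[0] / np.linalg.norm(model.filters[0])
        last = model.filters[-1] / np.linalg.norm(model.filters[-1])
        angle = lambda w, e: np.degrees(np.arccos(min(1.0, abs(w @ e))))
        assert angle(first, np.array([1.0, 0.0])) < 1.0
        assert angle(last, np.array([0.0, 1.0])) < 1.0

    def test_first_filter_beats_random_vectors(self):
        """Brute-force oracle: no random unit vector achieves a better variance ratio."""
        ep = make_two_cov_epochs(
            [5.0, 3.0, 1.0, 1.0, 0.5, 2.0],
            [1.0, 1.0, 3.0, 0.5, 2.0, 2.0],
            n_per_class=60,
            n_samples=400,
            seed=7,
        )
        channels = list(range(6))
        model = fit_csp(ep, channels, m=2)
        covs = class_covariances(ep, channels)
        best_fit = variance_ratio(model.filters[0], covs[1], covs[2])
        gen = np.random.default_rng(0)
        vecs = gen.standard_normal((10000, 6))
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        ratios = np.einsum("ki,ij,kj->k", vecs, covs[1], vecs) / np.einsum(
            "ki,ij,kj->k", vecs, covs[1] + covs[2], vecs
        )
        assert best_fit >= ratios.max() - 1e-9

    def test_identical_class_covariances_give_half_ratios(self, rng):
        from mielm import EpochSet

        block = rng.standard_normal((20, 4, 300))
        data = np.concatenate([block, block])  # class 2 = exact copies of class 1
        ep = EpochSet(data, np.repeat([1, 2], 20), 250.0, list("abcd"), ["x", "y"])
        model = fit_csp(ep, [0, 1, 2, 3], m=2)
        covs = class_covariances(ep, [0, 1, 2, 3])
        for w in model.filters:
            assert variance_ratio(w, covs[1], covs[2]) == pytest.approx(0.5, abs=1e-6)

    def test_whitening_contract(self):
        ep = make_two_cov_epochs([4.0, 1.0, 2.0, 0.5], [1.0, 4.0, 0.5, 2.0])
        model = fit_csp(ep, [0, 1, 2, 3], m=2)
        covs = class_covariances(ep, [0, 1, 2, 3])
        W = model.filters
        np.testing.assert_allclose(
            W @ (covs[1] + covs[2]) @ W.T, np.eye(W.shape[0]), atol=1e-6
        )

    def test_one_vs_rest_multiclass(self):
        from mielm import EpochSet

        gen = np.random.default_rng(11)
        variances = {1: [5, 1, 1, 1], 2: [1, 5, 1, 1], 3: [1, 1, 5, 1], 4: [1, 1, 1, 5]}
        data, labels = [], []
        for cls, var in variances.items():
            for _ in range(15):
                data.append(gen.standard_normal((4, 300)) * np.sqrt(var)[:, None])
                labels.append(cls)
        ep = EpochSet(np.stack(data), np.array(labels), 250.0, list("abcd"), list("1234"))
        model = fit_csp(ep, [0, 1, 2, 3], m=1)
        assert model.filters.shape == (8, 4)  # 2m filters per class, 4 classes
        assert model.class_pairs == [(1, -1), (2, -1), (3, -1), (4, -1)]

    def test_small_class_is_named_in_error(self, small_epochs):
        sub = small_epochs.subset([0, 1, 2])
        with pytest.raises(DataError, match=r"class \d"):
            fit_csp(sub, list(range(sub.n_channels)), m=1)

    def test_m_too_large(self, small_epochs):
        with pytest.raises(UsageError):
            fit_csp(small_epochs, [0, 1], m=2)

    def test_singular_covariance_advises_shrinkage(self):
        ep = make_two_cov_epochs([4.0, 1.0], [1.0, 4.0], n_per_class=5, n_samples=100)
        ep.data[:, 1, :] = ep.data[:, 0, :]  # duplicated channel -> rank deficiency
        with pytest.raises(DataError, match="shrinkage"):
            fit_csp(ep, [0, 1], m=1)
        # shrinkage makes the same fit possible
        model = fit_csp(ep, [0, 1], m=1, shrinkage=0.1)
        assert np.all(np.isfinite(model.filters))


class TestCspFeatures:
    @staticmethod
    def identity_model(n=4):
        return CSPModel(
            filters=np.eye(n),
            class_pairs=[(1, 2)],
            n_pairs_per_problem=n // 2,
            channel_names=[f"c{i}" for i in range(n)],
            channel_indices=np.arange(n),
        )

    def test_equal_variances_symmetry(self, rng):
        model = self.identity_model(4)
        trial = rng.standard_normal((4, 1000))
        trial /= trial.std(axis=1, keepdims=True)
        feats = csp_features(model, trial)
        np.testing.assert_allclose(feats, np.log(1 / 4), atol=0.05)

    def test_scale_invariance(self, rng):
        model = self.identity_model(4)
        trial = rng.standard_normal((4, 500))
        np.testing.assert_allclose(
            csp_features(model, trial), csp_features(model, 7.3 * trial), atol=1e-10
        )

    def test_class_separation_matches_construction(self):
        ep = make_two_cov_epochs([4.0, 1.0], [1.0, 4.0], n_per_class=50, n_samples=400)
        model = fit_csp(ep, [0, 1], m=1)
        feats = np.vstack([csp_features(model, ep.data[t]) for t in range(ep.n_trials)])
        mean_a = feats[ep.labels == 1].mean(axis=0)
        mean_b = feats[ep.labels == 2].mean(axis=0)
        # filter 1 favors class A variance, filter 2 class B: signs must separate
        assert mean_a[0] > mean_b[0] and mean_a[1] < mean_b[1]

    def test_zero_variance_floor(self):
        model = self.identity_model(2)
        feats = csp_features(model, np.zeros((2, 100)))
        np.testing.assert_allclose(feats, np.log(1e-12))

    def test_dimension_mismatch(self, rng):
        model = self.identity_model(4)
        with pytest.raises(UsageError):
            csp_features(model, rng.standard_normal((3, 100)))

    def test_channel_permutation_invariance(self):
        ep = make_two_cov_epochs([4.0, 1.0, 2.0], [1.0, 4.0, 2.0], n_per_class=30)
        model = fit_csp(ep, [0, 1, 2], m=1)
        perm = [2, 0, 1]
        permuted_model = CSPModel(
            filters=model.filters[:, perm],
            class_pairs=model.class_pairs,
            n_pairs_per_problem=model.n_pairs_per_problem,
            channel_names=[model.channel_names[i] for i in perm],
            channel_indices=np.arange(3),
        )
        trial = ep.data[0]
        np.testing.assert_allclose(
            csp_features(model, trial),
            csp_features(permuted_model, trial[perm]),
            atol=1e-12,
        )
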