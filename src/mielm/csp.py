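"""Common spatial patterns: supervised spatial filters for the non-LCD channels.

For two classes the filters jointly diagonalize the class-average covariances:
with per-trial covariances normalized as ``C = X X^T / trace(X X^T)`` and
class averages ``C_1``, ``C_2``, the generalized eigenproblem of
``(C_1, C_1 + C_2)`` yields filters ``w`` ordered by the variance ratio they
achieve between the classes. The ``m`` largest- and ``m`` smallest-eigenvalue
filters are kept (the most discriminative in either direction), and the full
filter matrix satisfies the whitening contract ``W (C_1 + C_2) W^T = I``.

More than two classes are handled one-vs-rest: each class is contrasted with
the pooled remaining trials and contributes its own ``2 m`` filters.

A trial's spatial feature per filter is the log of its normalized projected
variance, ``f = log(var(w^T X) / sum_filters var)``; with the default two-class
``m = 2`` configuration this is the 4-element vector ``V2 = [f_1 .. f_4]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import DataError, UsageError
from .io import EpochSet

logger = logging.getLogger(__name__)

__all__ = ["CSPModel", "csp_features", "fit_csp"]

#: variance floor substituted for zero-variance projections before the log
VAR_FLOOR = 1e-12

#: sentinel used in class_pairs for the pooled "rest" side of one-vs-rest fits
REST = -1


@dataclass
class CSPModel:
    """Fitted spatial filter bank over a fixed subset of channels."""

    filters: np.ndarray  # n_filters x n_selected_channels
    class_pairs: list[tuple[int, int]]
    n_pairs_per_problem: int
    channel_names: list[str]
    channel_indices: np.ndarray  # into the montage the model was fitted on

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    def transform(self, epochs: EpochSet) -> np.ndarray:
        """Feature matrix (trials x filters) for epochs on the fit-time montage."""
        return np.vstack(
            [csp_features(self, epochs.data[t][self.channel_indices]) for t in range(epochs.n_trials)]
        )


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalized per-trial covariances for trials x channels x samples."""
    covs = np.einsum("tcs,tds->tcd", data, data)
    traces = np.trace(covs, axis1=1, axis2=2)
    if np.any(traces <= 0):
        raise DataError("a trial has zero total power; cannot form its covariance")
    return covs / traces[:, None, None]


def _shrink(cov: np.ndarray, shrinkage: float) -> np.ndarray:
    if shrinkage <= 0:
        return cov
    n = cov.shape[0]
    return (1.0 - shrinkage) * cov + shrinkage * (np.trace(cov) / n) * np.eye(n)


def _two_class_filters(c_a: np.ndarray, c_b: np.ndarray, m: int) -> np.ndarray:
    """2m filters from the generalized eigenproblem of (c_a, c_a + c_b)."""
    pooled = c_a + c_b
    eigvals_pooled = scipy.linalg.eigvalsh(pooled)
    if eigvals_pooled[0] < 1e-12 * eigvals_pooled[-1]:
        raise DataError(
            "pooled class covariance is singular; enable shrinkage regularization "
            "(shrinkage > 0) or supply more/cleaner trials"
        )
    vals, vecs = scipy.linalg.eigh(c_a, pooled)  # ascending eigenvalues
    order = np.concatenate((np.argsort(vals)[::-1][:m], np.argsort(vals)[:m]))
    filters = vecs[:, order].T
    # sign convention: largest-magnitude coefficient positive, for stable output
    for w in filters:
        if w[np.argmax(np.abs(w))] < 0:
            w *= -1.0
    return filters


def fit_csp(
    epochs: EpochSet, csp_channels, m: int = 2, shrinkage: float = 0.0
) -> CSPModel:
    """Fit the spatial filter bank on the selected channels.

    Two classes give ``2 m`` filters; ``C > 2`` classes give ``2 m`` filters per
    class via one-vs-rest, ``2 m C`` in total.
    """
    channels = np.asarray(list(csp_channels), dtype=int)
    if m < 1:
        raise UsageError("m must be >= 1")
    if 2 * m > channels.size:
        raise UsageError(f"2*m = {2 * m} filters exceed the {channels.size} CSP channels")
    present = np.unique(epochs.labels)
    if present.size < 2:
        raise DataError("CSP needs at least 2 classes present")
    for cls in present:
        if np.sum(epochs.labels == cls) < 2:
            raise DataError(f"class {cls} has fewer than 2 trials; cannot fit CSP")
    covs = _trial_covariances(epochs.data[:, channels, :])
    class_covs = {
        int(cls): _shrink(covs[epochs.labels == cls].mean(axis=0), shrinkage)
        for cls in present
    }
    if present.size == 2:
        a, b = (int(c) for c in present)
        filters = _two_class_filters(class_covs[a], class_covs[b], m)
        pairs = [(a, b)]
    else:
        blocks, pairs = [], []
        for cls in present:
            rest = _shrink(covs[epochs.labels != cls].mean(axis=0), shrinkage)
            blocks.append(_two_class_filters(class_covs[int(cls)], rest, m))
            pairs.append((int(cls), REST))
        filters = np.vstack(blocks)
    return CSPModel(
        filters=filters,
        class_pairs=pairs,
        n_pairs_per_problem=m,
        channel_names=[epochs.channel_names[c] for c in channels],
        channel_indices=channels,
    )


def csp_features(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Log normalized-variance features of one trial (selected channels x samples)."""
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[0] != model.filters.shape[1]:
        raise UsageError(
            f"trial has {trial.shape[0] if trial.ndim == 2 else '?'} channels, "
            f"model expects {model.filters.shape[1]}"
        )
    proj = model.filters @ trial
    variances = proj.var(axis=1)
    total = variances.sum()
    if total <= 0:
        logger.warning("trial has zero projected variance under all filters")
        return np.full(model.n_filters, np.log(VAR_FLOOR))
    ratios = variances / total
    if np.any(ratios <= 0):
        logger.warning("zero-variance projection; flooring the affected feature(s)")
        ratios = np.maximum(ratios, VAR_FLOOR)
    return np.log(ratios)
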