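"""Contribution-rate channel selection and normalized serial feature fusion.

Channel selection scores every channel by how well its band power separates the
classes: the score is the Fisher discriminant ratio of per-trial log band power
(default band 8-30 Hz, spanning the mu and beta rhythms) -- between-class
variance of the class means over pooled within-class variance. The top-ranked
channels feed the time-frequency (LCD) branch and the remainder feed the
spatial (CSP) branch; with the default 22-channel montage that is the
"4 + 18" split. Montages too small to split (n_channels <= n_lcd + 1, e.g. a
3-channel recording with n_lcd = 4) fall back to using every channel for both
branches, flagged on the result.

Fusion is serial: each feature block is scaled to unit Euclidean norm and the
blocks are concatenated head-to-tail, ``V = [V1, V2]``. An elementwise
sign-normalization variant (each entry mapped to x/|x|) is available as
``mode="sign"`` for fidelity experiments; it discards magnitudes and is not
the default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, UsageError
from .io import BandSpec, EpochSet, bandpass

logger = logging.getLogger(__name__)

__all__ = ["ChannelSplit", "FusedFeature", "fuse", "rank_channels", "split_channels"]

DEFAULT_SELECT_BAND = BandSpec(8.0, 30.0)


@dataclass
class ChannelSplit:
    """Disjoint LCD/CSP channel index lists (equal, flagged, when split is impossible)."""

    lcd_channels: list[int]
    csp_channels: list[int]
    scores: np.ndarray
    overlap: bool = False


@dataclass
class FusedFeature:
    v1: np.ndarray
    v2: np.ndarray
    v: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.v = np.concatenate((self.v1, self.v2))


def rank_channels(epochs: EpochSet, band: BandSpec = DEFAULT_SELECT_BAND) -> np.ndarray:
    """Per-channel Fisher ratio of log band power; higher = more class-informative."""
    present = np.unique(epochs.labels)
    if present.size < 2:
        raise DataError("channel ranking needs at least 2 classes")
    for cls in present:
        if np.sum(epochs.labels == cls) < 2:
            raise DataError(f"class {cls} has fewer than 2 trials")
    narrow = bandpass(epochs, band)
    power = narrow.data.var(axis=2)  # trials x channels
    dead = power.max(axis=0) <= 0.0
    if np.any(dead):
        logger.warning("zero-power channel(s) %s scored 0", np.flatnonzero(dead).tolist())
    log_power = np.log(np.maximum(power, 1e-300))
    n_total = epochs.n_trials
    grand = log_power.mean(axis=0)
    between = np.zeros(epochs.n_channels)
    within = np.zeros(epochs.n_channels)
    for cls in present:
        block = log_power[epochs.labels == cls]
        n_c = block.shape[0]
        mean_c = block.mean(axis=0)
        between += n_c * (mean_c - grand) ** 2
        within += ((block - mean_c) ** 2).sum(axis=0)
    between /= n_total
    within /= max(n_total - present.size, 1)
    scores = between / np.maximum(within, 1e-30)
    scores[dead] = 0.0
    return scores


def split_channels(scores, n_lcd: int = 4) -> ChannelSplit:
    """Top ``n_lcd`` channels by score to the LCD branch, the rest to CSP.

    Ties are broken toward the lower channel index. When the montage is too
    small to split both branches receive every channel and ``overlap`` is set.
    """
    scores = np.asarray(scores, dtype=float)
    if n_lcd < 1:
        raise UsageError("n_lcd must be >= 1")
    if not np.all(np.isfinite(scores)):
        raise DataError("channel scores must be finite")
    n = scores.size
    if n <= n_lcd + 1:
        everything = list(range(n))
        logger.warning(
            "%d channels cannot be split into %d LCD + CSP; using all channels "
            "for both branches",
            n,
            n_lcd,
        )
        return ChannelSplit(everything, list(everything), scores, overlap=True)
    order = np.argsort(-scores, kind="stable")  # stable: ties keep index order
    lcd = sorted(int(i) for i in order[:n_lcd])
    csp = sorted(int(i) for i in order[n_lcd:])
    return ChannelSplit(lcd, csp, scores, overlap=False)


def _normalize_block(block: np.ndarray, mode: str, name: str) -> np.ndarray:
    if block.size == 0:
        return block.copy()
    if mode == "norm":
        norm = float(np.linalg.norm(block))
        if norm == 0.0:
            logger.warning("%s block is all zeros; passed through unnormalized", name)
            return block.copy()
        return block / norm
    if mode == "sign":
        out = np.sign(block)
        return out
    raise UsageError(f"unknown normalization mode {mode!r} (use 'norm' or 'sign')")


def fuse(v1_raw, v2_raw, mode: str = "norm") -> FusedFeature:
    """Normalize each block, then concatenate end to end into ``V = [V1, V2]``."""
    v1 = np.asarray(v1_raw, dtype=float).ravel()
    v2 = np.asarray(v2_raw, dtype=float).ravel()
    if not (np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise DataError("fusion inputs must be finite (found NaN or inf)")
    return FusedFeature(
        v1=_normalize_block(v1, mode, "V1"), v2=_normalize_block(v2, mode, "V2")
    )
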