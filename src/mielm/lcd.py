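"""Local characteristic-scale decomposition (LCD) and time-frequency energy features.

LCD adaptively splits a signal into *intrinsic scale components* (ISCs), ordered
from the fastest oscillatory scale to the slowest, plus a residual trend. Each
component is extracted by iterated sifting: for every interior extremum
``(tau_k, X_k)`` with neighbours ``(tau_{k-1}, X_{k-1})`` and
``(tau_{k+1}, X_{k+1})`` the chord value

    A_k = X_{k-1} + (tau_k - tau_{k-1}) / (tau_{k+1} - tau_{k-1}) * (X_{k+1} - X_{k-1})

is mixed with the extremum itself into a baseline knot
``L_k = a * A_k + (1 - a) * X_k`` (default ``a = 0.5``); the knots are
interpolated into a baseline curve which is subtracted from the signal. A
component is accepted once its baseline is negligible (RMS below
``stop_tol`` x input RMS) or the sift budget is exhausted. By construction the
components and residual re-sum to the input to floating-point precision.

The feature used downstream is the per-component time-frequency energy
``E = sum_t |ISC(t)|^2``: with four selected channels and the first three
layers per channel this yields the 12-element energy vector V1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import UsageError
from .io import EpochSet

logger = logging.getLogger(__name__)

__all__ = ["ISCStack", "isc_energy", "lcd_decompose", "lcd_features", "local_extrema"]


@dataclass
class ISCStack:
    """Ordered intrinsic scale components (fastest first) plus the residual."""

    components: list[np.ndarray] = field(default_factory=list)
    residual: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_sifts_used: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.components:
            out += c
        return out


def local_extrema(signal) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict interior local maxima and minima, in increasing order.

    Plateaus (runs of equal values) that form an extremum are reported once, at
    the midpoint of the run. Runs touching either end of the signal are not
    interior and are never reported.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise UsageError("local_extrema needs a 1-D signal of length >= 3")
    # Compress runs of equal values so plateaus become single candidates.
    change = np.flatnonzero(np.diff(x) != 0)
    run_starts = np.concatenate(([0], change + 1))
    run_ends = np.concatenate((change, [x.size - 1]))  # inclusive
    vals = x[run_starts]
    if vals.size < 3:
        empty = np.zeros(0, dtype=int)
        return empty, empty
    mid = (run_starts + run_ends) // 2
    v_prev, v_mid, v_next = vals[:-2], vals[1:-1], vals[2:]
    is_max = (v_mid > v_prev) & (v_mid > v_next)
    is_min = (v_mid < v_prev) & (v_mid < v_next)
    interior_mid = mid[1:-1]
    return interior_mid[is_max], interior_mid[is_min]


def _combined_extrema(x: np.ndarray) -> np.ndarray:
    maxima, minima = local_extrema(x)
    return np.sort(np.concatenate((maxima, minima)))


def _baseline(x: np.ndarray, ext: np.ndarray, a: float, interp: str) -> np.ndarray:
    """Baseline curve through the chord-mixed knots, mirror-extended at the ends."""
    tau = ext.astype(float)
    val = x[ext]
    # Mirror the second extremum from each end about the first so the boundary
    # extrema also get a chord value.
    tau_e = np.concatenate(([2 * tau[0] - tau[1]], tau, [2 * tau[-1] - tau[-2]]))
    val_e = np.concatenate(([val[1]], val, [val[-2]]))
    chord = val_e[:-2] + (tau_e[1:-1] - tau_e[:-2]) / (tau_e[2:] - tau_e[:-2]) * (
        val_e[2:] - val_e[:-2]
    )
    knots = a * chord + (1.0 - a) * val
    # Extend to the signal ends by linear extrapolation from the outermost knots.
    n = x.size
    xs, ks = [tau], [knots]
    if tau[0] > 0:
        slope = (knots[1] - knots[0]) / (tau[1] - tau[0])
        xs.insert(0, [0.0])
        ks.insert(0, [knots[0] - slope * tau[0]])
    if tau[-1] < n - 1:
        slope = (knots[-1] - knots[-2]) / (tau[-1] - tau[-2])
        xs.append([float(n - 1)])
        ks.append([knots[-1] + slope * (n - 1 - tau[-1])])
    tau_full = np.concatenate(xs)
    knots_full = np.concatenate(ks)
    t = np.arange(n, dtype=float)
    if interp == "linear":
        return np.interp(t, tau_full, knots_full)
    if interp == "cubic":
        from scipy.interpolate import CubicSpline

        return CubicSpline(tau_full, knots_full)(t)
    raise UsageError(f"unknown baseline interpolation {interp!r}")


def lcd_decompose(
    signal,
    max_components: int = 8,
    max_sifts: int = 30,
    stop_tol: float = 0.01,
    a: float = 0.5,
    interp: str = "linear",
) -> ISCStack:
    """Decompose a signal into intrinsic scale components plus a residual.

    Parameters
    ----------
    signal : 1-D array
    max_components : maximum number of ISCs to extract.
    max_sifts : sift budget per component.
    stop_tol : a sift's baseline with RMS below ``stop_tol`` x input RMS ends
        the component's sifting.
    a : chord/extremum mixing weight of the baseline knots.
    interp : ``"linear"`` (default) or ``"cubic"`` knot interpolation.

    Signals that are too short or too smooth to sift (fewer than 4 interior
    extrema) are returned whole as the residual with zero components.
    """
    if max_components < 1 or max_sifts < 1:
        raise UsageError("max_components and max_sifts must be >= 1")
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise UsageError("signal must be 1-D")
    stack = ISCStack(residual=x.copy())
    if x.size < 5:
        return stack
    maxima, minima = local_extrema(x)
    if maxima.size + minima.size < 4:
        return stack
    input_rms = float(np.sqrt(np.mean(x**2)))
    if input_rms == 0.0:
        return stack
    residual = stack.residual
    for _ in range(max_components):
        ext = _combined_extrema(residual)
        if ext.size < 3:  # monotone or near-monotone: nothing left to sift
            break
        h = residual.copy()
        n_sifts = 0
        for _ in range(max_sifts):
            ext_h = _combined_extrema(h)
            if ext_h.size < 3:
                break
            base = _baseline(h, ext_h, a, interp)
            h -= base
            n_sifts += 1
            if float(np.sqrt(np.mean(base**2))) < stop_tol * input_rms:
                break
        if n_sifts == 0:
            break
        stack.components.append(h)
        stack.n_sifts_used.append(n_sifts)
        residual = residual - h
    stack.residual = residual
    return stack


def isc_energy(component) -> float:
    """Time-frequency energy of one component: ``sum_t |c(t)|^2``."""
    c = np.asarray(component, dtype=float)
    return float(np.sum(np.abs(c) ** 2))


def lcd_features(
    epochs: EpochSet,
    lcd_channels,
    n_layers: int = 3,
    max_sifts: int = 30,
    stop_tol: float = 0.01,
    a: float = 0.5,
    cache: dict | None = None,
    trial_indices=None,
) -> np.ndarray:
    """Per-trial energy features: channel-major, layer-minor.

    For each trial and each selected channel the signal is decomposed and the
    energies of the first ``n_layers`` components are emitted (zero-filled when
    a channel yields fewer components). With 4 channels and 3 layers this is
    the 12-element vector ``V1 = [H_11, ..., H_13, ..., H_43]``.

    ``cache`` (optional) memoizes energies per ``(trial_id, channel)``; the
    decomposition is label-free, so sharing it across cross-validation folds
    leaks nothing. ``trial_indices`` supplies stable trial ids for the cache
    when ``epochs`` is a subset of a larger set.
    """
    channels = list(lcd_channels)
    if not channels:
        raise UsageError("lcd_channels must not be empty")
    if n_layers < 1:
        raise UsageError("n_layers must be >= 1")
    if trial_indices is None:
        trial_indices = range(epochs.n_trials)
    out = np.zeros((epochs.n_trials, len(channels) * n_layers))
    for row, (t, tid) in enumerate(zip(range(epochs.n_trials), trial_indices)):
        for ci, ch in enumerate(channels):
            key = (tid, ch)
            if cache is not None and key in cache:
                energies = cache[key]
            else:
                stack = lcd_decompose(
                    epochs.data[t, ch],
                    max_components=n_layers,
                    max_sifts=max_sifts,
                    stop_tol=stop_tol,
                    a=a,
                )
                energies = np.zeros(n_layers)
                for j, comp in enumerate(stack.components[:n_layers]):
                    energies[j] = isc_energy(comp)
                if cache is not None:
                    cache[key] = energies
            out[row, ci * n_layers : (ci + 1) * n_layers] = energies
    return out
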