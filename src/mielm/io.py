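"""Data model, file readers and preprocessing for multichannel EEG trials.

The common currency of the pipeline is the :class:`EpochSet`: a labeled tensor of
trials x channels x samples (microvolts) with its sampling rate and channel
metadata. Continuous recordings are epoched around cue events ("interception":
only the imagination phase of each trial is retained) and band-pass filtered to
0.5-30 Hz, which removes slow drifts as well as EMG/ECG components above the
beta band.

Supported on-disk forms:

* ``gdf`` -- the EEG biosignal format used by the Graz BCI competition
  recordings, read through :mod:`mne` (optional dependency).
* ``mat`` -- MATLAB containers, both a plain layout (``X`` channels x time,
  ``fs``, ``event_pos``/``event_typ``) and the competition struct layout
  (``s`` time x channels plus an ``HDR`` struct with ``SampleRate`` and
  ``EVENT.POS``/``EVENT.TYP``, 1-based positions).
* ``npz`` -- the package's own flat bundle, used for recordings, epoch sets and
  fitted models alike.

Conventions fixed once, package-wide: sample indices are 0-based and epoch
windows are half-open ``[start, start + length)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.signal

from .exceptions import DataError, UsageError

logger = logging.getLogger(__name__)

__all__ = [
    "BandSpec",
    "ContinuousRecording",
    "EpochSet",
    "bandpass",
    "extract_epochs",
    "load_epochs",
    "load_recording",
    "save_epochs",
    "write_recording",
]


@dataclass
class BandSpec:
    """A pass band in Hz; must satisfy ``0 < low < high < fs/2`` for the data it filters."""

    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise UsageError(
                f"invalid band ({self.low_hz}, {self.high_hz}) Hz: need 0 < low < high"
            )

    def validate_for(self, fs: float) -> None:
        if self.high_hz >= fs / 2.0:
            raise UsageError(
                f"band edge {self.high_hz} Hz is at or above Nyquist ({fs / 2.0} Hz)"
            )


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with cue events.

    ``samples`` is channels x time (microvolts); ``events`` is a list of
    ``(sample_index, event_code)`` pairs with 0-based sample indices.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise UsageError("samples must be a channels x time matrix")
        if self.fs <= 0:
            raise UsageError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.channel_names):
            raise UsageError(
                f"{self.samples.shape[0]} channels but {len(self.channel_names)} names"
            )
        self.events = [(int(p), int(c)) for p, c in self.events]
        for pos, _ in self.events:
            if not 0 <= pos < self.n_times:
                raise UsageError(f"event at sample {pos} outside [0, {self.n_times})")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]


@dataclass
class EpochSet:
    """Labeled trials: ``data`` is trials x channels x samples, labels in ``1..n_classes``."""

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise UsageError("data must be trials x channels x samples")
        if len(self.labels) != self.data.shape[0]:
            raise UsageError("one label per trial required")
        if self.fs <= 0:
            raise UsageError("sampling rate must be positive")
        if self.data.shape[1] != len(self.channel_names):
            raise UsageError("channel_names length must match channel axis")
        n_classes = len(self.class_names)
        if self.labels.size and not (
            self.labels.min() >= 1 and self.labels.max() <= n_classes
        ):
            raise UsageError(f"labels must lie in 1..{n_classes}")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, indices) -> "EpochSet":
        """A new EpochSet restricted to the given trial indices."""
        idx = np.asarray(indices, dtype=int)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            fs=self.fs,
            channel_names=list(self.channel_names),
            class_names=list(self.class_names),
        )


# ---------------------------------------------------------------------------
# file I/O


def write_recording(rec: ContinuousRecording, path, dialect: str = "npz") -> None:
    """Write a recording as an NPZ bundle or a plain-layout MAT container."""
    path = Path(path)
    events = np.asarray(rec.events, dtype=int).reshape(-1, 2)
    if dialect == "npz":
        np.savez(
            path,
            samples=rec.samples,
            fs=float(rec.fs),
            channel_names=np.array(rec.channel_names, dtype=object),
            event_pos=events[:, 0],
            event_typ=events[:, 1],
        )
    elif dialect == "mat":
        scipy.io.savemat(
            path,
            {
                "X": rec.samples,
                "fs": float(rec.fs),
                "channel_names": np.array(rec.channel_names, dtype=object),
                "event_pos": events[:, 0],
                "event_typ": events[:, 1],
            },
        )
    else:
        raise UsageError(f"unknown write dialect {dialect!r} (use 'npz' or 'mat')")


def load_recording(path, dialect: str) -> ContinuousRecording:
    """Read a continuous recording in the named dialect (``gdf``, ``mat`` or ``npz``)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    if dialect == "gdf":
        return _load_gdf(path)
    if dialect == "mat":
        return _load_mat(path)
    if dialect == "npz":
        return _load_npz_recording(path)
    raise UsageError(f"unknown dialect {dialect!r} (expected 'gdf', 'mat' or 'npz')")


def _load_gdf(path: Path) -> ContinuousRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise DataError("reading GDF requires the optional 'mne' dependency") from exc
    try:
        raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise DataError(f"cannot parse {path} as GDF: {exc}") from exc
    # GDF stores volts; the pipeline works in microvolts throughout.
    samples = raw.get_data() * 1e6
    events = []
    for onset, _, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        try:
            code = int(desc)
        except ValueError:
            continue
        events.append((int(round(onset * raw.info["sfreq"])), code))
    return ContinuousRecording(
        samples=samples,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=events,
    )


def _load_mat(path: Path) -> ContinuousRecording:
    try:
        mat = scipy.io.loadmat(str(path), squeeze_me=True, struct_as_record=False)
    except Exception as exc:
        raise DataError(f"cannot parse {path} as MAT: {exc}") from exc
    if "X" in mat:  # plain layout: channels x time
        samples = np.atleast_2d(np.asarray(mat["X"], dtype=float))
        fs = float(np.squeeze(mat["fs"]))
        if "event_pos" not in mat or "event_typ" not in mat:
            raise DataError(f"{path}: plain MAT layout is missing its event table")
        pos = np.atleast_1d(np.asarray(mat["event_pos"], dtype=int))
        typ = np.atleast_1d(np.asarray(mat["event_typ"], dtype=int))
        names = _channel_names_from(mat.get("channel_names"), samples.shape[0])
        events = list(zip(pos.tolist(), typ.tolist()))
    elif "s" in mat:  # competition struct layout: time x channels, 1-based positions
        samples = np.atleast_2d(np.asarray(mat["s"], dtype=float)).T
        if "HDR" not in mat:
            raise DataError(f"{path}: struct MAT layout is missing the HDR record")
        hdr = mat["HDR"]
        try:
            fs = float(np.squeeze(hdr.SampleRate))
            pos = np.atleast_1d(np.asarray(hdr.EVENT.POS, dtype=int)) - 1
            typ = np.atleast_1d(np.asarray(hdr.EVENT.TYP, dtype=int))
        except AttributeError as exc:
            raise DataError(f"{path}: HDR lacks SampleRate or EVENT.POS/TYP") from exc
        names = _channel_names_from(getattr(hdr, "Label", None), samples.shape[0])
        events = list(zip(pos.tolist(), typ.tolist()))
    else:
        raise DataError(f"{path}: no recognized MAT layout (expected 'X' or 's')")
    return ContinuousRecording(samples=samples, fs=fs, channel_names=names, events=events)


def _load_npz_recording(path: Path) -> ContinuousRecording:
    try:
        with np.load(path, allow_pickle=True) as bundle:
            samples = bundle["samples"]
            fs = float(bundle["fs"])
            names = [str(n) for n in bundle["channel_names"]]
            events = list(
                zip(bundle["event_pos"].astype(int), bundle["event_typ"].astype(int))
            )
    except KeyError as exc:
        raise DataError(f"{path}: NPZ bundle is missing array {exc}") from exc
    except Exception as exc:
        raise DataError(f"cannot parse {path} as an NPZ bundle: {exc}") from exc
    return ContinuousRecording(samples=samples, fs=fs, channel_names=names, events=events)


def _channel_names_from(raw_names, n_channels: int) -> list[str]:
    if raw_names is None:
        return [f"ch{i}" for i in range(n_channels)]
    names = [str(n) for n in np.atleast_1d(np.asarray(raw_names, dtype=object))]
    if len(names) != n_channels:
        return [f"ch{i}" for i in range(n_channels)]
    return names


def save_epochs(epochs: EpochSet, path) -> None:
    """Write an EpochSet as the package's flat NPZ bundle."""
    np.savez(
        Path(path),
        data=epochs.data,
        labels=epochs.labels,
        fs=float(epochs.fs),
        channel_names=np.array(epochs.channel_names, dtype=object),
        class_names=np.array(epochs.class_names, dtype=object),
    )


def load_epochs(path) -> EpochSet:
    path = Path(path)
    if not path.exists():
        raise DataError(f"file not found: {path}")
    try:
        with np.load(path, allow_pickle=True) as bundle:
            return EpochSet(
                data=bundle["data"],
                labels=bundle["labels"],
                fs=float(bundle["fs"]),
                channel_names=[str(n) for n in bundle["channel_names"]],
                class_names=[str(n) for n in bundle["class_names"]],
            )
    except KeyError as exc:
        raise DataError(f"{path}: epoch bundle is missing array {exc}") from exc


# ---------------------------------------------------------------------------
# epoching and filtering


def extract_epochs(
    rec: ContinuousRecording,
    class_codes: dict[int, int],
    window_start_s: float = 0.5,
    window_len_s: float = 3.0,
    class_names: list[str] | None = None,
) -> EpochSet:
    """Cut one fixed-length trial per cue event, keeping only the imagination phase.

    Trial ``t`` for an event at sample ``e`` spans
    ``[e + window_start_s * fs, e + (window_start_s + window_len_s) * fs)``.
    Events whose window does not fit inside the recording are dropped with a
    warning; events whose code is not in ``class_codes`` are ignored.
    """
    if window_len_s <= 0:
        raise UsageError("window_len_s must be positive")
    offset = int(round(window_start_s * rec.fs))
    length = int(round(window_len_s * rec.fs))
    trials, labels, dropped = [], [], 0
    for pos, code in rec.events:
        if code not in class_codes:
            continue
        start = pos + offset
        stop = start + length
        if start < 0 or stop > rec.n_times:
            dropped += 1
            continue
        trials.append(rec.samples[:, start:stop])
        labels.append(class_codes[code])
    if dropped:
        logger.warning("dropped %d event(s) whose window exceeded the recording", dropped)
    if not trials:
        raise DataError("empty epoch set: no usable events for the requested window")
    if class_names is None:
        class_names = [f"class{c}" for c in sorted(set(class_codes.values()))]
    return EpochSet(
        data=np.stack(trials),
        labels=np.asarray(labels, dtype=int),
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        class_names=class_names,
    )


def bandpass(epochs: EpochSet, band: BandSpec, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of every channel of every trial.

    The filter is applied forward and backward (``sosfiltfilt``), so the pass
    band is attenuated twice as steeply as a single pass of the given order and
    no phase distortion is introduced -- ERD/ERS latencies are preserved.
    """
    band.validate_for(epochs.fs)
    sos = scipy.signal.butter(
        order, [band.low_hz, band.high_hz], btype="bandpass", fs=epochs.fs, output="sos"
    )
    # even reflection with generous padding: the low corner's settling time can
    # approach the trial length, and odd reflection of oscillatory trials kicks
    # the near-DC poles into a slow in-band transient
    padlen = min(epochs.n_samples - 1, int(3 * epochs.fs / band.low_hz))
    filtered = scipy.signal.sosfiltfilt(
        sos, epochs.data, axis=-1, padtype="even", padlen=padlen
    )
    return EpochSet(
        data=filtered,
        labels=epochs.labels.copy(),
        fs=epochs.fs,
        channel_names=list(epochs.channel_names),
        class_names=list(epochs.class_names),
    )
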