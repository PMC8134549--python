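"""Seeded generator of synthetic motor-imagery trials with ERD structure.

Imagining a limb movement attenuates the mu (8-13 Hz) and beta (14-30 Hz)
rhythms over the sensorimotor cortex contralateral to the imagined limb
(event-related desynchronization, ERD). The generator embodies exactly that
class signature: every channel of every trial carries 1/f-shaped broadband
noise plus one mu-band and one beta-band oscillation with random frequency and
phase; on the channels designated informative for the trial's class the
oscillation amplitudes are multiplied by ``(1 - erd_depth)``. Class membership
is therefore encoded purely as a band-power decrease on a class-specific
channel subset -- the cue the selection, LCD, CSP and ELM stages must recover.

ERD is modeled as a sustained amplitude scaling over the whole trial (the
epoching step is assumed to retain only the imagination phase); an onset ramp
can be enabled for experiments on time-locked dynamics. Volume conduction,
eye-blink and EMG artifacts are deliberately not simulated.

Default scales: per-channel noise RMS is 1 (arbitrary microvolt units), each
oscillation's RMS is ``snr`` (default 1.0), and ``erd_depth = 0.5`` halves the
informative-channel amplitudes, i.e. a 4x band-power contrast before the noise
floor is added. Under these defaults a simple band-power threshold classifier
scores around 0.9 on two balanced classes, leaving the pipeline a realistic,
non-saturated problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import UsageError
from .io import ContinuousRecording, EpochSet

__all__ = ["SynthConfig", "generate_mi_dataset", "generate_mi_recording", "generate_two_tone"]


def _default_informative(n_classes: int, n_channels: int) -> dict[int, list[int]]:
    width = min(4 if n_classes == 2 else 2, n_channels // n_classes)
    if width < 1:
        raise UsageError("montage too small for the default informative map")
    return {
        cls: list(range((cls - 1) * width, cls * width))
        for cls in range(1, n_classes + 1)
    }


@dataclass
class SynthConfig:
    """Study conditions for one synthetic dataset."""

    n_trials_per_class: int = 60
    n_channels: int = 22
    n_classes: int = 2
    fs: float = 250.0
    trial_len_s: float = 3.0
    mu_band: tuple[float, float] = (8.0, 13.0)
    beta_band: tuple[float, float] = (14.0, 30.0)
    erd_depth: float = 0.5
    informative_channels: dict[int, list[int]] | None = None
    noise_exponent: float = 1.0  # power ~ 1/f^alpha
    white_floor_db: float = -20.0  # white noise power relative to the 1/f part
    snr: float = 1.0  # oscillation RMS relative to unit noise RMS
    onset_ramp_s: float = 0.0  # >0 ramps the ERD in over this many seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth < 1.0:
            raise UsageError("erd_depth must lie in [0, 1)")
        if self.fs <= 0 or self.trial_len_s <= 0:
            raise UsageError("fs and trial_len_s must be positive")
        if self.n_classes < 2:
            raise UsageError("need at least 2 classes")
        if self.n_trials_per_class < 1 or self.n_channels < 1:
            raise UsageError("need at least 1 trial per class and 1 channel")
        if self.informative_channels is None:
            self.informative_channels = _default_informative(
                self.n_classes, self.n_channels
            )
        for cls, chans in self.informative_channels.items():
            for c in chans:
                if not 0 <= c < self.n_channels:
                    raise UsageError(f"informative channel {c} (class {cls}) out of range")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_len_s * self.fs))


def _pink_noise(rng: np.random.Generator, n: int, fs: float, alpha: float) -> np.ndarray:
    """1/f^alpha-shaped Gaussian noise, unit RMS."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-alpha / 2.0)
    spectrum = shaping * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    noise = np.fft.irfft(spectrum, n=n)
    return noise / np.sqrt(np.mean(noise**2))


def _oscillation(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-amplitude sinusoid at a random in-band frequency and phase."""
    f = rng.uniform(*band)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.arange(n) / fs
    return np.sin(2.0 * np.pi * f * t + phase)


def generate_mi_dataset(cfg: SynthConfig) -> EpochSet:
    """Generate a balanced, seeded EpochSet of synthetic motor-imagery trials."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    labels = np.repeat(np.arange(1, cfg.n_classes + 1), cfg.n_trials_per_class)
    rng.shuffle(labels)
    white_amp = 10.0 ** (cfg.white_floor_db / 20.0)
    osc_amp = cfg.snr * np.sqrt(2.0)  # sinusoid of amplitude A has RMS A/sqrt(2)
    ramp = np.ones(n)
    if cfg.onset_ramp_s > 0:
        k = min(n, int(round(cfg.onset_ramp_s * cfg.fs)))
        ramp[:k] = np.linspace(0.0, 1.0, k)
    data = np.empty((labels.size, cfg.n_channels, n))
    for t, cls in enumerate(labels):
        informative = set(cfg.informative_channels[int(cls)])
        for ch in range(cfg.n_channels):
            noise = _pink_noise(rng, n, cfg.fs, cfg.noise_exponent)
            noise += white_amp * rng.standard_normal(n)
            mu = _oscillation(rng, n, cfg.fs, cfg.mu_band)
            beta = _oscillation(rng, n, cfg.fs, cfg.beta_band)
            amp = osc_amp
            if ch in informative:
                # ERD: attenuated rhythms on the class's contralateral channels
                scale = 1.0 - cfg.erd_depth * ramp
                data[t, ch] = noise + amp * scale * (mu + beta)
            else:
                data[t, ch] = noise + amp * (mu + beta)
    return EpochSet(
        data=data,
        labels=labels,
        fs=cfg.fs,
        channel_names=[f"ch{i}" for i in range(cfg.n_channels)],
        class_names=[f"class{c}" for c in range(1, cfg.n_classes + 1)],
    )


def generate_mi_recording(
    cfg: SynthConfig, gap_s: float = 1.0
) -> ContinuousRecording:
    """The same trials laid out as one continuous recording with cue events.

    Trials are separated by ``gap_s`` seconds of noise; each trial start is
    marked by an event whose code equals the class id. Intended for exercising
    the file readers and the epoching step without external downloads.
    """
    epochs = generate_mi_dataset(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    n_gap = int(round(gap_s * cfg.fs))
    n = epochs.n_samples
    total = epochs.n_trials * (n + n_gap) + n_gap
    samples = np.empty((cfg.n_channels, total))
    for ch in range(cfg.n_channels):
        samples[ch] = _pink_noise(rng, total, cfg.fs, cfg.noise_exponent)
    events = []
    pos = n_gap
    for t in range(epochs.n_trials):
        samples[:, pos : pos + n] = epochs.data[t]
        events.append((pos, int(epochs.labels[t])))
        pos += n + n_gap
    return ContinuousRecording(
        samples=samples,
        fs=cfg.fs,
        channel_names=list(epochs.channel_names),
        events=events,
    )


def generate_two_tone(
    f1: float, f2: float, fs: float, dur_s: float, amps: tuple[float, float] = (1.0, 1.0)
) -> np.ndarray:
    """Sum of two zero-phase sinusoids -- the standard decomposition fixture."""
    if f1 == f2:
        raise UsageError("the two tone frequencies must differ")
    if not (0 < f1 < fs / 2 and 0 < f2 < fs / 2):
        raise UsageError("tone frequencies must lie in (0, fs/2)")
    if dur_s <= 0:
        raise UsageError("duration must be positive")
    t = np.arange(int(round(dur_s * fs))) / fs
    return amps[0] * np.sin(2 * np.pi * f1 * t) + amps[1] * np.sin(2 * np.pi * f2 * t)
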