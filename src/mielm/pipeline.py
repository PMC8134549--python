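"""End-to-end motor-imagery recognition: configuration, model and results objects.

The user-facing surface follows the fit/results idiom of statistical modelling
libraries:

>>> from mielm import MotorImageryELM, PipelineConfig
>>> model = MotorImageryELM(epochs)          # epochs: a labeled EpochSet
>>> cv = model.cross_validate(seed=7)        # repeated stratified 5-fold CV
>>> print(cv.summary())
>>> res = model.fit(seed=7)                  # train on all trials
>>> labels, raw = res.predict(new_epochs)

One fitted pipeline consists of: the 0.5-30 Hz zero-phase band-pass, the
contribution-rate channel split (LCD branch vs CSP branch), the per-trial LCD
energy block V1 and CSP log-variance block V2, their unit-norm serial fusion
``V = [V1, V2]``, per-feature standardization, and the pseudoinverse-trained
ELM. Everything with fitted state is learned from training trials only;
cross-validation refits the whole chain per fold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import csp as _csp
from . import elm as _elm
from . import evaluation as _evaluation
from .exceptions import DataError, UsageError
from .fusion import ChannelSplit, fuse, rank_channels, split_channels
from .io import BandSpec, EpochSet, bandpass, load_epochs
from .lcd import lcd_features

logger = logging.getLogger(__name__)

__all__ = [
    "MotorImageryELM",
    "MotorImageryResults",
    "PipelineConfig",
    "classify_trials",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Every tunable of the recognition chain, serializable to YAML.

    The defaults encode the standard configuration: 0.5-30 Hz preprocessing
    band, 8-30 Hz selection band, 4 LCD channels x 3 ISC layers (12 energies),
    m = 2 CSP filter pairs, unit-norm serial fusion, sigmoid ELM with
    ``min(100, n_train)`` hidden units, and 5x5-fold cross-validation.
    """

    band: tuple[float, float] = (0.5, 30.0)
    select_band: tuple[float, float] = (8.0, 30.0)
    window_start_s: float = 0.5
    window_len_s: float = 3.0
    n_lcd: int = 4
    n_layers: int = 3
    m_pairs: int = 2
    n_hidden: int | None = None  # None -> min(100, n_train)
    activation: str = "sigmoid"
    normalization: str = "norm"  # "norm" (blockwise unit norm) | "sign" (literal x/|x|)
    feature_mode: str = "fused"  # "fused" | "lcd" | "csp"
    standardize: bool = True
    lcd_a: float = 0.5
    lcd_max_sifts: int = 30
    lcd_stop_tol: float = 0.01
    shrinkage: float = 0.0
    allow_channel_overlap: bool = True
    F: int = 5
    repetitions: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in ("fused", "lcd", "csp"):
            raise UsageError(f"unknown feature_mode {self.feature_mode!r}")
        if self.normalization not in ("norm", "sign"):
            raise UsageError(f"unknown normalization {self.normalization!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(d["band"])
        d["select_band"] = list(d["select_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("band", "select_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class _FittedFold:
    """Trained state of one pipeline fit (one CV fold or the full set)."""

    config: PipelineConfig
    split: ChannelSplit
    csp_model: _csp.CSPModel
    scaler_mean: np.ndarray
    scaler_std: np.ndarray
    elm_model: _elm.ELMModel
    channel_names: list[str]
    class_names: list[str]
    fs: float


def _raw_blocks(
    fitted_split: ChannelSplit,
    csp_model: _csp.CSPModel,
    epochs: EpochSet,
    indices,
    config: PipelineConfig,
    lcd_cache: dict | None,
) -> tuple[np.ndarray, np.ndarray]:
    idx = np.asarray(indices, dtype=int)
    sub = epochs.subset(idx)
    v1 = lcd_features(
        sub,
        fitted_split.lcd_channels,
        n_layers=config.n_layers,
        max_sifts=config.lcd_max_sifts,
        stop_tol=config.lcd_stop_tol,
        a=config.lcd_a,
        cache=lcd_cache,
        trial_indices=idx,
    )
    v2 = csp_model.transform(sub)
    return v1, v2


def _fused_rows(v1: np.ndarray, v2: np.ndarray, config: PipelineConfig) -> np.ndarray:
    rows = []
    for i in range(v1.shape[0]):
        if config.feature_mode == "fused":
            rows.append(fuse(v1[i], v2[i], mode=config.normalization).v)
        elif config.feature_mode == "lcd":
            rows.append(fuse(v1[i], np.zeros(0), mode=config.normalization).v)
        else:  # csp only
            rows.append(fuse(np.zeros(0), v2[i], mode=config.normalization).v)
    return np.vstack(rows)


def _fit_on_indices(
    epochs: EpochSet,
    train_idx,
    config: PipelineConfig,
    elm_seed: int,
    lcd_cache: dict | None = None,
) -> _FittedFold:
    """Fit every stage with state on the training trials only."""
    train_idx = np.asarray(train_idx, dtype=int)
    train = epochs.subset(train_idx)
    scores = rank_channels(train, BandSpec(*config.select_band))
    split = split_channels(scores, config.n_lcd)
    if split.overlap and not config.allow_channel_overlap:
        raise UsageError(
            f"{epochs.n_channels} channels cannot supply {config.n_lcd} LCD leads "
            "plus a CSP set; set allow_channel_overlap=True to use all channels "
            "for both branches"
        )
    csp_model = _csp.fit_csp(
        train, split.csp_channels, m=config.m_pairs, shrinkage=config.shrinkage
    )
    v1, v2 = _raw_blocks(split, csp_model, epochs, train_idx, config, lcd_cache)
    X = _fused_rows(v1, v2, config)
    if config.standardize:
        mean = X.mean(axis=0)
        std = np.maximum(X.std(axis=0), 1e-12)
    else:
        mean = np.zeros(X.shape[1])
        std = np.ones(X.shape[1])
    Xs = (X - mean) / std
    n_hidden = config.n_hidden if config.n_hidden is not None else min(100, X.shape[0])
    elm_model = _elm.train_elm(
        Xs,
        train.labels,
        n_hidden=n_hidden,
        seed=elm_seed,
        activation=config.activation,
        class_names=list(epochs.class_names),
    )
    return _FittedFold(
        config=config,
        split=split,
        csp_model=csp_model,
        scaler_mean=mean,
        scaler_std=std,
        elm_model=elm_model,
        channel_names=list(epochs.channel_names),
        class_names=list(epochs.class_names),
        fs=epochs.fs,
    )


def _features_on_indices(
    fitted: _FittedFold, epochs: EpochSet, indices, lcd_cache: dict | None = None
) -> np.ndarray:
    v1, v2 = _raw_blocks(
        fitted.split, fitted.csp_model, epochs, indices, fitted.config, lcd_cache
    )
    X = _fused_rows(v1, v2, fitted.config)
    return (X - fitted.scaler_mean) / fitted.scaler_std


def _predict_on_indices(
    fitted: _FittedFold, epochs: EpochSet, indices, lcd_cache: dict | None = None
) -> np.ndarray:
    Xs = _features_on_indices(fitted, epochs, indices, lcd_cache)
    pred, _ = _elm.predict(fitted.elm_model, Xs)
    return pred


class MotorImageryELM:
    """Motor-imagery intention recognition model over a labeled EpochSet.

    Construction applies the preprocessing band-pass; all supervised fitting
    happens in :meth:`fit` / :meth:`cross_validate`.

    Parameters
    ----------
    epochs : EpochSet
        Labeled trials (already epoched to the imagination window).
    config : PipelineConfig, optional
        Full configuration; keyword overrides are applied on top.
    """

    def __init__(self, epochs: EpochSet, config: PipelineConfig | None = None, **overrides):
        if config is None:
            config = PipelineConfig()
        if overrides:
            config = PipelineConfig.from_dict({**config.to_dict(), **overrides})
        if not config.allow_channel_overlap and epochs.n_channels <= config.n_lcd + 1:
            raise UsageError(
                f"{epochs.n_channels} channels cannot supply {config.n_lcd} LCD leads "
                "plus a CSP set (strict mode)"
            )
        self.config = config
        self.raw_epochs = epochs
        self.epochs = bandpass(epochs, BandSpec(*config.band))

    @classmethod
    def from_bundle(cls, path, config: PipelineConfig | None = None, **overrides):
        """Build the model from an epoch NPZ bundle on disk."""
        return cls(load_epochs(path), config=config, **overrides)

    def fit(self, seed: int | None = None) -> "MotorImageryResults":
        """Train the full chain on every trial; returns the results object."""
        if seed is None:
            seed = self.config.seed
        fitted = _fit_on_indices(
            self.epochs, np.arange(self.epochs.n_trials), self.config, int(seed)
        )
        return MotorImageryResults(fitted)

    def cross_validate(
        self,
        F: int | None = None,
        repetitions: int | None = None,
        seed: int | None = None,
    ) -> _evaluation.EvalResult:
        """Repeated stratified F-fold cross-validation of the full chain."""
        return _evaluation.cross_validate(
            self.epochs,
            self.config,
            F=F if F is not None else self.config.F,
            repetitions=repetitions if repetitions is not None else self.config.repetitions,
            seed=seed if seed is not None else self.config.seed,
        )


class MotorImageryResults:
    """A trained recognition chain: transforms + classifier, ready to predict."""

    def __init__(self, fitted: _FittedFold):
        self._fitted = fitted
        self.config = fitted.config
        self.channel_split = fitted.split
        self.csp_model = fitted.csp_model
        self.elm_model = fitted.elm_model
        self.class_names = fitted.class_names

    def predict(self, epochs: EpochSet) -> tuple[np.ndarray, np.ndarray]:
        """Predicted class ids and raw ELM outputs for new (unfiltered) epochs."""
        if epochs.n_channels != len(self._fitted.channel_names):
            raise DataError(
                f"epochs have {epochs.n_channels} channels, model expects "
                f"{len(self._fitted.channel_names)}"
            )
        filtered = bandpass(epochs, BandSpec(*self.config.band))
        Xs = _features_on_indices(self._fitted, filtered, np.arange(epochs.n_trials))
        return _elm.predict(self.elm_model, Xs)

    def summary(self) -> str:
        f = self._fitted
        lines = [
            "Fitted motor-imagery recognition chain",
            "======================================",
            f"channels             : {len(f.channel_names)}",
            f"LCD channels         : {f.split.lcd_channels}"
            + (" (overlap fallback)" if f.split.overlap else ""),
            f"CSP channels         : {len(f.split.csp_channels)}"
            f" -> {f.csp_model.n_filters} filters (m={f.csp_model.n_pairs_per_problem})",
            f"feature mode         : {f.config.feature_mode}"
            f" ({f.config.normalization} normalization)",
            f"feature length       : {f.scaler_mean.size}",
            f"ELM hidden units     : {f.elm_model.n_hidden} ({f.elm_model.activation})",
            f"classes              : {f.class_names}",
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize the fitted chain to a flat NPZ bundle."""
        f = self._fitted
        np.savez(
            Path(path),
            config_json=json.dumps(f.config.to_dict(), sort_keys=True),
            lcd_channels=np.asarray(f.split.lcd_channels, dtype=int),
            csp_channels=np.asarray(f.split.csp_channels, dtype=int),
            channel_scores=f.split.scores,
            overlap=np.asarray(f.split.overlap),
            csp_filters=f.csp_model.filters,
            csp_pairs=np.asarray(f.csp_model.class_pairs, dtype=int),
            csp_channel_indices=f.csp_model.channel_indices,
            scaler_mean=f.scaler_mean,
            scaler_std=f.scaler_std,
            elm_input_weights=f.elm_model.input_weights,
            elm_biases=f.elm_model.biases,
            elm_output_weights=f.elm_model.output_weights,
            elm_activation=f.elm_model.activation,
            elm_seed=f.elm_model.seed,
            elm_class_labels=f.elm_model.class_labels,
            channel_names=np.array(f.channel_names, dtype=object),
            class_names=np.array(f.class_names, dtype=object),
            fs=f.fs,
        )

    @classmethod
    def load(cls, path) -> "MotorImageryResults":
        path = Path(path)
        if not path.exists():
            raise DataError(f"model bundle not found: {path}")
        with np.load(path, allow_pickle=True) as b:
            config = PipelineConfig.from_dict(json.loads(str(b["config_json"])))
            split = ChannelSplit(
                lcd_channels=[int(i) for i in b["lcd_channels"]],
                csp_channels=[int(i) for i in b["csp_channels"]],
                scores=b["channel_scores"],
                overlap=bool(b["overlap"]),
            )
            channel_names = [str(n) for n in b["channel_names"]]
            csp_model = _csp.CSPModel(
                filters=b["csp_filters"],
                class_pairs=[tuple(int(v) for v in row) for row in b["csp_pairs"]],
                n_pairs_per_problem=config.m_pairs,
                channel_names=[channel_names[i] for i in b["csp_channel_indices"]],
                channel_indices=b["csp_channel_indices"],
            )
            elm_model = _elm.ELMModel(
                input_weights=b["elm_input_weights"],
                biases=b["elm_biases"],
                output_weights=b["elm_output_weights"],
                activation=str(b["elm_activation"]),
                seed=int(b["elm_seed"]),
                class_labels=b["elm_class_labels"],
                class_names=[str(n) for n in b["class_names"]],
            )
            fitted = _FittedFold(
                config=config,
                split=split,
                csp_model=csp_model,
                scaler_mean=b["scaler_mean"],
                scaler_std=b["scaler_std"],
                elm_model=elm_model,
                channel_names=channel_names,
                class_names=[str(n) for n in b["class_names"]],
                fs=float(b["fs"]),
            )
        return cls(fitted)


# ---------------------------------------------------------------------------
# script-level entry points (used by the CLI)


def run_pipeline(
    epochs: EpochSet, config: PipelineConfig, outdir, seed: int | None = None
) -> _evaluation.EvalResult:
    """Cross-validate the chain and write results + reproducibility manifest.

    Writes ``results.tsv`` (one row per fold plus a summary block) and
    ``manifest.json`` (config dump, config hash, seed, package version).
    Outputs contain no timestamps: a (config, seed) pair reproduces them
    byte-for-byte.
    """
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.seed
    model = MotorImageryELM(epochs, config)
    result = model.cross_validate(seed=seed)
    lines = ["repetition\tfold\tacc\tkappa"]
    for rep, fold, a, k in result.to_rows():
        lines.append(f"{rep}\t{fold}\t{a:.6f}\t{k:.6f}")
    lines += [
        "",
        f"# mean_acc\t{result.mean_acc:.6f}",
        f"# mean_kappa\t{result.mean_kappa:.6f}",
        f"# config_hash\t{config.config_hash()}",
    ]
    (outdir / "results.tsv").write_text("\n".join(lines) + "\n")
    manifest = {
        "package": "mielm",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_trials": epochs.n_trials,
        "n_channels": epochs.n_channels,
        "n_classes": epochs.n_classes,
        "mean_acc": round(result.mean_acc, 6),
        "mean_kappa": round(result.mean_kappa, 6),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return result


def classify_trials(model_path, epochs_path, out_path=None) -> list[tuple[int, np.ndarray]]:
    """Apply a saved model bundle to an epoch bundle; one (class, raw outputs) per trial."""
    results = MotorImageryResults.load(model_path)
    epochs = load_epochs(epochs_path)
    if epochs.n_trials == 0:
        logger.warning("epoch bundle %s holds no trials; empty output", epochs_path)
        rows: list[tuple[int, np.ndarray]] = []
    else:
        pred, raw = results.predict(epochs)
        rows = [(int(p), raw[i]) for i, p in enumerate(pred)]
    if out_path is not None:
        lines = ["trial\tpredicted_class\traw_outputs"]
        for i, (p, r) in enumerate(rows):
            lines.append(f"{i}\t{p}\t" + ",".join(f"{v:.6f}" for v in r))
        Path(out_path).write_text("\n".join(lines) + "\n")
    return rows
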