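"""Repeated stratified k-fold cross-validation, accuracy and the kappa coefficient.

The evaluation protocol: the trial set is split into ``F`` stratified folds
(default 5); each fold in turn is held out while the *entire* pipeline --
channel ranking, LCD energies, CSP filters, feature standardization and the ELM
-- is refitted on the remaining folds, so no stage ever sees test labels. The
whole procedure is repeated (default 5 times) with fresh fold assignments, and
the reported accuracy and kappa are the means over all ``F x repetitions``
folds:

    A_bar = (1/F) sum_i acc_i        K_bar = (1/F) sum_i K_i

with the chance-corrected per-fold kappa ``K_i = (acc_i - 1/N) / (1 - 1/N)``
for ``N`` classes. Kappa is computed per fold and then averaged (the literal
reading of the averaging formulas), not obtained by applying the kappa formula
to the mean accuracy; the two differ in general.

All randomness (fold shuffles, ELM weights) derives from one master seed via
numpy seed-sequence spawning, so a result is reproducible from its seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .exceptions import DataError, UsageError
from .io import EpochSet

__all__ = ["EvalResult", "cross_validate", "kappa", "stratified_folds"]


def kappa(acc: float, n_classes: int) -> float:
    """Chance-corrected accuracy ``(acc - 1/N) / (1 - 1/N)``.

    1 at perfect accuracy, 0 at chance level ``1/N``; negative for
    below-chance accuracy (the coefficient's range is [0, 1] only at or above
    chance).
    """
    if n_classes < 2:
        raise UsageError("kappa needs at least 2 classes")
    if not 0.0 <= acc <= 1.0:
        raise UsageError("accuracy must lie in [0, 1]")
    chance = 1.0 / n_classes
    return (acc - chance) / (1.0 - chance)


def stratified_folds(labels, F: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified partition into ``F`` disjoint test folds.

    Per-class counts across folds differ by at most 1; the union of the test
    folds is the full index set.
    """
    labels = np.asarray(labels, dtype=int)
    if F < 2:
        raise UsageError("F must be >= 2")
    for cls in np.unique(labels):
        count = int(np.sum(labels == cls))
        if count < F:
            raise DataError(f"class {cls} has only {count} trials, fewer than F={F}")
    splitter = StratifiedKFold(n_splits=F, shuffle=True, random_state=int(seed))
    return [
        (train.copy(), test.copy())
        for train, test in splitter.split(np.zeros(labels.size), labels)
    ]


@dataclass
class EvalResult:
    """Per-fold accuracies/kappas with their averages and the pooled confusion matrix."""

    fold_acc: list[float]
    fold_kappa: list[float]
    F: int
    repetitions: int
    n_classes: int
    confusion: np.ndarray  # true x predicted counts over all folds
    config: dict = field(default_factory=dict)

    @property
    def mean_acc(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.fold_kappa))

    def repetition_means(self) -> np.ndarray:
        """Mean accuracy of each repetition (F folds each)."""
        return np.asarray(self.fold_acc).reshape(self.repetitions, self.F).mean(axis=1)

    def to_rows(self) -> list[tuple[int, int, float, float]]:
        """(repetition, fold, acc, kappa) rows in evaluation order."""
        rows = []
        for i, (a, k) in enumerate(zip(self.fold_acc, self.fold_kappa)):
            rows.append((i // self.F, i % self.F, a, k))
        return rows

    def summary(self) -> str:
        lines = [
            "Cross-validation summary",
            "========================",
            f"folds per repetition : {self.F}",
            f"repetitions          : {self.repetitions}",
            f"classes              : {self.n_classes}",
            f"mean accuracy  A_bar : {self.mean_acc:.4f}",
            f"mean kappa     K_bar : {self.mean_kappa:.4f}",
            f"accuracy sd over folds: {np.std(self.fold_acc):.4f}",
            "",
            "repetition  fold   acc     kappa",
        ]
        for rep, fold, a, k in self.to_rows():
            lines.append(f"{rep:>10d}  {fold:>4d}  {a:.4f}  {k:+.4f}")
        lines.append("")
        lines.append("confusion matrix (rows = true class):")
        for r in range(self.n_classes):
            lines.append("  " + "  ".join(f"{int(v):>5d}" for v in self.confusion[r]))
        return "\n".join(lines)


def cross_validate(
    epochs: EpochSet, config=None, F: int = 5, repetitions: int = 5, seed: int = 0
) -> EvalResult:
    """Run the full pipeline under repeated stratified F-fold cross-validation.

    ``config`` is a :class:`~mielm.pipeline.PipelineConfig` (or None for
    defaults). Every stage with fitted state is refitted on each training fold.
    """
    from .pipeline import PipelineConfig, _fit_on_indices, _predict_on_indices

    if config is None:
        config = PipelineConfig()
    labels = epochs.labels
    n_classes = epochs.n_classes
    master = np.random.SeedSequence(seed)
    rep_seeds = master.spawn(repetitions)
    fold_acc: list[float] = []
    fold_kappa: list[float] = []
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    lcd_cache: dict = {}  # label-free per-(trial, channel) energies, shared across folds
    for rep, rep_ss in enumerate(rep_seeds):
        states = rep_ss.generate_state(2 * F + 1)
        folds = stratified_folds(labels, F, int(states[0] % (2**31 - 1)))
        for fold_id, (train_idx, test_idx) in enumerate(folds):
            elm_seed = int(states[1 + fold_id] % (2**31 - 1))
            try:
                fitted = _fit_on_indices(epochs, train_idx, config, elm_seed, lcd_cache)
                pred = _predict_on_indices(fitted, epochs, test_idx, lcd_cache)
            except Exception as exc:
                raise type(exc)(
                    f"repetition {rep}, fold {fold_id}: {exc}"
                ) from exc
            truth = labels[test_idx]
            acc = float(np.mean(pred == truth))
            fold_acc.append(acc)
            fold_kappa.append(kappa(acc, n_classes))
            for t, p in zip(truth, pred):
                confusion[t - 1, p - 1] += 1
    return EvalResult(
        fold_acc=fold_acc,
        fold_kappa=fold_kappa,
        F=F,
        repetitions=repetitions,
        n_classes=n_classes,
        confusion=confusion,
        config=config.to_dict() if hasattr(config, "to_dict") else {},
    )
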