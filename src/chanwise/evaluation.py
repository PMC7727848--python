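"""Cross-validation, confusion matrices and the L/K/N hyperparameter sweep.

Two fold-assignment modes ship side by side.  ``random_mixed`` reproduces
the evaluation protocol in which windows from the same subject and the same
stimulus can land in both train and test — it leaks subject identity and
inflates accuracy.  ``subject_wise`` keeps whole subjects out of the
training folds and is the honest cross-subject estimate.  The default is
``random_mixed`` with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .features import (
    LabeledExample,
    WindowingParams,
    examples_to_arrays,
    make_training_examples,
)
from .io import EmotionLabel, RawRecording
from .model import ModelConfig, TrainConfig, build_model, predict_batch, train

__all__ = [
    "FoldAssignment",
    "CVResult",
    "kfold_split",
    "cross_validate",
    "sweep_hyperparameters",
    "extract_examples",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldAssignment:
    fold_of_example: np.ndarray  # int fold id per example
    k: int
    mode: str
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold_of_example, minlength=self.k)
        if len(counts) != self.k or (counts == 0).any():
            raise ValueError("folds must form a partition with no empty fold")

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_example == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_example != fold)


@dataclass(frozen=True)
class CVResult:
    per_fold_accuracy: tuple[float, ...]
    mean_accuracy: float
    confusion: np.ndarray  # class x class counts pooled over folds
    config: dict

    def confusion_frame(self, class_names: tuple[str, ...]) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=class_names, columns=class_names)


def kfold_split(
    examples: list[LabeledExample],
    k: int,
    mode: str = "random_mixed",
    seed: int = 0,
) -> FoldAssignment:
    """Assign examples to ``k`` folds.

    ``random_mixed`` shuffles example indices and deals them round-robin.
    ``subject_wise`` shuffles subjects and deals whole subjects round-robin,
    so no subject ever appears in two folds.
    """
    n = len(examples)
    if n < k:
        raise ValueError(f"cannot split {n} examples into {k} folds")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    if mode == "random_mixed":
        logger.warning(
            "random_mixed folds let the same subject and stimulus appear in "
            "train and test; use subject_wise for an honest cross-subject "
            "estimate"
        )
        order = rng.permutation(n)
        folds[order] = np.arange(n) % k
    elif mode == "subject_wise":
        subjects = sorted({ex.subject_id for ex in examples})
        if len(subjects) < k:
            raise ValueError(
                f"subject_wise split needs >= {k} subjects, got {len(subjects)}"
            )
        order = rng.permutation(len(subjects))
        fold_of_subject = {
            subjects[idx]: pos % k for pos, idx in enumerate(order)
        }
        folds[:] = [fold_of_subject[ex.subject_id] for ex in examples]
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    return FoldAssignment(fold_of_example=folds, k=k, mode=mode, seed=seed)


def cross_validate(
    examples: list[LabeledExample],
    model_config: ModelConfig,
    train_config: TrainConfig,
    folds: FoldAssignment,
    train_fn=None,
    predict_fn=None,
) -> CVResult:
    """Train a fresh model per fold and aggregate accuracy and confusion.

    ``train_fn(X, y, fold) -> model`` and ``predict_fn(model, X) -> probs``
    may be injected (e.g. stub classifiers in tests); the defaults build and
    train the stacked-LSTM classifier with a per-fold derived seed.
    """
    X, y = examples_to_arrays(examples)
    n_classes = model_config.num_classes
    if train_fn is None:

        def train_fn(Xtr, ytr, fold):
            model = build_model(model_config, seed=train_config.seed + 1000 * fold)
            cfg = replace(train_config, seed=train_config.seed + 1000 * fold)
            return train(model, (Xtr, ytr), cfg)

    if predict_fn is None:
        predict_fn = predict_batch

    accs = []
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for fold in range(folds.k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        model = train_fn(X[tr], y[tr], fold)
        pred = np.asarray(predict_fn(model, X[te])).argmax(axis=1)
        accs.append(float((pred == y[te]).mean()))
        np.add.at(confusion, (y[te], pred), 1)
    return CVResult(
        per_fold_accuracy=tuple(accs),
        mean_accuracy=float(np.mean(accs)),
        confusion=confusion,
        config={
            "k": folds.k,
            "mode": folds.mode,
            "split_seed": folds.seed,
            "model": vars(model_config).copy(),
            "train": vars(train_config).copy(),
        },
    )


def extract_examples(
    dataset: list[tuple[RawRecording, EmotionLabel]], params: WindowingParams
) -> list[LabeledExample]:
    """Sliding-window augmentation over every trial; trials shorter than
    one window are skipped with a warning."""
    out: list[LabeledExample] = []
    for rec, label in dataset:
        if rec.n_samples < params.window_samples:
            logger.warning(
                "trial %s/%s (%d samples) shorter than one window (%d); skipped",
                rec.subject_id,
                rec.trial_id,
                rec.n_samples,
                params.window_samples,
            )
            continue
        out.extend(make_training_examples(rec, params, label))
    return out


def sweep_hyperparameters(
    dataset: list[tuple[RawRecording, EmotionLabel]],
    L_values=(),
    K_values=(),
    N_values=(),
    fixed: WindowingParams = WindowingParams(),
    model_config: ModelConfig | None = None,
    train_config: TrainConfig = TrainConfig(),
    k: int = 10,
    mode: str = "random_mixed",
) -> pd.DataFrame:
    """One-at-a-time sweep over L, K and N around ``fixed``.

    For each setting, features are re-extracted and cross-validation re-run.
    Settings whose window exceeds every trial are reported as skipped rows,
    not errors.  Returns a tidy frame with columns
    ``varied, L, K, N, mean_accuracy, status``.
    """
    settings = (
        [("L", replace(fixed, L=v)) for v in L_values]
        + [("K", replace(fixed, K=v)) for v in K_values]
        + [("N", replace(fixed, N=v)) for v in N_values]
    )
    rows = []
    for varied, params in settings:
        row = {"varied": varied, "L": params.L, "K": params.K, "N": params.N}
        examples = extract_examples(dataset, params)
        if len(examples) < k:
            rows.append({**row, "mean_accuracy": np.nan, "status": "skipped"})
            continue
        C = examples[0].sequence.C
        mc = model_config or ModelConfig(
            input_dim=C * (C - 1) // 2,
            num_classes=examples[0].label.n_classes,
            hidden_dim=32,
        )
        mc = replace(mc, input_dim=C * (C - 1) // 2)
        folds = kfold_split(examples, k=k, mode=mode, seed=train_config.seed)
        result = cross_validate(examples, mc, train_config, folds)
        rows.append({**row, "mean_accuracy": result.mean_accuracy, "status": "ok"})
    return pd.DataFrame(rows)
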