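"""Within- and cross-condition decoding of awareness ratings from epoched data.

Temporal generalization: a classifier is trained at every time point and
tested at every time point, giving a train-time x test-time accuracy matrix.
Within-condition decoding trains and tests on trials of the same stimulus
under balanced 5-fold cross-validation; cross-condition decoding trains on
one stimulus and tests on the other (folds are defined on the test-stimulus
trials; the training set is a balanced sample of the train-stimulus trials,
which never overlaps the test set by construction).  Above-chance transfer in
the cross scheme is the operational signature of a content-invariant code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lda import ShrinkageLDA, batched_lda_fit
from .preprocess import boxcar_smooth
from .simulate import EpochedRecording

__all__ = [
    "FoldScheme",
    "TemporalGeneralizationMatrix",
    "make_balanced_folds",
    "temporal_generalization",
    "confusion_over_time",
    "binary_stimulus_decode",
    "binarize_visibility_by_median",
    "apply_min_trial_exclusion",
]

LOW_PAS = (1, 2)
HIGH_PAS = (3, 4)


@dataclass
class FoldScheme:
    """Disjoint folds with equal class counts inside every fold."""

    folds: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        all_idx = np.concatenate(self.folds)
        if np.unique(all_idx).size != all_idx.size:
            raise ValueError("folds must be disjoint")

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    @property
    def retained(self) -> np.ndarray:
        return np.sort(np.concatenate(self.folds))


@dataclass
class TemporalGeneralizationMatrix:
    """Train-time x test-time proportion-correct matrix."""

    accuracy: np.ndarray
    time_ms: np.ndarray
    chance: float
    scheme: str
    direction: str = ""

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.accuracy)


def make_balanced_folds(y: np.ndarray, n_folds: int = 5, seed: int = 0) -> FoldScheme:
    """Random k-fold partition with equal class counts in every fold.

    Each class is down-sampled to a multiple of ``n_folds``; surplus trials
    are dropped at random under ``seed``.  Raises if any class has fewer than
    ``n_folds`` trials.
    """
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    per_fold = counts.min() // n_folds
    if per_fold < 1:
        raise ValueError(
            f"cannot balance {n_folds} folds: smallest class has {counts.min()} trials"
        )
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in classes:
        idx = rng.permutation(np.flatnonzero(y == c))[: per_fold * n_folds]
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            folds[f].extend(chunk.tolist())
    scheme = FoldScheme([np.sort(np.array(f)) for f in folds], seed)
    for f in scheme.folds:  # invariant: per-fold class balance
        _, fc = np.unique(y[f], return_counts=True)
        assert fc.size == classes.size and np.all(fc == per_fold)
    return scheme


def _fit_predict_tgm(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray, yte: np.ndarray,
                     shrinkage) -> np.ndarray:
    """Accuracy matrix (train-sample x test-sample) for one train/test split."""
    classes, W, b = batched_lda_fit(Xtr, ytr, shrinkage)
    m, p, T = Xte.shape
    K = classes.size
    # scores[j, s, t, k]: test trial j at test time s under the time-t decoder
    flat = Xte.transpose(0, 2, 1).reshape(m * T, p) @ W.transpose(1, 0, 2).reshape(p, T * K)
    scores = flat.reshape(m, T, T, K) + b[None, None, :, :]
    pred = classes[np.argmax(scores, axis=3)]  # (m, test_t, train_t)
    return np.mean(pred == yte[:, None, None], axis=0).T


def _diag_predictions(Xtr, ytr, Xte, shrinkage) -> np.ndarray:
    """Per-sample predictions training and testing at the same time point."""
    classes, W, b = batched_lda_fit(Xtr, ytr, shrinkage)
    scores = np.einsum("npt,tpk->ntk", Xte, W) + b[None]
    return classes[np.argmax(scores, axis=2)]


def _resolve_subsets(rec, scheme, train_subset, test_subset):
    n = rec.n_trials
    if train_subset is None and test_subset is None:
        if scheme == "cross":
            raise ValueError("cross decoding needs explicit train/test subsets")
        train_subset = test_subset = np.ones(n, dtype=bool)
    train_subset = np.asarray(train_subset, dtype=bool)
    test_subset = np.asarray(test_subset, dtype=bool)
    if not train_subset.any() or not test_subset.any():
        raise ValueError("train and test subsets must be non-empty")
    if scheme == "within":
        if not np.array_equal(train_subset, test_subset):
            raise ValueError("within decoding requires identical train and test subsets")
    elif scheme == "cross":
        if np.any(train_subset & test_subset):
            raise ValueError("cross decoding requires disjoint train and test subsets")
        # content-invariance claim rests on never training on the test stimulus
        tr_stims = set(rec.labels.loc[train_subset, "stimulus"])
        te_stims = set(rec.labels.loc[test_subset, "stimulus"])
        assert not tr_stims & te_stims, "train/test stimuli overlap in cross scheme"
    else:
        raise ValueError("scheme must be 'within' or 'cross'")
    return train_subset, test_subset


def temporal_generalization(
    rec: EpochedRecording,
    y: np.ndarray,
    scheme: str = "within",
    train_subset: np.ndarray | None = None,
    test_subset: np.ndarray | None = None,
    n_folds: int = 5,
    shrinkage: str | float = "auto",
    smooth_samples: int | None = 7,
    seed: int = 0,
    direction: str = "",
) -> TemporalGeneralizationMatrix:
    """Fold-averaged temporal-generalization accuracy matrix.

    ``y`` holds the per-trial class labels (e.g. PAS ratings).  Within scheme:
    balanced ``n_folds``-fold CV on the subset.  Cross scheme: balanced folds
    are built on both subsets; fold ``f`` trains on the other folds of the
    train stimulus and tests on fold ``f`` of the test stimulus, so training
    sets match the within scheme in size and the test data are never seen in
    training.  Data are boxcar-smoothed over ``smooth_samples`` first (None
    to skip).
    """
    y = np.asarray(y)
    train_subset, test_subset = _resolve_subsets(rec, scheme, train_subset, test_subset)
    data = boxcar_smooth(rec.data, smooth_samples, axis=-1) if smooth_samples else rec.data

    test_idx = np.flatnonzero(test_subset)
    test_folds = make_balanced_folds(y[test_idx], n_folds, seed)
    chance = 1.0 / np.unique(y[test_idx]).size

    accs = []
    if scheme == "within":
        for f in range(n_folds):
            te = test_idx[test_folds.folds[f]]
            tr = test_idx[np.concatenate([test_folds.folds[g] for g in range(n_folds) if g != f])]
            accs.append(_fit_predict_tgm(data[tr], y[tr], data[te], y[te], shrinkage))
    else:
        # the test data are never seen in training, but the same fold structure
        # is applied to the training stimulus so that training-set sizes match
        # the within scheme and performance differences cannot stem from them
        train_idx = np.flatnonzero(train_subset)
        train_folds = make_balanced_folds(y[train_idx], n_folds, seed + 1)
        for f in range(n_folds):
            te = test_idx[test_folds.folds[f]]
            tr = train_idx[np.concatenate([train_folds.folds[g] for g in range(n_folds) if g != f])]
            accs.append(_fit_predict_tgm(data[tr], y[tr], data[te], y[te], shrinkage))
    return TemporalGeneralizationMatrix(
        np.mean(accs, axis=0), rec.time_ms.copy(), chance, scheme, direction
    )


def confusion_over_time(
    rec: EpochedRecording,
    y: np.ndarray,
    n_folds: int = 5,
    shrinkage: str | float = "auto",
    smooth_samples: int | None = 7,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample row-normalised confusion matrix from diagonal CV decoding.

    Returns (n_samples, K, K); rows are true classes and sum to 1.  Under a
    graded vividness code, neighbouring ratings are confused most often (the
    distance effect in the classifier's mistakes).
    """
    y = np.asarray(y)
    classes = np.unique(y)
    data = boxcar_smooth(rec.data, smooth_samples, axis=-1) if smooth_samples else rec.data
    folds = make_balanced_folds(y, n_folds, seed)
    n_samples = rec.data.shape[2]
    counts = np.zeros((n_samples, classes.size, classes.size))
    for f in range(n_folds):
        te = folds.folds[f]
        tr = np.concatenate([folds.folds[g] for g in range(n_folds) if g != f])
        preds = _diag_predictions(data[tr], y[tr], data[te], shrinkage)
        true_i = np.searchsorted(classes, y[te])
        for t in range(n_samples):
            pred_i = np.searchsorted(classes, preds[:, t])
            np.add.at(counts[t], (true_i, pred_i), 1)
    return counts / counts.sum(axis=2, keepdims=True)


def binary_stimulus_decode(
    rec: EpochedRecording,
    visibility_group: str,
    n_folds: int = 5,
    shrinkage: str | float = "auto",
    smooth_samples: int | None = 7,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample CV accuracy of binary stimulus decoding in one visibility group.

    ``visibility_group`` is "low" (PAS 1-2) or "high" (PAS 3-4); stimulus
    identity is the class label.  Returns accuracy over time (chance 0.5).
    """
    if visibility_group not in ("low", "high"):
        raise ValueError("visibility_group must be 'low' or 'high'")
    ratings = LOW_PAS if visibility_group == "low" else HIGH_PAS
    sel = rec.labels["pas"].isin(ratings).to_numpy()
    if not sel.any():
        raise ValueError(f"no trials in the {visibility_group}-visibility group")
    y = rec.labels["stimulus"].to_numpy()[sel]
    if np.unique(y).size < 2:
        raise ValueError("both stimulus classes must be present in the group")
    data = boxcar_smooth(rec.data[sel], smooth_samples, axis=-1) if smooth_samples else rec.data[sel]
    folds = make_balanced_folds(y, n_folds, seed)
    n_samples = data.shape[2]
    acc = np.zeros(n_samples)
    for f in range(n_folds):
        te = folds.folds[f]
        tr = np.concatenate([folds.folds[g] for g in range(n_folds) if g != f])
        preds = _diag_predictions(data[tr], y[tr], data[te], shrinkage)
        acc += np.mean(preds == y[te][:, None], axis=0)
    return acc / n_folds


def binarize_visibility_by_median(ratings: np.ndarray) -> np.ndarray:
    """Median-split visibility ratings into "low"/"high" per-trial labels.

    The subject's median rating (standard interpolated median) is the
    boundary: ratings strictly below it are "low", ratings at or above it are
    "high".  E.g. a subject using ratings 2 and 3 on half the trials and 4 on
    the other half has median 3.5, so 2 and 3 are low and 4 is high; if all
    ratings are identical, every trial is "high".
    """
    ratings = np.asarray(ratings)
    if ratings.size == 0:
        raise ValueError("no ratings given")
    med = np.median(ratings)
    return np.where(ratings < med, "low", "high")


def apply_min_trial_exclusion(
    animacy: np.ndarray, visibility: np.ndarray, min_per_cell: int = 10
) -> bool:
    """Keep a subject only if all four animacy x visibility cells have enough trials.

    Counts trials in the 2x2 (animate/inanimate x low/high) table; returns
    False (drop) if any cell holds fewer than ``min_per_cell`` trials
    (threshold inclusive: exactly ``min_per_cell`` keeps).
    """
    tab = pd.crosstab(pd.Series(np.asarray(animacy)), pd.Series(np.asarray(visibility)))
    if tab.shape != (2, 2):
        return False
    return bool((tab.to_numpy() >= min_per_cell).all())
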