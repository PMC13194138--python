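"""Wrapper channel selection: binary-mask search under a cross-validated
classifier fitness.

The search variable is a binary mask over the electrode montage.  The
optimizer explores a continuous box; each position is thresholded at
t = 0 (strict) into a mask, optionally repaired to a fixed cardinality,
and scored by the mean cross-validated classification accuracy of the
fused per-channel features restricted to the masked columns.  Folds are
built at the *subject* level, so all epochs of a subject travel together
and no subject leaks across a split.

The public surface follows the fitted-model idiom:
``ChannelSelectionModel(fused, labels, subjects).fit(...)`` returns a
``ChannelSelectionResults`` with the selected mask, the fitness record,
optimizer curves and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .optimize import (OptimizationResult, OptimizerConfig, SearchSpace,
                       binarize_position, run_optimizer)

__all__ = [
    "make_cv_splits", "make_classifier", "fitness_accuracy",
    "classification_metrics", "FitnessRecord", "MetricsReport",
    "ChannelSelectionModel", "ChannelSelectionResults", "select_channels",
]


# ---------------------------------------------------------------------------
# cross-validation schemes

def make_cv_splits(subjects: np.ndarray, groups: np.ndarray,
                   scheme: str = "kfold5", seed: int = 0,
                   n_splits: int = 5) -> list[tuple[np.ndarray, np.ndarray]]:
    """Subject-level CV folds as (train_subjects, test_subjects) pairs.

    ``subjects``/``groups`` are per-subject arrays (one entry per unique
    subject, aligned).  ``kfold5`` partitions subjects into ``n_splits``
    group-stratified folds; ``loso`` puts one subject per test fold.
    Folds are disjoint and exhaustive.
    """
    subjects = np.asarray(subjects)
    groups = np.asarray(groups)
    if len(subjects) != len(np.unique(subjects)):
        raise ValueError("subjects must be unique (one entry per subject)")
    if scheme == "loso":
        return [(np.delete(subjects, i), subjects[i:i + 1])
                for i in range(len(subjects))]
    if scheme == "kfold5":
        _, counts = np.unique(groups, return_counts=True)
        if counts.min() < max(2, n_splits):
            raise ValueError(
                f"stratified {n_splits}-fold needs >= {n_splits} subjects "
                "per group")
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        return [(subjects[tr], subjects[te])
                for tr, te in skf.split(subjects, groups)]
    raise ValueError(f"unknown CV scheme {scheme!r}")


def epoch_indices(split: tuple[np.ndarray, np.ndarray],
                  epoch_subjects: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand a subject-level split to epoch row indices."""
    train_subjects, test_subjects = split
    tr = np.isin(epoch_subjects, train_subjects)
    te = np.isin(epoch_subjects, test_subjects)
    return np.where(tr)[0], np.where(te)[0]


# ---------------------------------------------------------------------------
# classifiers

def make_classifier(spec: str = "gbdt", seed: int = 0):
    """Instantiate the fitness classifier.

    ``"gbdt"`` is a gradient-boosted decision tree ensemble with 1000
    boosting iterations, learning rate 0.02 and maximum depth 6; ``"logistic"``
    is a fast linear fallback suitable for desk-scale experiments.  Any
    object honouring fit/predict can be passed directly wherever a spec is
    accepted.
    """
    if spec == "gbdt":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(n_estimators=1000, learning_rate=0.02,
                              max_depth=6, random_state=seed, verbose=-1,
                              deterministic=True, force_row_wise=True,
                              min_child_samples=5)
    if spec == "logistic":
        return LogisticRegression(max_iter=500, random_state=seed)
    raise ValueError(f"unknown classifier spec {spec!r}")


# ---------------------------------------------------------------------------
# fitness and metrics

@dataclass
class FitnessRecord:
    """Cross-validated accuracy of one channel mask."""

    mask: np.ndarray
    fitness: float            # mean test accuracy over folds
    optimal_accuracy: float   # best single-fold accuracy
    per_fold: np.ndarray

    def __post_init__(self) -> None:
        if self.per_fold.size and not (self.fitness <= self.optimal_accuracy + 1e-12):
            raise ValueError("mean fitness cannot exceed the best fold accuracy")


def fitness_accuracy(mask: np.ndarray, fused: pd.DataFrame, labels: np.ndarray,
                     subjects: np.ndarray,
                     splits: list[tuple[np.ndarray, np.ndarray]],
                     classifier_spec="logistic", seed: int = 0) -> FitnessRecord:
    """Score a mask by mean cross-validated accuracy on the masked columns.

    The all-zero mask gets the defined penalty fitness 0 so the optimizer
    can recover from infeasible positions.
    """
    mask = np.asarray(mask, dtype=int)
    if mask.sum() == 0:
        return FitnessRecord(mask=mask, fitness=0.0, optimal_accuracy=0.0,
                             per_fold=np.array([]))
    X = fused.to_numpy()[:, mask.astype(bool)]
    y = np.asarray(labels)
    classes = np.unique(y)
    y_bin = (y == classes[-1]).astype(int)
    accs = []
    for split in splits:
        tr, te = epoch_indices(split, subjects)
        clf = (make_classifier(classifier_spec, seed)
               if isinstance(classifier_spec, str) else classifier_spec)
        clf.fit(X[tr], y_bin[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y_bin[te])))
    accs = np.asarray(accs)
    return FitnessRecord(mask=mask, fitness=float(accs.mean()),
                         optimal_accuracy=float(accs.max()), per_fold=accs)


@dataclass
class MetricsReport:
    """Confusion-matrix derived classification metrics.

    Zero-denominator metrics are NaN (flagged undefined).  The AUC is the
    rank (Mann-Whitney) statistic of the scores and needs ``scores``.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    sensitivity: float
    specificity: float
    f1: float
    accuracy: float
    auc: float

    def to_series(self) -> pd.Series:
        return pd.Series({
            "precision": self.precision, "auc": self.auc, "f1": self.f1,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy,
        })


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                           scores: np.ndarray | None = None) -> MetricsReport:
    """Precision, sensitivity, specificity, F1, accuracy and rank AUC."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    precision = _safe_div(tp, tp + fp)
    sensitivity = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = (_safe_div(2 * precision * sensitivity, precision + sensitivity)
          if np.isfinite(precision) and np.isfinite(sensitivity) else float("nan"))
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn)
    auc = float("nan")
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != y_true.shape:
            raise ValueError("scores length mismatch")
        pos = scores[y_true == 1]
        neg = scores[y_true == 0]
        if pos.size and neg.size:
            # Mann-Whitney U with half credit for ties
            greater = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            auc = float((greater + 0.5 * ties) / (pos.size * neg.size))
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, precision=precision,
                         sensitivity=sensitivity, specificity=specificity,
                         f1=f1, accuracy=accuracy, auc=auc)


# ---------------------------------------------------------------------------
# the model / results pair

def _repair_topk(position: np.ndarray, k: int) -> np.ndarray:
    """Cardinality repair: keep the k largest coordinates as selected."""
    mask = np.zeros(position.size, dtype=int)
    mask[np.argsort(position, kind="stable")[::-1][:k]] = 1
    return mask


@dataclass
class ChannelSelectionResults:
    """Fitted channel-selection outcome.

    Carries the selected mask and channel names, the cross-validated
    fitness record of the selected mask, the optimizer's convergence and
    diversity curves, and the evaluation cache (mask -> fitness) explored
    during the search.
    """

    model: "ChannelSelectionModel"
    mask: np.ndarray
    channel_names: tuple[str, ...]
    record: FitnessRecord
    optimization: OptimizationResult
    cache: dict = field(default_factory=dict)

    @property
    def cardinality(self) -> int:
        return int(self.mask.sum())

    def evaluate_mask(self, mask: np.ndarray) -> FitnessRecord:
        """Score an arbitrary mask under the same CV protocol."""
        return self.model._score(np.asarray(mask, dtype=int))

    def summary(self) -> str:
        lines = [
            "Channel selection results",
            "=" * 60,
            f"algorithm:        {self.optimization.algorithm}",
            f"seed:             {self.optimization.seed}",
            f"selected mask:    {''.join(map(str, self.mask))}",
            f"channels ({self.cardinality}):     {', '.join(self.channel_names)}",
            f"fitness (mean CV accuracy): {self.record.fitness:.4f}",
            f"optimal accuracy (best fold): {self.record.optimal_accuracy:.4f}",
            f"per-fold accuracy: {np.array2string(self.record.per_fold, precision=4)}",
            f"objective evaluations: {self.optimization.evaluations} "
            f"({len(self.cache)} distinct masks)",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_convergence(self, ax=None):  # pragma: no cover - plotting helper
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(-self.optimization.convergence_curve)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best CV accuracy")
        return ax


class ChannelSelectionModel:
    """Wrapper feature-selection model over a fused channel table.

    Parameters
    ----------
    fused : DataFrame (epochs x channels)
        One fused feature per channel, channel names as columns.
    labels : array-like per epoch
        Two-class group labels.
    subjects : array-like per epoch
        Subject identifier of each epoch; folds never split a subject.
    scheme : {"kfold5", "loso"}
        Subject-level CV scheme used for the fitness.
    classifier : str or estimator
        ``"gbdt"`` (gradient-boosted trees, 1000 rounds, lr 0.02, depth 6)
        or ``"logistic"``; or any fit/predict estimator instance.
    """

    def __init__(self, fused: pd.DataFrame, labels, subjects,
                 scheme: str = "kfold5", classifier="gbdt", seed: int = 0):
        self.fused = fused
        self.labels = np.asarray(labels)
        self.subjects = np.asarray(subjects)
        if not (len(fused) == len(self.labels) == len(self.subjects)):
            raise ValueError("fused table, labels and subjects must align")
        self.channel_names = tuple(fused.columns)
        self.scheme = scheme
        self.classifier = classifier
        self.seed = seed
        subj, first = np.unique(self.subjects, return_index=True)
        self.splits = make_cv_splits(subj, self.labels[first], scheme=scheme,
                                     seed=seed)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, label_col: str = "group",
                       subject_col: str = "subject", **kwargs):
        """Build from a tidy frame holding channel columns plus metadata."""
        labels = frame[label_col].to_numpy()
        subjects = frame[subject_col].to_numpy()
        fused = frame.drop(columns=[label_col, subject_col])
        return cls(fused, labels, subjects, **kwargs)

    def _score(self, mask: np.ndarray) -> FitnessRecord:
        return fitness_accuracy(mask, self.fused, self.labels, self.subjects,
                                self.splits, self.classifier, self.seed)

    def fit(self, algorithm: str = "woa_gwo", k_channels: int | None = None,
            config: OptimizerConfig | None = None,
            threshold: float = 0.0) -> ChannelSelectionResults:
        """Search the mask space and return the fitted results.

        The optimizer explores [-1, 1]^n; each position is binarized at
        ``threshold`` (strict >) or, when ``k_channels`` is given,
        repaired to exactly k selected channels by keeping the k largest
        coordinates.  Mask fitness values are memoized: a 16-bit mask
        space is revisited heavily across 300 iterations.
        """
        n = len(self.channel_names)
        if k_channels is not None and k_channels > n:
            raise ValueError(f"k_channels={k_channels} exceeds {n} channels")
        config = config or OptimizerConfig(seed=self.seed)
        cache: dict[tuple[int, ...], float] = {}

        def position_to_mask(x: np.ndarray) -> np.ndarray:
            if k_channels is not None:
                return _repair_topk(x, k_channels)
            return binarize_position(x, threshold)

        def objective(x: np.ndarray) -> float:
            key = tuple(position_to_mask(x).tolist())
            if key not in cache:
                cache[key] = self._score(np.array(key)).fitness
            return cache[key]

        space = SearchSpace(dim=n, lower=-1.0, upper=1.0, objective=objective,
                            maximize=True)
        opt = run_optimizer(space, config, algorithm)
        mask = position_to_mask(opt.best_position)
        record = self._score(mask)
        names = tuple(c for c, m in zip(self.channel_names, mask) if m)
        return ChannelSelectionResults(model=self, mask=mask,
                                       channel_names=names, record=record,
                                       optimization=opt, cache=cache)


def select_channels(fused: pd.DataFrame, labels, subjects,
                    algorithm: str = "woa_gwo", k_channels: int | None = None,
                    scheme: str = "kfold5", classifier="gbdt", seed: int = 0,
                    config: OptimizerConfig | None = None) -> ChannelSelectionResults:
    """One-call convenience wrapper around :class:`ChannelSelectionModel`."""
    model = ChannelSelectionModel(fused, labels, subjects, scheme=scheme,
                                  classifier=classifier, seed=seed)
    return model.fit(algorithm=algorithm, k_channels=k_channels, config=config)
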