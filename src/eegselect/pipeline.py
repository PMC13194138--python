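"""End-to-end conveniences wiring the stages together.

The full study pipeline is: segment recordings into 10-s epochs, z-score,
extract nonlinear features, screen them (redundancy + ANOVA retention),
fuse each channel's retained trio into a single feature via ReliefF, then
search channel masks with the hybrid optimizer under a cross-validated
classifier fitness.

``fused_cohort_table`` defaults to fusing the geometric trio SAV/STD/STA —
the features that dominate the retention ranking (the screening module
recomputes that ranking on any table) and are cheap enough to extract at
full epoch length.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FeatureConfig, FeatureTable, extract_feature_table
from .io import EEGRecording, segment_cohort
from .optimize import OptimizerConfig
from .relieff import fuse_channels
from .selection import (ChannelSelectionModel, ChannelSelectionResults,
                        epoch_indices, make_classifier, make_cv_splits)

FUSION_TRIO = ("SAV", "STD", "STA")


def extract_cohort_features(recordings: list[EEGRecording],
                            epoch_seconds: float = 10.0,
                            config: FeatureConfig | None = None) -> FeatureTable:
    """Segment all recordings and extract the configured feature table."""
    epochs = segment_cohort(recordings, epoch_seconds=epoch_seconds)
    return extract_feature_table(epochs, config)


def fused_cohort_table(recordings: list[EEGRecording],
                       features: tuple[str, ...] = FUSION_TRIO,
                       epoch_seconds: float = 10.0,
                       k: int = 5) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Cohort -> per-channel fused feature table.

    Extracts only the features to be fused, then ReliefF-fuses them
    channel-locally.  Returns ``(fused, labels, subjects)`` aligned by
    epoch row.
    """
    config = FeatureConfig(features=tuple(features))
    table = extract_cohort_features(recordings, epoch_seconds, config)
    fused = fuse_channels(table, tuple(features), k=k)
    return fused, table.labels, table.subjects


def desk_scale_optimizer_config(seed: int = 0, pop_size: int = 20,
                                max_iter: int = 60) -> OptimizerConfig:
    """Optimizer settings for desk-scale wrapper runs.

    A 16-bit mask space is small: with fitness memoization a modest
    population and iteration budget visits the informative masks many
    times over, so the search behaves as at full budget at a fraction of
    the cost.
    """
    return OptimizerConfig(pop_size=pop_size, max_iter=max_iter, seed=seed,
                           perturb_period=15)


def nested_cv_accuracy(fused: pd.DataFrame, labels, subjects,
                       algorithm: str = "woa_gwo", k_channels: int | None = 4,
                       classifier="logistic", seed: int = 0,
                       config: OptimizerConfig | None = None,
                       n_outer: int = 5) -> float:
    """Leakage-free accuracy: channel selection nested inside an outer CV.

    For each outer subject-stratified fold, the wrapper search runs on the
    training subjects only; the selected mask is then scored once on the
    held-out subjects.  The mean over outer folds estimates the accuracy
    of the *procedure*, free of selection bias.
    """
    labels = np.asarray(labels)
    subjects = np.asarray(subjects)
    subj, first = np.unique(subjects, return_index=True)
    outer = make_cv_splits(subj, labels[first], scheme="kfold5", seed=seed,
                           n_splits=n_outer)
    classes = np.unique(labels)
    y_bin = (labels == classes[-1]).astype(int)
    accs = []
    for split in outer:
        tr, te = epoch_indices(split, subjects)
        model = ChannelSelectionModel(fused.iloc[tr], labels[tr], subjects[tr],
                                      scheme="kfold5", classifier=classifier,
                                      seed=seed)
        res = model.fit(algorithm=algorithm, k_channels=k_channels,
                        config=config or desk_scale_optimizer_config(seed))
        cols = res.mask.astype(bool)
        clf = (make_classifier(classifier, seed)
               if isinstance(classifier, str) else classifier)
        X = fused.to_numpy()
        clf.fit(X[tr][:, cols], y_bin[tr])
        accs.append(float(np.mean(clf.predict(X[te][:, cols]) == y_bin[te])))
    return float(np.mean(accs))
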