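"""Deterministic ReliefF feature weighting and per-channel feature fusion.

ReliefF scores a feature by how well it separates each instance from its
nearest other-class neighbours (misses) relative to its nearest same-class
neighbours (hits).  The variant here is the deterministic full-pass form:
every row serves as an instance, neighbours are found by Euclidean
distance on z-scored features, and per-feature differences are normalized
by the feature's value range, so weights lie in [-1, 1].

Fusion compresses each channel's selected features into a single column:
weights are computed channel-locally, clipped at zero (anti-informative
features are dropped rather than subtracted) and used as a normalized
weighted average of the z-scored features.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .features import FeatureTable

logger = logging.getLogger(__name__)


def relieff_weights(X: np.ndarray, y: np.ndarray, k: int = 5) -> np.ndarray:
    """Classic ReliefF weights for a binary-labelled matrix.

    Parameters
    ----------
    X : ndarray (n_rows, n_features)
        Feature matrix; z-scored internally so the Euclidean neighbourhood
        treats features on an even footing.
    y : array-like (n_rows,)
        Two-class labels (any hashable values).
    k : int
        Neighbourhood size; each class must contain at least ``k + 1``
        rows so that k hits exist after excluding the instance itself.

    Returns
    -------
    ndarray (n_features,)
        Weight vector: ``w_f = sum_miss diff / (m k) - sum_hit diff / (m k)``
        accumulated over all m rows, with range-normalized absolute
        differences.  Constant features get weight exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if k <= 0:
        raise ValueError("k must be positive")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {len(classes)}")
    if counts.min() < k + 1:
        raise ValueError(
            f"smallest class has {counts.min()} rows; need at least k+1={k + 1}")
    m, n_feat = X.shape
    rng_span = X.max(axis=0) - X.min(axis=0)
    constant = rng_span == 0
    span = np.where(constant, 1.0, rng_span)
    # standardize for the neighbourhood metric only
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    w = np.zeros(n_feat)
    for i in range(m):
        same = y == y[i]
        hits = np.where(same)[0]
        hits = hits[hits != i]
        misses = np.where(~same)[0]
        hit_idx = hits[np.argsort(d2[i, hits], kind="stable")[:k]]
        miss_idx = misses[np.argsort(d2[i, misses], kind="stable")[:k]]
        diff_hit = np.abs(X[i] - X[hit_idx]) / span
        diff_miss = np.abs(X[i] - X[miss_idx]) / span
        w += diff_miss.sum(axis=0) / (m * k) - diff_hit.sum(axis=0) / (m * k)
    w[constant] = 0.0
    return w


def fuse_channels(table: FeatureTable, selected_features: tuple[str, ...],
                  k: int = 5) -> pd.DataFrame:
    """Fuse each channel's selected features into one column.

    Per channel: z-score the selected feature columns, compute ReliefF
    weights of that channel's block against the group labels, clip
    negative weights at 0 and take the weight-normalized average.  When a
    channel has no positive weight the unweighted mean of z-scores is
    used (logged).  Output: epochs x channels frame, columns named by
    channel.
    """
    missing = [f for f in selected_features if f not in table.features]
    if missing:
        raise KeyError(f"features {missing} not present in the table")
    y = table.labels
    fused = {}
    for ch in table.channels:
        block = table.channel_block(ch)[list(selected_features)].to_numpy()
        sd = block.std(axis=0)
        if np.any(sd == 0):
            sd = np.where(sd == 0, 1.0, sd)
        z = (block - block.mean(axis=0)) / sd
        w = np.clip(relieff_weights(block, y, k=k), 0.0, None)
        if w.sum() <= 0:
            logger.warning("channel %s: no positive ReliefF weight, "
                           "falling back to unweighted mean", ch)
            fused[ch] = z.mean(axis=1)
        else:
            fused[ch] = z @ (w / w.sum())
    return pd.DataFrame(fused, columns=list(table.channels))
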