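"""Feature-redundancy and group-discriminability screening.

Three complementary screens reduce the channel x feature grid to a small
set of stable, discriminative features before fusion:

* maximum cross-correlation (MCC) between channel-averaged per-epoch
  feature series exposes redundant feature clusters;
* per-(channel, feature) one-way ANOVA between the diagnostic groups
  flags where a feature separates the cohorts, and per-feature retention
  counts (number of channels significant) rank feature stability;
* coefficient-of-variation profiling quantifies within-subject,
  within-group and between-group dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable


@dataclass
class ScreeningReport:
    """Bundled outputs of the screening stage."""

    mcc: pd.DataFrame
    anova_f: pd.DataFrame
    anova_p: pd.DataFrame
    significant_05: pd.DataFrame
    significant_01: pd.DataFrame
    cv_within_subject: pd.DataFrame
    cv_within_group: pd.DataFrame
    cv_between_group: pd.DataFrame
    retention: pd.Series
    selected_features: tuple[str, ...] = ()
    notes: dict = field(default_factory=dict)


def _lagged_corr(a: np.ndarray, b: np.ndarray, max_lag: int) -> float:
    """Max over lags of |Pearson correlation| between the overlapping parts."""
    best = np.nan
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            x, y = a[lag:], b[: b.size - lag]
        else:
            x, y = a[: a.size + lag], b[-lag:]
        if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
            continue
        c = abs(float(np.corrcoef(x, y)[0, 1]))
        if np.isnan(best) or c > best:
            best = c
    return best


def mcc_matrix(table: FeatureTable, max_lag: int = 0) -> pd.DataFrame:
    """Maximum cross-correlation between per-epoch feature series.

    Each feature is first averaged over channels to a single series over
    epochs; entry (i, j) is the maximum over lags in [-max_lag, max_lag]
    of the absolute normalized cross-correlation.  With the default
    max_lag = 0 this is |Pearson|.  Constant series give NaN entries
    (flagged undefined); the diagonal is 1.
    """
    feats = list(table.features)
    series = {f: table.feature_block(f).mean(axis=1).to_numpy() for f in feats}
    if len(next(iter(series.values()))) < 3:
        raise ValueError("need at least 3 epochs per feature series")
    n = len(feats)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _lagged_corr(series[feats[i]],
                                                 series[feats[j]], max_lag)
    for i, f in enumerate(feats):
        if np.std(series[f]) == 0:
            out[i, :] = np.nan
            out[:, i] = np.nan
            out[i, i] = 1.0
    return pd.DataFrame(out, index=feats, columns=feats)


def select_low_correlation_subset(mcc: pd.DataFrame, k: int) -> tuple[str, ...]:
    """Greedily pick ``k`` mutually least-correlated features.

    Starting from the feature whose maximum off-diagonal MCC is smallest,
    repeatedly add the feature minimizing its maximum MCC to the already
    selected set.  Ties break lexicographically, so the selection is
    deterministic.  NaN correlations are treated as 1 (worst case).
    """
    feats = list(mcc.index)
    if k > len(feats):
        raise ValueError(f"k={k} exceeds the {len(feats)} available features")
    m = mcc.to_numpy(copy=True)
    np.fill_diagonal(m, 0.0)
    m = np.nan_to_num(m, nan=1.0)
    order = {f: i for i, f in enumerate(feats)}
    # seed: smallest max correlation to anything else, lexicographic ties
    seed = min(feats, key=lambda f: (m[order[f]].max(), f))
    selected = [seed]
    while len(selected) < k:
        chosen = min(
            (f for f in feats if f not in selected),
            key=lambda f: (max(m[order[f], order[s]] for s in selected), f),
        )
        selected.append(chosen)
    return tuple(selected)


def anova_screen(table: FeatureTable, alphas: tuple[float, float] = (0.05, 0.01)):
    """One-way ANOVA of each (channel, feature) cell between the groups.

    Returns (F, p, flags) where ``flags`` maps each alpha level to a
    channels x features boolean frame.  Identical group distributions give
    F = 0, p = 1.
    """
    groups = np.unique(table.labels)
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    masks = [table.labels == g for g in groups]
    if any(m.sum() < 2 for m in masks):
        raise ValueError("each group needs at least 2 observations")
    channels, feats = table.channels, table.features
    f_mat = np.empty((len(channels), len(feats)))
    p_mat = np.empty_like(f_mat)
    for i, ch in enumerate(channels):
        for j, feat in enumerate(feats):
            col = table.column(ch, feat).to_numpy()
            samples = [col[m] for m in masks]
            if all(np.ptp(s) == 0 for s in samples) and np.ptp(col) == 0:
                f_mat[i, j], p_mat[i, j] = 0.0, 1.0
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                f, p = stats.f_oneway(*samples)
            if np.isnan(f):  # zero within-group variance edge cases
                f_mat[i, j] = 0.0 if np.ptp(col) == 0 else np.inf
                p_mat[i, j] = 1.0 if np.ptp(col) == 0 else 0.0
            else:
                f_mat[i, j], p_mat[i, j] = f, p
    f_df = pd.DataFrame(f_mat, index=channels, columns=feats)
    p_df = pd.DataFrame(p_mat, index=channels, columns=feats)
    flags = {a: p_df < a for a in alphas}
    return f_df, p_df, flags


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation sd/|mean| (population sd); NaN when the
    mean is numerically zero."""
    mean = values.mean()
    if abs(mean) < 1e-12:
        return np.nan
    return float(values.std() / abs(mean))


def cv_profile(table: FeatureTable):
    """Within-subject, within-group and between-group CV per cell.

    Within-subject CVs are computed per subject (over that subject's
    epochs) and averaged across subjects; within-group CVs are computed
    per group and averaged over groups; the between-group CV pools all
    epochs of both groups.
    """
    channels, feats = table.channels, table.features
    subjects = np.unique(table.subjects)
    groups = np.unique(table.labels)
    for s in subjects:
        if (table.subjects == s).sum() < 2:
            raise ValueError(f"subject {s} has fewer than 2 epochs")
    ws = np.empty((len(channels), len(feats)))
    wg = np.empty_like(ws)
    bg = np.empty_like(ws)
    for i, ch in enumerate(channels):
        for j, feat in enumerate(feats):
            col = table.column(ch, feat).to_numpy()
            per_subj = [_cv(col[table.subjects == s]) for s in subjects]
            per_group = [_cv(col[table.labels == g]) for g in groups]
            ws[i, j] = np.nanmean(per_subj) if not all(np.isnan(per_subj)) else np.nan
            wg[i, j] = np.nanmean(per_group) if not all(np.isnan(per_group)) else np.nan
            bg[i, j] = _cv(col)
    idx = dict(index=channels, columns=feats)
    return (pd.DataFrame(ws, **idx), pd.DataFrame(wg, **idx), pd.DataFrame(bg, **idx))


def retention_counts(flags: pd.DataFrame) -> pd.Series:
    """Per feature, the number of channels flagged significant.

    ``flags`` is a channels x features boolean frame.  The result is
    sorted by count descending with lexicographic tie-break.
    """
    counts = flags.sum(axis=0).astype(int)
    order = sorted(counts.index, key=lambda f: (-counts[f], f))
    return counts.loc[order]


def run_screening(table: FeatureTable, k_low_corr: int = 8, k_final: int = 3,
                  max_lag: int = 0, alpha: float = 0.05) -> ScreeningReport:
    """Full screening pipeline: MCC -> low-correlation subset -> ANOVA
    retention ranking -> top ``k_final`` features for fusion."""
    mcc = mcc_matrix(table, max_lag=max_lag)
    low_corr = select_low_correlation_subset(mcc, min(k_low_corr, len(mcc)))
    f_df, p_df, flags = anova_screen(table)
    ws, wg, bg = cv_profile(table)
    retention = retention_counts(flags[alpha][list(low_corr)])
    selected = tuple(retention.index[:k_final])
    return ScreeningReport(
        mcc=mcc, anova_f=f_df, anova_p=p_df,
        significant_05=flags[0.05], significant_01=flags[0.01],
        cv_within_subject=ws, cv_within_group=wg, cv_between_group=bg,
        retention=retention, selected_features=selected,
        notes={"k_low_corr": k_low_corr, "k_final": k_final,
               "low_correlation_subset": list(low_corr), "alpha": alpha},
    )
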