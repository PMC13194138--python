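"""Per-epoch, per-channel nonlinear feature extraction.

The default roster holds 12 features per channel: seven SODP geometric
descriptors (STD, SAV, SDC, STA, SSHD, SCC, SSVL), the central tendency
measure at three radii (CTM0.2, CTM0.5, CTM0.8, meaningful as absolute
radii because epochs are z-scored first) and the two entropies (SampEn,
FuzzyEn).  A 16-channel montage therefore yields a 16 x 12 = 192-column
table with one row per epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import entropy, sodp
from .io import EpochSet, zscore_epoch

#: Features computable from the SODP cloud alone (no O(N^2) cost).
SODP_FEATURES = ("STD1", "STD2", "STD", "SAV", "SDC", "STA", "SSHD", "SCC", "SSVL")
ENTROPY_FEATURES = ("SampEn", "FuzzyEn")

DEFAULT_CTM_RADII = (0.2, 0.5, 0.8)
DEFAULT_FEATURES = (
    "STD", "SAV", "SDC", "STA", "SSHD", "SCC", "SSVL",
    "CTM0.2", "CTM0.5", "CTM0.8", "SampEn", "FuzzyEn",
)


@dataclass
class FeatureConfig:
    """Settings for feature extraction.

    ``features`` lists the enabled feature names (``CTM<r>`` entries are
    parsed for their radius).  Entropy parameters follow the standard
    configuration m = 2, r = 0.15 x SD (and tau = 1, n = 2 for FuzzyEn);
    ``sav_mode`` selects the printed-formula or arccos-angle variant.
    ``zscore`` applies per-epoch, per-channel standardization before any
    feature is computed.
    """

    features: tuple[str, ...] = DEFAULT_FEATURES
    sav_mode: str = "printed"
    entropy_m: int = 2
    entropy_r: float = 0.15
    fuzzy_tau: int = 1
    fuzzy_n: float = 2.0
    zscore: bool = True

    def ctm_radii(self) -> tuple[float, ...]:
        return tuple(float(f[3:]) for f in self.features if f.startswith("CTM"))

    def to_dict(self) -> dict:
        return {
            "features": list(self.features), "sav_mode": self.sav_mode,
            "entropy_m": self.entropy_m, "entropy_r": self.entropy_r,
            "fuzzy_tau": self.fuzzy_tau, "fuzzy_n": self.fuzzy_n,
            "zscore": self.zscore,
        }


@dataclass
class FeatureTable:
    """Epochs x (channel, feature) numeric table with per-row metadata.

    Columns of ``values`` are flattened as ``"CH.FEATURE"``; ``labels``
    and ``subjects`` align with the rows.
    """

    values: pd.DataFrame
    labels: np.ndarray
    subjects: np.ndarray
    channels: tuple[str, ...]
    features: tuple[str, ...]
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.values)
        if len(self.labels) != n or len(self.subjects) != n:
            raise ValueError("labels/subjects must align with table rows")
        if self.values.isna().any().any():
            raise ValueError("feature table contains NaN")

    def column(self, channel: str, feature: str) -> pd.Series:
        return self.values[f"{channel}.{feature}"]

    def channel_block(self, channel: str) -> pd.DataFrame:
        """All feature columns of one channel, named by feature."""
        cols = [f"{channel}.{f}" for f in self.features]
        block = self.values[cols].copy()
        block.columns = list(self.features)
        return block

    def feature_block(self, feature: str) -> pd.DataFrame:
        """One feature across channels, columns named by channel."""
        cols = [f"{c}.{feature}" for c in self.channels]
        block = self.values[cols].copy()
        block.columns = list(self.channels)
        return block

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "subject", self.subjects)
        out.insert(1, "group", self.labels)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, config: dict | None = None) -> "FeatureTable":
        subjects = frame["subject"].to_numpy()
        labels = frame["group"].to_numpy()
        values = frame.drop(columns=["subject", "group"])
        channels, features = [], []
        for col in values.columns:
            ch, feat = col.split(".", 1)
            if ch not in channels:
                channels.append(ch)
            if feat not in features:
                features.append(feat)
        return cls(values=values, labels=labels, subjects=subjects,
                   channels=tuple(channels), features=tuple(features),
                   config=config or {})


def extract_features(signal: np.ndarray, config: FeatureConfig) -> dict[str, float]:
    """Compute the configured features of one 1-D signal."""
    out: dict[str, float] = {}
    p = sodp.sodp_points(signal)
    need = set(config.features)
    if need & {"STD1", "STD2", "STD"}:
        s1, s2, s = sodp.std_descriptors(p)
        out.update(STD1=s1, STD2=s2, STD=s)
    if "SAV" in need:
        out["SAV"] = sodp.sav(p, mode=config.sav_mode)
    if "SDC" in need:
        out["SDC"] = sodp.sdc(p)
    if "STA" in need:
        out["STA"] = sodp.sta(p)
    if "SSHD" in need:
        out["SSHD"] = sodp.sshd(p)
    if "SCC" in need:
        out["SCC"] = sodp.scc(p)
    if "SSVL" in need:
        out["SSVL"] = sodp.ssvl(p)
    for radius in config.ctm_radii():
        out[f"CTM{radius:g}"] = sodp.ctm(p, radius)
    if "SampEn" in need:
        out["SampEn"] = entropy.sample_entropy(
            signal, m=config.entropy_m, r=config.entropy_r)
    if "FuzzyEn" in need:
        out["FuzzyEn"] = entropy.fuzzy_entropy(
            signal, m=config.entropy_m, tau=config.fuzzy_tau,
            n=config.fuzzy_n, r=config.entropy_r)
    return {f: out[f] for f in config.features}


def extract_feature_table(epochs: EpochSet, config: FeatureConfig | None = None) -> FeatureTable:
    """Extract the channel x feature grid for every epoch.

    Rows follow the epoch order of ``epochs``; columns are grouped by
    channel in montage order, features in config order.  Errors in a
    single feature are re-raised with channel/epoch context.
    """
    config = config or FeatureConfig()
    channels = epochs.channel_labels
    columns = [f"{ch}.{f}" for ch in channels for f in config.features]
    rows = np.empty((len(epochs), len(columns)))
    labels, subjects = [], []
    for i, (epoch, (subject, group, _)) in enumerate(
            zip(epochs.epochs, epochs.provenance)):
        try:
            data = zscore_epoch(epoch) if config.zscore else np.asarray(epoch, float)
        except ValueError as exc:
            raise ValueError(f"normalization failed on epoch {i}: {exc}") from exc
        vals = []
        for c, ch in enumerate(channels):
            try:
                feats = extract_features(data[c], config)
            except ValueError as exc:
                raise ValueError(
                    f"feature extraction failed on epoch {i}, channel {ch}: {exc}"
                ) from exc
            vals.extend(feats.values())
        rows[i] = vals
        labels.append(group)
        subjects.append(subject)
    values = pd.DataFrame(rows, columns=columns)
    return FeatureTable(values=values, labels=np.asarray(labels),
                        subjects=np.asarray(subjects), channels=tuple(channels),
                        features=tuple(config.features), config=config.to_dict())
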