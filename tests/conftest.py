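import logging

import numpy as np
import pandas as pd
import pytest

from eegselect.features import FeatureTable

logging.getLogger("eegselect").setLevel(logging.ERROR)


def make_table(values: dict[str, np.ndarray], labels, subjects) -> FeatureTable:
    """Build a FeatureTable from a {"CH.FEAT": column} mapping."""
    df = pd.DataFrame(values)
    channels, features = [], []
    for col in df.columns:
        ch, feat = col.split(".", 1)
        if ch not in channels:
            channels.append(ch)
        if feat not in features:
            features.append(feat)
    return FeatureTable(values=df, labels=np.asarray(labels),
                        subjects=np.asarray(subjects),
                        channels=tuple(channels), features=tuple(features))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def random_clouds():
    """100 seeded random SODP point clouds of varied size."""
    from eegselect.sodp import SODPPoints

    gen = np.random.default_rng(7)
    clouds = []
    for _ in range(100):
        n = int(gen.integers(5, 80))
        scale = float(gen.uniform(0.1, 10.0))
        clouds.append(SODPPoints(x=scale * gen.standard_normal(n),
                                 y=scale * gen.standard_normal(n)))
    return clouds
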