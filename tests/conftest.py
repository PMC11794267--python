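import numpy as np
import pytest

from emgsel.classifier import ANNConfig
from emgsel.features import FeatureMatrix
from emgsel.synth import SynthConfig, generate_recording


def make_feature_matrix(X, y, names, subjects=None):
    """Wrap a plain (rows x features) array as a single-channel FeatureMatrix."""
    names = tuple(names)
    return FeatureMatrix(
        values=np.asarray(X, dtype=float),
        column_meta=[(0, n) for n in names],
        labels=np.asarray(y),
        feature_names=names,
        n_channels=1,
        subjects=subjects,
    )


@pytest.fixture(scope="session")
def fast_ann():
    """Desk-scale ANN: the fixed 3x20 ReLU architecture, reduced epochs."""
    return ANNConfig(max_iter=150, seed=0)


@pytest.fixture(scope="session")
def small_recording():
    """Small 6-movement recording: 4 channels, 2 reps of 2 s, 1 s rest."""
    cfg = SynthConfig(n_channels=4, n_reps=2, rep_duration=2.0,
                      rest_duration=1.0, seed=11)
    return generate_recording(cfg)
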