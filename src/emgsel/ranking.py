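"""Single-feature ranking and threshold elimination.

Each catalog feature is scored by the cross-validated accuracy of the ANN
when given only that feature's columns (one value per channel, so an
n_channels-dimensional input per window).  Features whose accuracy falls
below the elimination threshold are dropped.  The commonly retained 16-name
set from the amplitude-family features is shipped as the ``paper16`` preset
so downstream stages can run without re-ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import ANNConfig, evaluate_cv
from .features import FeatureMatrix

__all__ = ["FeatureRanking", "rank_features", "apply_retention", "PAPER16"]

# Reference retained set: amplitude/difference family features that survive
# the 85% single-feature accuracy cut on real recordings.
PAPER16 = (
    "MMAV1", "IQR", "MAD", "IAV", "IEMG", "VO", "MAV", "STD",
    "DAMV", "WL", "DASDV", "ASS", "MFL", "LDAMV", "RMS", "LD",
)


class ParameterError(ValueError):
    pass


class EmptyRetentionError(ValueError):
    pass


@dataclass
class FeatureRanking:
    accuracies: dict            # feature name -> CV mean accuracy
    threshold: float
    retained: tuple             # descending accuracy, ties by catalog order
    eliminated: tuple

    def to_frame(self) -> pd.DataFrame:
        order = sorted(self.accuracies,
                       key=lambda f: (-self.accuracies[f], list(self.accuracies).index(f)))
        return pd.DataFrame({
            "feature": order,
            "accuracy": [self.accuracies[f] for f in order],
            "retained": [f in self.retained for f in order],
        })


def rank_features(fm: FeatureMatrix, cfg: ANNConfig | None = None,
                  threshold: float = 0.85, subject_filter=None,
                  k: int = 5, seed: int = 0) -> FeatureRanking:
    """Score every feature in ``fm`` individually and apply the threshold.

    ``subject_filter`` optionally restricts rows to one subject, matching the
    single-subject ranking protocol.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold {threshold} outside [0, 1]")
    rows = slice(None)
    if subject_filter is not None:
        if fm.subjects is None:
            raise ParameterError("feature matrix has no subject metadata")
        rows = np.asarray(fm.subjects) == subject_filter
    y = fm.labels[rows]
    accuracies = {}
    for feat in fm.feature_names:
        cols = fm.columns_for(feat)
        rep = evaluate_cv(fm.values[rows][:, cols], y, cfg, k=k, seed=seed)
        accuracies[feat] = rep.mean_accuracy
    catalog_pos = {f: i for i, f in enumerate(fm.feature_names)}
    ordered = sorted(fm.feature_names,
                     key=lambda f: (-accuracies[f], catalog_pos[f]))
    retained = tuple(f for f in ordered if accuracies[f] >= threshold)
    eliminated = tuple(f for f in ordered if accuracies[f] < threshold)
    return FeatureRanking(accuracies=accuracies, threshold=threshold,
                          retained=retained, eliminated=eliminated)


def apply_retention(fm: FeatureMatrix, ranking: FeatureRanking) -> FeatureMatrix:
    """Restrict the matrix to the retained features (all channels of each)."""
    unknown = set(ranking.retained) - set(fm.feature_names)
    if unknown:
        raise ParameterError(f"ranking features not in matrix: {sorted(unknown)}")
    if not ranking.retained:
        raise EmptyRetentionError("no features retained at threshold "
                                  f"{ranking.threshold}")
    return fm.subset(ranking.retained)
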