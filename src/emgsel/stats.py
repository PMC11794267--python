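"""One-way ANOVA for comparing groups of accuracy replicates."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["AnovaResult", "anova_oneway"]


class DegenerateGroupsError(ValueError):
    pass


@dataclass
class AnovaResult:
    labels: list
    group_means: list
    F: float
    df_between: int
    df_within: int
    p: float

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "group_means": [float(m) for m in self.group_means],
            "F": float(self.F),
            "df_between": int(self.df_between),
            "df_within": int(self.df_within),
            "p": float(self.p),
        }


def anova_oneway(groups, labels=None) -> AnovaResult:
    """Classical between/within mean-square F test over >= 2 groups.

    Requires each group to have >= 2 values and at least one group with
    nonzero within-group variance (otherwise the F statistic is undefined).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise DegenerateGroupsError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise DegenerateGroupsError("every group needs at least 2 values")
    if all(np.var(g) == 0 for g in groups):
        raise DegenerateGroupsError("all groups have zero within-group variance")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    F, p = sps.f_oneway(*groups)
    n_total = sum(len(g) for g in groups)
    return AnovaResult(
        labels=list(labels),
        group_means=[float(g.mean()) for g in groups],
        F=float(F),
        df_between=len(groups) - 1,
        df_within=n_total - len(groups),
        p=float(p),
    )
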