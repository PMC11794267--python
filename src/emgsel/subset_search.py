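"""Exhaustive feature-subset search with shared-fold ANN evaluation.

Every k-combination of the retained features is evaluated by stratified
cross-validation of the ANN, with one fold assignment shared across all
subsets so accuracies are directly comparable.  Results are ranked by mean
accuracy (ties broken by lexicographic subset order over the input feature
ordering) and the top 10 reported.  A JSON checkpoint makes long searches
resumable with an identical final report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import ANNConfig, CVReport, evaluate_cv, stratified_folds
from .features import FeatureMatrix
from .stats import AnovaResult, anova_oneway

__all__ = ["SubsetResult", "SearchReport", "SizeComparison",
           "enumerate_subsets", "exhaustive_search", "compare_set_sizes"]


class ParameterError(ValueError):
    pass


@dataclass
class SubsetResult:
    subset: tuple
    k: int
    cv: CVReport


@dataclass
class SearchReport:
    k: int
    n_evaluated: int
    results: list                    # SubsetResult, sorted by mean accuracy desc
    top10: list
    accuracy_range: tuple            # (min, max) over all subsets

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.results) + 1),
            "subset": ["+".join(r.subset) for r in self.results],
            "mean_accuracy": [r.cv.mean_accuracy for r in self.results],
            "sd_accuracy": [r.cv.sd_accuracy for r in self.results],
        })

    def to_json(self, path) -> None:
        payload = {
            "k": self.k,
            "n_evaluated": self.n_evaluated,
            "accuracy_range": list(self.accuracy_range),
            "results": [
                {"subset": list(r.subset), "cv": r.cv.to_dict()} for r in self.results
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class SizeComparison:
    ks: list
    top10_means: dict               # k -> mean of top-10 accuracies
    anova: AnovaResult
    accuracy_increases_with_k: bool
    groups: dict = field(default_factory=dict)  # k -> top-10 accuracy vector


def enumerate_subsets(features, k: int) -> list:
    """All k-subsets in lexicographic order over the input ordering."""
    features = list(features)
    if not 1 <= k <= len(features):
        raise ParameterError(f"k={k} outside [1, {len(features)}]")
    out = list(combinations(features, k))
    assert len(out) == comb(len(features), k)
    return out


def exhaustive_search(fm: FeatureMatrix, retained, k: int,
                      cfg: ANNConfig | None = None, seed: int = 0,
                      cv_k: int = 5, checkpoint_path=None) -> SearchReport:
    """Evaluate every k-subset of ``retained`` (all channels per feature).

    The stratified fold assignment is computed once from ``seed`` and reused
    for every subset.  If ``checkpoint_path`` exists, finished subsets are
    loaded from it and skipped; progress is appended as the search runs.
    """
    retained = list(retained)
    missing = set(retained) - set(fm.feature_names)
    if missing:
        raise ParameterError(f"retained features not in matrix: {sorted(missing)}")
    subsets = enumerate_subsets(retained, k)
    folds = stratified_folds(fm.labels, k=cv_k, seed=seed)

    done = {}
    ckpt = Path(checkpoint_path) if checkpoint_path else None
    if ckpt and ckpt.exists():
        for line in ckpt.read_text().splitlines():
            rec = json.loads(line)
            done[tuple(rec["subset"])] = rec["cv"]

    results = []
    for subset in subsets:
        if subset in done:
            cv_dict = done[subset]
            cv = CVReport(fold_accuracies=cv_dict["fold_accuracies"],
                          mean_accuracy=cv_dict["mean_accuracy"],
                          sd_accuracy=cv_dict["sd_accuracy"],
                          n_samples=cv_dict["n_samples"],
                          n_classes=cv_dict["n_classes"],
                          train_seconds=cv_dict["train_seconds"])
        else:
            cols = fm.columns_for(subset)
            try:
                cv = evaluate_cv(fm.values[:, cols], fm.labels, cfg, folds=folds)
            except Exception as exc:
                raise RuntimeError(f"evaluation failed for subset {subset}") from exc
            if ckpt:
                with ckpt.open("a") as fh:
                    fh.write(json.dumps({"subset": list(subset),
                                         "cv": cv.to_dict()}) + "\n")
        results.append(SubsetResult(subset=subset, k=k, cv=cv))

    # stable sort keeps lexicographic order among ties
    results.sort(key=lambda r: -r.cv.mean_accuracy)
    accs = [r.cv.mean_accuracy for r in results]
    return SearchReport(k=k, n_evaluated=len(results), results=results,
                        top10=results[:10],
                        accuracy_range=(min(accs), max(accs)))


def compare_set_sizes(reports) -> SizeComparison:
    """Compare top-10 accuracies across subset sizes with one-way ANOVA."""
    reports = list(reports)
    if len(reports) < 2:
        raise ParameterError("need >= 2 set sizes to compare")
    groups, top10_means = {}, {}
    for rep in reports:
        accs = [r.cv.mean_accuracy for r in rep.top10]
        if len(accs) < 2:
            raise ParameterError(f"k={rep.k} has fewer than 2 top-set accuracies")
        groups[rep.k] = accs
        top10_means[rep.k] = float(np.mean(accs))
    ks = sorted(groups)
    anova = anova_oneway([groups[k] for k in ks], labels=[str(k) for k in ks])
    means = [top10_means[k] for k in ks]
    increasing = all(b >= a for a, b in zip(means, means[1:]))
    return SizeComparison(ks=ks, top10_means=top10_means, anova=anova,
                          accuracy_increases_with_k=increasing, groups=groups)
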