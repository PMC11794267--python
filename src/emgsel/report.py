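"""Pipeline report bundle: config snapshot, CSV tables, JSON summary, log.

A report directory is self-contained: it records the seeds and decided
parameters alongside the ranking table, the reduction-method comparison
(method, mean accuracy, SD, wall-clock seconds), one search table per subset
size, and any ANOVA results.  Stages that were not run are flagged rather
than omitted so partial runs remain interpretable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["build_report"]


def build_report(out_dir, ranking=None, reductions=None, searches=None,
                 anova=None, config=None) -> Path:
    """Write a report directory; returns its path.

    ``reductions`` is a mapping method -> (CVReport, seconds); ``searches``
    a mapping k -> SearchReport; ``anova`` a mapping name -> AnovaResult.
    """
    if all(x is None for x in (ranking, reductions, searches, anova)):
        raise ValueError("at least one stage result is required")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"config": config or {}, "stages": {}}
    log = []

    if ranking is not None:
        ranking.to_frame().to_csv(out / "ranking.csv", index=False)
        summary["stages"]["ranking"] = {
            "threshold": ranking.threshold,
            "n_retained": len(ranking.retained),
            "retained": list(ranking.retained),
        }
        log.append(f"ranking: {len(ranking.retained)} features retained at "
                   f"threshold {ranking.threshold}")
    else:
        summary["stages"]["ranking"] = "not run"
        log.append("ranking: not run")

    if reductions is not None:
        rows = [{"method": m, "mean_accuracy": rep.mean_accuracy,
                 "sd_accuracy": rep.sd_accuracy, "seconds": secs}
                for m, (rep, secs) in reductions.items()]
        pd.DataFrame(rows).to_csv(out / "reduction_comparison.csv", index=False)
        summary["stages"]["reduction"] = {
            m: {"mean_accuracy": rep.mean_accuracy, "seconds": secs}
            for m, (rep, secs) in reductions.items()
        }
        log.append(f"reduction: {len(reductions)} methods compared")
    else:
        summary["stages"]["reduction"] = "not run"
        log.append("reduction: not run")

    if searches is not None:
        for k, rep in searches.items():
            rep.to_frame().to_csv(out / f"search_k{k}.csv", index=False)
        summary["stages"]["search"] = {
            str(k): {"n_evaluated": rep.n_evaluated,
                     "accuracy_range": list(rep.accuracy_range),
                     "best_subset": list(rep.results[0].subset)}
            for k, rep in searches.items()
        }
        log.append(f"search: set sizes {sorted(searches)}")
    else:
        summary["stages"]["search"] = "not run"
        log.append("search: not run")

    if anova is not None:
        payload = {name: res.to_dict() for name, res in anova.items()}
        (out / "anova.json").write_text(json.dumps(payload, indent=1))
        summary["stages"]["anova"] = list(anova)
        log.append(f"anova: {list(anova)}")
    else:
        summary["stages"]["anova"] = "not run"
        log.append("anova: not run")

    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    (out / "report.log").write_text("\n".join(log) + "\n")
    return out
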