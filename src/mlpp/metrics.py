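"""Ranking metrics with bootstrap confidence intervals.

auROC, partial auROC at FPR < 0.1 (standardized to [0, 1] by dividing
the restricted area by the FPR budget), and average precision, each
with a 1000-resample percentile bootstrap 95% CI.  Also the
pathway-level percentile comparison used to contrast scorers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score, roc_curve

N_BOOTSTRAP = 1000
PARTIAL_AUC_MAX_FPR = 0.1


def partial_auroc(y_true, y_score, max_fpr: float = PARTIAL_AUC_MAX_FPR) -> float:
    """Area under the ROC restricted to FPR < max_fpr, rescaled to [0, 1].

    The restricted area is divided by max_fpr, so a perfect ranking
    scores 1 and a random one ~0.5 * max_fpr / max_fpr = 0.5 of the
    diagonal's share, i.e. ~0.05 at max_fpr = 0.1.
    """
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        return float("nan")
    fpr, tpr, _ = roc_curve(y_true, y_score)
    # interpolate the curve at max_fpr and integrate up to it
    tpr_at = np.interp(max_fpr, fpr, tpr)
    keep = fpr < max_fpr
    xs = np.concatenate([fpr[keep], [max_fpr]])
    ys = np.concatenate([tpr[keep], [tpr_at]])
    return float(np.trapezoid(ys, xs) / max_fpr)


def _point_metrics(y_true, y_score) -> dict[str, float]:
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        return {"auroc": float("nan"), "partial_auroc": float("nan"),
                "average_precision": float("nan")}
    return {
        "auroc": float(roc_auc_score(y_true, y_score)),
        "partial_auroc": partial_auroc(y_true, y_score),
        "average_precision": float(average_precision_score(y_true, y_score)),
    }


@dataclass
class MetricReport:
    """Point estimates with percentile-bootstrap 95% CIs."""

    n: int
    n_positive: int
    auroc: float
    partial_auroc: float
    average_precision: float
    ci: dict[str, tuple[float, float]]

    def as_dict(self) -> dict:
        return asdict(self)


def evaluate(
    y_score,
    y_true,
    n_bootstrap: int = N_BOOTSTRAP,
    seed: int = 0,
) -> MetricReport:
    """Score a ranking against binary labels.

    Single-class inputs yield NaN metrics.  CIs are percentile
    bootstrap over ``n_bootstrap`` resamples of the (score, label)
    rows (default 1000).
    """
    y_true = np.asarray(y_true).astype(int)
    y_score = np.asarray(y_score, dtype=float)
    if y_true.shape != y_score.shape:
        raise ValueError("score/label vectors must be aligned")
    point = _point_metrics(y_true, y_score)
    ci: dict[str, tuple[float, float]] = {}
    if n_bootstrap and len(np.unique(y_true)) == 2:
        rng = np.random.default_rng(seed)
        samples: dict[str, list[float]] = {k: [] for k in point}
        n = len(y_true)
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            m = _point_metrics(y_true[idx], y_score[idx])
            for k, v in m.items():
                if np.isfinite(v):
                    samples[k].append(v)
        for k, vs in samples.items():
            if vs:
                lo, hi = np.percentile(vs, [2.5, 97.5])
                ci[k] = (float(lo), float(hi))
    return MetricReport(
        n=len(y_true),
        n_positive=int(y_true.sum()),
        auroc=point["auroc"],
        partial_auroc=point["partial_auroc"],
        average_precision=point["average_precision"],
        ci=ci,
    )


def pathway_percentile_comparison(
    method_scores: dict[str, pd.Series],
    pathway_sets: dict[str, set],
    exclude_pairs: set | None = None,
) -> pd.DataFrame:
    """Median within-pathway score percentile, per pathway and method.

    Each method's scores over the common evaluated pair universe are
    converted to percentile ranks in (0, 100]; for every pathway the
    median percentile of its within-pathway pairs is reported.  Pairs
    in ``exclude_pairs`` (e.g. paralogs) are dropped before ranking.
    Pathways with no scorable pair are skipped.
    """
    if not method_scores:
        raise ValueError("no method scores supplied")
    common = None
    for s in method_scores.values():
        common = s.index if common is None else common.intersection(s.index)
    if exclude_pairs:
        common = common[~common.isin(exclude_pairs)]
    if len(common) == 0:
        raise ValueError("empty common pair universe")

    percentiles = {
        m: pd.Series(
            rankdata(s.loc[common].to_numpy(), method="average") / len(common) * 100.0,
            index=common,
        )
        for m, s in method_scores.items()
    }
    rows = []
    for pw, pairs in sorted(pathway_sets.items()):
        idx = common[common.isin(pairs)]
        if len(idx) == 0:
            continue
        row = {"pathway": pw, "n_pairs": len(idx)}
        for m, pct in percentiles.items():
            row[m] = float(pct.loc[idx].median())
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["n_pairs", *method_scores]).rename_axis("pathway")
    return pd.DataFrame(rows).set_index("pathway")
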