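"""PathScore: random-walk prioritization of genes on a predicted network.

The predicted-probability matrix for an interaction context is
sparsified (entries below the 75th percentile of off-diagonal values
set to 0), rows are divided by their sums to form a stochastic walk
matrix, and the walk's stationary distribution is computed by power
iteration.  Min-max scaling of the stationary mass gives the PathScore
in [0, 1]; the descending-score rank prioritizes genes, and a label is
vetted by the precision of its top-100 ranks against known members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata

DEFAULT_PERCENTILE = 75.0
DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 100_000
PRECISION_K = 100
MIN_PRECISION = 0.10


def sparsify(pred: pd.DataFrame, percentile: float = DEFAULT_PERCENTILE) -> pd.DataFrame:
    """Zero entries below the given percentile of off-diagonal values.

    The diagonal (self-interaction) is forced to 0 and excluded from
    the percentile computation.  An all-equal matrix keeps everything
    (with a warning).
    """
    if not 0 <= percentile < 100:
        raise ValueError("percentile must be in [0, 100)")
    vals = pred.to_numpy(dtype=float).copy()
    np.fill_diagonal(vals, 0.0)
    off = vals[~np.eye(len(vals), dtype=bool)]
    threshold = float(np.percentile(off, percentile))
    if off.size and np.all(off == off[0]):
        warnings.warn("all off-diagonal values equal; nothing sparsified",
                      stacklevel=2)
    vals[vals < threshold] = 0.0
    np.fill_diagonal(vals, 0.0)
    return pd.DataFrame(vals, index=pred.index, columns=pred.columns)


def row_normalize(w: pd.DataFrame, dangling: str = "uniform") -> pd.DataFrame:
    """Divide each row by its sum to form a stochastic matrix.

    Dangling (all-zero) rows are replaced by the uniform distribution
    (``dangling="uniform"``) or left as zero (``"keep"``).
    """
    vals = w.to_numpy(dtype=float).copy()
    if (vals < 0).any():
        raise ValueError("walk matrix must be non-negative")
    sums = vals.sum(axis=1)
    dang = sums == 0
    sums_safe = np.where(dang, 1.0, sums)
    out = vals / sums_safe[:, None]
    if dang.any() and dangling == "uniform":
        out[dang] = 1.0 / vals.shape[1]
    return pd.DataFrame(out, index=w.index, columns=w.columns)


def stationary_distribution(
    w: pd.DataFrame | np.ndarray,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by power method.

    Iterates the lazy-walk update pi <- (pi + pi P) / 2 from the
    uniform start until the L1 change drops below ``tol``.  The lazy
    walk has the same stationary distribution as P but converges
    geometrically even on periodic (bipartite) graphs; raises on
    non-convergence with diagnostics.
    """
    P = np.asarray(w, dtype=float)
    n = P.shape[0]
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("matrix is not row-stochastic; row-normalize first")
    pi = np.full(n, 1.0 / n)
    for it in range(max_iter):
        nxt = 0.5 * (pi + pi @ P)
        nxt /= nxt.sum()  # guard drift
        delta = np.abs(nxt - pi).sum()
        pi = nxt
        if delta < tol:
            return pi
    raise RuntimeError(
        f"power method did not converge in {max_iter} iterations "
        f"(last L1 change {delta:.3e})"
    )


@dataclass
class PathScoreResult:
    """Stationary mass, scaled score and rank per gene."""

    table: pd.DataFrame          # columns: pi, score, rank
    excluded_genes: list[str]    # outside the largest connected component
    threshold_percentile: float

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]

    def top(self, k: int) -> list[str]:
        return list(self.table.sort_values(["rank"]).index[:k])


def pathscore(
    pred: pd.DataFrame,
    percentile: float = DEFAULT_PERCENTILE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    damping: float | None = None,
) -> PathScoreResult:
    """Full PathScore pipeline for one interaction-context network.

    sparsify -> restrict to the largest strongly connected component of
    the surviving graph -> row-normalize -> stationary distribution ->
    min-max scale to [0, 1] -> descending ranks (ties: average).  Genes
    outside the component are reported excluded (score NaN, rank last).
    ``damping`` optionally mixes in uniform teleportation (off by
    default; the plain walk is the published procedure).
    """
    sp = sparsify(pred, percentile=percentile)
    vals = sp.to_numpy()
    if not vals.any():
        raise ValueError("graph is empty after sparsification")
    n_comp, comp = connected_components(vals != 0, directed=True,
                                        connection="strong")
    sizes = np.bincount(comp, minlength=n_comp)
    # ignore singleton components of isolated genes when picking largest
    main = int(np.argmax(sizes))
    in_main = comp == main
    if sizes[main] < 2:
        raise ValueError("largest connected component is a single gene")
    genes = pd.Index(pred.index)
    excluded = list(genes[~in_main])

    P = row_normalize(sp.iloc[in_main, :].iloc[:, in_main])
    Pv = P.to_numpy()
    if damping:
        Pv = (1 - damping) * Pv + damping / Pv.shape[0]
    pi = stationary_distribution(Pv, tol=tol, max_iter=max_iter)

    span = pi.max() - pi.min()
    if span <= 1e-12:
        warnings.warn("degenerate stationary distribution; all scores 0",
                      stacklevel=2)
        score = np.zeros_like(pi)
    else:
        score = np.clip((pi - pi.min()) / span, 0.0, 1.0)

    table = pd.DataFrame(index=genes)
    table["pi"] = pd.Series(pi, index=genes[in_main])
    table["score"] = pd.Series(score, index=genes[in_main])
    # descending score rank; excluded genes rank after everything else
    ranks = rankdata(-table["score"].fillna(-np.inf).to_numpy(), method="average")
    table["rank"] = ranks
    return PathScoreResult(table=table, excluded_genes=excluded,
                           threshold_percentile=percentile)


def precision_at_k(result: PathScoreResult, known_genes: set,
                   k: int = PRECISION_K) -> float:
    """Fraction of the k top-ranked genes that are known members."""
    if k > len(result.table):
        raise ValueError(f"k={k} exceeds the {len(result.table)} scored genes")
    top = result.top(k)
    return len(set(top) & set(known_genes)) / k


def vet_labels(
    results: dict[str, PathScoreResult],
    known_sets: dict[str, set],
    k: int = PRECISION_K,
    min_precision: float = MIN_PRECISION,
) -> dict[str, float]:
    """Keep labels whose PathScore precision@k reaches ``min_precision``.

    Returns the precision per retained label; labels below the cutoff
    (10% by default) are discarded.
    """
    kept = {}
    for label, res in sorted(results.items()):
        k_eff = min(k, len(res.table))
        prec = precision_at_k(res, known_sets.get(label, set()), k=k_eff)
        if prec >= min_precision:
            kept[label] = prec
    return kept
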