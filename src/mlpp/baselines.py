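"""Whole-tree phylogenetic-profiling similarity baselines.

Four classic pairwise scorers that use the entire species panel at
once, with no clade structure:

* NPP — normalized phylogenetic profiling: log2 then per-species
  (column) standardization, Pearson correlation between gene rows.
* SVD-Phy — truncated SVD of the profile matrix (first 35% of
  components by default), Pearson correlation between the genes'
  component-score vectors.
* BPP / Hamming — mismatch count between binary presence profiles.
* PrePhyloPro (PPP) — rank of the Jaccard index of binary profiles per
  query gene, with pairs whose Pearson correlation is negative forced
  to the last rank.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.linalg import svd as _svd
from scipy.stats import rankdata

DEFAULT_SVD_COMPONENT_FRACTION = 0.35


def npp_transform(pm: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """log2 + per-column z-score of a (non-negative) profile matrix.

    Zeros are shifted by a pseudocount (half the smallest positive
    value by default) before the log.  Zero-variance columns are set to
    0 with a warning.
    """
    vals = pm.to_numpy(dtype=float).copy()
    if pseudocount is None:
        positive = vals[vals > 0]
        pseudocount = positive.min() / 2 if positive.size else 1.0
    logged = np.log2(vals + pseudocount)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=0)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance species column(s) set to 0",
            stacklevel=2,
        )
    sd_safe = np.where(flat, 1.0, sd)
    out = (logged - mean) / sd_safe
    out[:, flat] = 0.0
    return pd.DataFrame(out, index=pm.index, columns=pm.columns)


def _row_pearson(values: np.ndarray) -> np.ndarray:
    """Pearson correlation between all rows; constant rows -> 0."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    return np.clip(corr, -1.0, 1.0)


def npp_similarity(pm: pd.DataFrame, pseudocount: float | None = None) -> pd.DataFrame:
    """Pearson correlation between NPP-transformed gene rows."""
    npp = npp_transform(pm, pseudocount=pseudocount)
    corr = _row_pearson(npp.to_numpy())
    return pd.DataFrame(corr, index=pm.index, columns=pm.index)


def svdphy_similarity(
    pm: pd.DataFrame,
    component_fraction: float = DEFAULT_SVD_COMPONENT_FRACTION,
) -> pd.DataFrame:
    """Pearson correlation between truncated-SVD component scores.

    Keeps ceil(fraction * min(n_genes, n_species)) components of the
    full SVD.  Singular-vector signs are fixed deterministically (the
    largest-magnitude loading of each component is made positive), as
    Pearson between score vectors is not sign-invariant.
    """
    if not 0 < component_fraction <= 1:
        raise ValueError("component_fraction must be in (0, 1]")
    vals = pm.to_numpy(dtype=float)
    u, s, vt = _svd(vals, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(vals.shape) * np.finfo(float).eps)) if s.size else 0
    k = int(np.ceil(component_fraction * min(vals.shape)))
    if k > rank:
        warnings.warn(
            f"requested {k} components but matrix rank is {rank}; components "
            "beyond the rank carry zero scores",
            stacklevel=2,
        )
    # deterministic sign: largest |loading| in each right singular vector > 0
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = (u * s)[:, :k] * flip[:k]
    corr = _row_pearson(scores)
    return pd.DataFrame(corr, index=pm.index, columns=pm.index)


def hamming_distance(bpm: pd.DataFrame) -> pd.DataFrame:
    """Pairwise count of mismatching species between binary profiles."""
    vals = bpm.to_numpy(dtype=float)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("hamming_distance expects a binary matrix")
    ones = vals @ vals.T
    zeros = (1 - vals) @ (1 - vals).T
    dist = vals.shape[1] - ones - zeros
    return pd.DataFrame(dist, index=bpm.index, columns=bpm.index)


def hamming_similarity(bpm: pd.DataFrame) -> pd.DataFrame:
    """Rank-equivalent similarity: negative Hamming distance."""
    return -hamming_distance(bpm)


def _jaccard_matrix(vals: np.ndarray) -> np.ndarray:
    inter = vals @ vals.T
    row_sums = vals.sum(axis=1)
    union = row_sums[:, None] + row_sums[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return jac


def ppp_rank_similarity(bpm: pd.DataFrame, pm: pd.DataFrame) -> pd.DataFrame:
    """PrePhyloPro rank-of-Jaccard similarity.

    For each query gene, all other genes are ranked by descending
    Jaccard index of binary profiles (ties: average rank).  Wherever
    the Pearson correlation of the normalized profiles is negative the
    rank is forced to last.  Similarity = 1 - (rank-1)/(n-1), computed
    directionally per query and symmetrized by the maximum.
    """
    if list(bpm.index) != list(pm.index):
        raise ValueError("bpm and pm must share the same gene axis")
    vals = bpm.to_numpy(dtype=float)
    n = vals.shape[0]
    if (vals.sum(axis=1) == 0).any():
        warnings.warn("all-zero binary profile(s): Jaccard treated as 0",
                      stacklevel=2)
    jac = _jaccard_matrix(vals)
    corr = _row_pearson(pm.to_numpy(dtype=float))

    sim = np.zeros((n, n))
    for g in range(n):
        others = np.arange(n) != g
        keys = jac[g, others].copy()
        negative = corr[g, others] < 0
        # descending Jaccard -> rank 1 best; negative-correlation pairs last
        ranks = rankdata(-keys, method="average")
        last = float(negative.sum())
        if last:
            # forced-last block shares the trailing average rank
            forced_rank = (n - 1) - (last - 1) / 2
            ranks_ok = rankdata(-keys[~negative], method="average")
            ranks[~negative] = ranks_ok
            ranks[negative] = forced_rank
        sim[g, others] = 1.0 - (ranks - 1.0) / (n - 1 if n > 1 else 1)
    out = np.maximum(sim, sim.T)
    np.fill_diagonal(out, 1.0)
    return pd.DataFrame(out, index=bpm.index, columns=bpm.index)


SIMILARITY_METHODS = {
    "npp": lambda pm, bpm: npp_similarity(pm),
    "svdphy": lambda pm, bpm: svdphy_similarity(pm),
    "bpp": lambda pm, bpm: hamming_similarity(bpm),
    "ppp": lambda pm, bpm: ppp_rank_similarity(bpm, pm),
}


def similarity_matrix(method: str, pm: pd.DataFrame | None,
                      bpm: pd.DataFrame | None) -> pd.DataFrame:
    """Dispatch a baseline similarity by name ('npp', 'svdphy', 'bpp', 'ppp')."""
    try:
        fn = SIMILARITY_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(SIMILARITY_METHODS)}"
        ) from None
    return fn(pm, bpm)
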