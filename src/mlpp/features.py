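"""Per-clade covariance features for gene pairs.

For a gene pair (a, b) and a clade c, the feature is the sample
covariance (ddof=1) between the two genes' normalized profiles over the
clade's unmasked species.  One feature per kept clade yields the
classifier's feature vector; with the published species panel this is
49 clade-wise covariances.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .profiles import CladeSet

logger = logging.getLogger(__name__)


def canonical_pair(g_a: str, g_b: str) -> tuple[str, str]:
    """Unordered-pair canonical form: lexicographic gene-id order."""
    return (g_a, g_b) if g_a <= g_b else (g_b, g_a)


def _pair_cov(x: np.ndarray, y: np.ndarray, ddof: int) -> float:
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    return float(np.dot(xs - xs.mean(), ys - ys.mean()) / (n - ddof))


def clade_covariance(
    pm: pd.DataFrame, g_a: str, g_b: str, clade, ddof: int = 1
) -> float:
    """Covariance of two genes' profiles restricted to one clade.

    ``clade`` may be a Clade object or an iterable of species ids.
    Masked (NA) species are skipped; with fewer than two usable species
    the value is missing (NaN).
    """
    species = sorted(clade.species) if hasattr(clade, "species") else sorted(clade)
    sub = pm.loc[[g_a, g_b], species].to_numpy(dtype=float)
    return _pair_cov(sub[0], sub[1], ddof)


class CladeCovarianceFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer mapping gene pairs to per-clade covariance vectors.

    Parameters
    ----------
    clades : CladeSet or mapping name -> iterable of species
        Clade definitions; feature columns follow the clade order.
    ddof : int, default 1
        Covariance denominator n - ddof (1 = unbiased sample covariance).
    impute_missing : float or None, default 0.0
        Value substituted for undefined features (clade fully masked or
        <2 usable species).  0 encodes "no co-evolution evidence", which
        tree models treat as absent signal.  None keeps NaN.

    Attributes
    ----------
    clade_names_ : list of str
        Feature column order, fixed at fit.
    clade_columns_ : dict name -> integer column indices into the
        fitted profile matrix.
    """

    def __init__(self, clades=None, ddof: int = 1, impute_missing=0.0):
        self.clades = clades
        self.ddof = ddof
        self.impute_missing = impute_missing

    def _clade_items(self):
        if isinstance(self.clades, CladeSet):
            return [(c.name, sorted(c.species)) for c in self.clades.kept]
        if isinstance(self.clades, dict):
            return [(k, sorted(v)) for k, v in self.clades.items()]
        raise TypeError("clades must be a CladeSet or a dict")

    def fit(self, pm: pd.DataFrame, y=None):
        """Bind to a profile matrix (genes x species, NA = masked)."""
        if self.clades is None:
            raise ValueError("clades must be provided")
        cols = pd.Index(pm.columns)
        self.profile_ = pm
        self.clade_names_ = []
        self.clade_columns_ = {}
        for name, species in self._clade_items():
            missing = [s for s in species if s not in cols]
            if missing:
                raise KeyError(
                    f"clade {name!r} references unknown species {missing[:5]}"
                )
            self.clade_names_.append(name)
            self.clade_columns_[name] = cols.get_indexer(species)
        return self

    def transform(self, pairs) -> pd.DataFrame:
        """Feature table for a list of (gene_a, gene_b) pairs.

        Returns a DataFrame indexed by the canonical pair key with one
        covariance column per clade.  Duplicate pairs are collapsed with
        a warning; features are symmetric in the pair by construction.
        """
        pm = self.profile_
        canon = [canonical_pair(a, b) for a, b in pairs]
        uniq = list(dict.fromkeys(canon))
        if len(uniq) < len(canon):
            warnings.warn(
                f"{len(canon) - len(uniq)} duplicate pair(s) collapsed",
                stacklevel=2,
            )
        gene_index = pm.index
        values = pm.to_numpy(dtype=float)
        ia = gene_index.get_indexer([p[0] for p in uniq])
        ib = gene_index.get_indexer([p[1] for p in uniq])
        if (ia < 0).any() or (ib < 0).any():
            bad = [uniq[i] for i in np.flatnonzero((ia < 0) | (ib < 0))[:5]]
            raise KeyError(f"pairs reference genes absent from matrix: {bad}")

        out = np.empty((len(uniq), len(self.clade_names_)))
        for j, name in enumerate(self.clade_names_):
            sub = values[:, self.clade_columns_[name]]
            xa, xb = sub[ia], sub[ib]
            ok = np.isfinite(xa) & np.isfinite(xb)
            n = ok.sum(axis=1)
            xa_f = np.where(ok, xa, 0.0)
            xb_f = np.where(ok, xb, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ma = xa_f.sum(axis=1) / n
                mb = xb_f.sum(axis=1) / n
                cross = (xa_f * xb_f).sum(axis=1) - n * ma * mb
                cov = cross / (n - self.ddof)
            cov[n < 2] = np.nan
            out[:, j] = cov

        n_missing = int(np.isnan(out).sum())
        if n_missing and self.impute_missing is not None:
            logger.info("imputing %d missing clade features as %s",
                        n_missing, self.impute_missing)
            out = np.where(np.isnan(out), self.impute_missing, out)
        idx = pd.MultiIndex.from_tuples(uniq, names=["gene_a", "gene_b"])
        return pd.DataFrame(out, index=idx, columns=self.clade_names_)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.clade_names_, dtype=object)


def build_pair_features(
    pm: pd.DataFrame,
    clades,
    pairs,
    ddof: int = 1,
    impute_missing=0.0,
    chunk_size: int = 100_000,
) -> pd.DataFrame:
    """One row per gene pair, one covariance column per clade.

    Thin functional wrapper over CladeCovarianceFeaturizer; large pair
    lists are processed in chunks to bound memory.
    """
    fz = CladeCovarianceFeaturizer(
        clades=clades, ddof=ddof, impute_missing=impute_missing
    ).fit(pm)
    pairs = list(pairs)
    if len(pairs) <= chunk_size:
        return fz.transform(pairs)
    chunks = [
        fz.transform(pairs[i: i + chunk_size])
        for i in range(0, len(pairs), chunk_size)
    ]
    out = pd.concat(chunks)
    return out[~out.index.duplicated()]
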