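"""Phylogenetic profile matrix construction.

A phylogenetic profile records, for one gene, the similarity of its best
ortholog candidate in every species of a panel.  Profiles are built from
BLAST best-hit tables: the raw bitscore matrix is thresholded, then each
gene row is divided by the bitscore of the gene aligned against itself
(self-hit normalization), which corrects for protein length and
composition so values land in [0, 1].

The species panel is organised into clades (subtrees of the species
taxonomy).  Clades are derived from per-species lineages, small clades
are discarded, and near-duplicate clades (high Jaccard overlap with a
larger clade) are removed so the clade set stays non-redundant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_BITSCORE_MIN = 60.0
DEFAULT_EVALUE_MAX = 1e-3
DEFAULT_CLADE_MIN_SIZE = 10
DEFAULT_CLADE_JACCARD_MAX = 0.8


# ---------------------------------------------------------------------------
# Clades


@dataclass(frozen=True)
class Clade:
    """A named set of species columns of the profile matrix."""

    name: str
    species: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.species)


@dataclass
class CladeSet:
    """Ordered, non-redundant collection of clades with provenance.

    ``kept`` is ordered by decreasing size (ties broken by name) — the
    order used for feature columns everywhere downstream.  ``dropped``
    maps clade name -> reason ("small" or "redundant:<kept clade>").
    """

    kept: list[Clade]
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.kept]

    def __len__(self) -> int:
        return len(self.kept)

    def __iter__(self):
        return iter(self.kept)

    def __getitem__(self, name: str) -> Clade:
        for c in self.kept:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"clade": c.name, "size": c.size,
             "species": ";".join(sorted(c.species)), "status": "kept"}
            for c in self.kept
        ]
        rows += [
            {"clade": n, "size": -1, "species": "", "status": reason}
            for n, reason in self.dropped.items()
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bitscore matrix construction


def _check_hits(hits: pd.DataFrame) -> pd.DataFrame:
    required = {"gene", "species", "bitscore"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return hits


def build_bitscore_matrix(
    hits: pd.DataFrame,
    gene_order: list[str],
    species_order: list[str],
) -> pd.DataFrame:
    """Dense gene x species bitscore matrix from a best-hit table.

    Absent (gene, species) pairs get 0.  Duplicate hits for the same
    (gene, species) are reduced to the maximum bitscore.  Hits whose
    gene or species is not in the requested axes raise.
    """
    hits = _check_hits(hits)
    genes = pd.Index(gene_order)
    species = pd.Index(species_order)
    if genes.has_duplicates or species.has_duplicates:
        raise ValueError("gene_order / species_order must be unique")

    unknown_genes = set(hits["gene"]) - set(genes)
    if unknown_genes:
        raise ValueError(f"unknown gene ids in hit table: {sorted(unknown_genes)[:10]}")
    unknown_species = set(hits["species"]) - set(species)
    if unknown_species:
        raise ValueError(
            f"unknown species ids in hit table: {sorted(unknown_species)[:10]}"
        )

    mat = np.zeros((len(genes), len(species)))
    if len(hits):
        best = hits.groupby(["gene", "species"], sort=False)["bitscore"].max()
        gi = genes.get_indexer(best.index.get_level_values("gene"))
        si = species.get_indexer(best.index.get_level_values("species"))
        mat[gi, si] = best.to_numpy()
    return pd.DataFrame(mat, index=genes, columns=species)


def threshold_bitscores(
    matrix: pd.DataFrame, threshold: float = DEFAULT_BITSCORE_MIN
) -> pd.DataFrame:
    """Zero out entries strictly below ``threshold`` (default 60).

    Entries equal to the threshold are kept ("lower than" is strict).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = matrix.copy()
    vals = out.to_numpy()
    vals[vals < threshold] = 0.0
    return out


def self_hit_normalize(
    matrix: pd.DataFrame,
    self_hits: pd.Series | dict,
    cap: bool = True,
    strict: bool = False,
) -> pd.DataFrame:
    """Divide each gene row by that gene's self-hit bitscore.

    Genes lacking a positive self-hit are dropped with a warning (or
    raise under ``strict=True``).  Rare hits scoring above the self-hit
    (isoforms) are capped at 1.0 unless ``cap=False``.
    """
    self_hits = pd.Series(self_hits, dtype=float)
    ok = matrix.index.intersection(self_hits.index[self_hits > 0])
    bad = matrix.index.difference(ok)
    if len(bad):
        msg = f"{len(bad)} gene(s) lack a positive self-hit: {list(bad[:5])}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " — dropped", stacklevel=2)
        logger.warning(msg)
    out = matrix.loc[ok].div(self_hits.loc[ok], axis=0)
    if cap:
        out = out.clip(upper=1.0)
    return out


def binarize_by_evalue(
    hits: pd.DataFrame,
    gene_order: list[str],
    species_order: list[str],
    evalue_threshold: float = DEFAULT_EVALUE_MAX,
) -> pd.DataFrame:
    """Binary presence matrix: 1 where a hit's E-value < threshold."""
    hits = _check_hits(hits)
    if "evalue" not in hits.columns:
        raise ValueError("hit table has no 'evalue' column")
    present = hits[hits["evalue"] < evalue_threshold]
    # reuse dense construction, then binarize on hit support
    mat = build_bitscore_matrix(
        present.assign(bitscore=1.0), gene_order, species_order
    )
    return (mat > 0).astype(np.int8)


def mask_species(pm: pd.DataFrame, species_to_mask: set[str]) -> pd.DataFrame:
    """Exclude species columns by setting them to NA.

    Downstream statistics (clade covariances, conservation fractions)
    skip NA entries.  Unmasked entries are untouched.
    """
    unknown = set(species_to_mask) - set(pm.columns)
    if unknown:
        raise KeyError(f"unknown species: {sorted(unknown)}")
    out = pm.copy()
    if species_to_mask:
        out.loc[:, sorted(species_to_mask)] = np.nan
    return out


# ---------------------------------------------------------------------------
# Taxonomy -> clades


def read_taxonomy(path) -> pd.Series:
    """Read a 2-column TSV: species_id <tab> semicolon-joined lineage."""
    df = pd.read_csv(path, sep="\t", header=None, names=["species", "lineage"],
                     dtype=str, comment="#")
    return df.set_index("species")["lineage"]


def clades_from_taxonomy(taxonomy: pd.Series | dict) -> dict[str, set[str]]:
    """All distinct lineage names with their species sets."""
    taxonomy = pd.Series(taxonomy, dtype=str)
    if taxonomy.empty:
        raise ValueError("empty taxonomy")
    out: dict[str, set[str]] = {}
    for sp, lineage in taxonomy.items():
        parts = [p.strip() for p in str(lineage).split(";") if p.strip()]
        if not parts:
            raise ValueError(f"species {sp!r} has an empty lineage")
        for name in parts:
            out.setdefault(name, set()).add(sp)
    return out


def jaccard(a: set | frozenset, b: set | frozenset) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def select_clades(
    taxonomy: pd.Series | dict,
    min_size: int = DEFAULT_CLADE_MIN_SIZE,
    jaccard_max: float = DEFAULT_CLADE_JACCARD_MAX,
) -> CladeSet:
    """Derive the non-redundant clade set from per-species lineages.

    Candidate clades are every distinct lineage name.  Clades with fewer
    than ``min_size`` species are dropped.  The remainder are scanned in
    decreasing-size order (ties broken by name) and a clade is dropped
    as redundant when its Jaccard similarity with an already-kept
    (larger or equal) clade exceeds ``jaccard_max``.
    """
    candidates = clades_from_taxonomy(taxonomy)
    dropped: dict[str, str] = {}
    sized = []
    for name, species in candidates.items():
        if len(species) < min_size:
            dropped[name] = "small"
        else:
            sized.append(Clade(name, frozenset(species)))
    sized.sort(key=lambda c: (-c.size, c.name))
    kept: list[Clade] = []
    for cand in sized:
        clash = next(
            (k for k in kept if jaccard(cand.species, k.species) > jaccard_max),
            None,
        )
        if clash is not None:
            dropped[cand.name] = f"redundant:{clash.name}"
        else:
            kept.append(cand)
    return CladeSet(kept=kept, dropped=dropped)


# ---------------------------------------------------------------------------
# Gene age


def gene_age_category(
    bpm: pd.DataFrame,
    clade_defs: CladeSet | dict[str, set[str]],
    order: tuple[str, ...] = ("Chordata", "Metazoa"),
) -> pd.Series:
    """Classify genes as lineage-restricted ("young") or ancient.

    A gene is X-specific when every species outside clade X lacks the
    gene in the binary presence matrix.  Categories are checked from the
    most specific clade outward, so a Chordata-specific gene is reported
    as "Chordata-specific" even though it is also Metazoa-specific.
    Genes with presence outside all listed clades are labelled "all".
    """
    if isinstance(clade_defs, CladeSet):
        membership = {c.name: set(c.species) for c in clade_defs.kept}
    else:
        membership = {k: set(v) for k, v in clade_defs.items()}
    for name in order:
        if name not in membership:
            raise KeyError(f"clade {name!r} not present in taxonomy/clade set")

    result = pd.Series("all", index=bpm.index, dtype=object)
    assigned = pd.Series(False, index=bpm.index)
    for name in order:  # most specific first
        outside = [s for s in bpm.columns if s not in membership[name]]
        specific = (bpm[outside].sum(axis=1) == 0) & ~assigned
        result[specific] = f"{name}-specific"
        assigned |= specific
    return result
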