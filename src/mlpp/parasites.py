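"""Conservation analysis of parasitic clades.

Parasitic organisms undergo vast gene losses relative to free-living
relatives.  This module quantifies per-organism conservation (fraction
of reference genes with a present ortholog), extracts genes that are
broadly conserved across eukaryotes yet depleted in at least one
parasitic clade, builds the per-clade presence/absence occurrence
matrix of those loss genes with its combination (UpSet-style)
intersection counts, and compares conservation distributions between
groups with a two-sided Mann-Whitney test.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

EUKARYOTE_FRAC_MIN = 0.75   # "more than 75%" — strict
PARASITE_FRAC_MAX = 0.25    # "less than 25%" — strict
CLADE_FOUND_FRAC = 0.5      # "at least 50%" — inclusive
EXACT_TEST_MAX_N = 20


def conservation_fraction(bpm: pd.DataFrame) -> pd.Series:
    """Per-organism fraction of genes present (column mean over unmasked rows)."""
    vals = bpm.to_numpy(dtype=float)
    ok = np.isfinite(vals)
    with np.errstate(invalid="ignore"):
        frac = np.where(ok, vals, 0.0).sum(axis=0) / ok.sum(axis=0)
    return pd.Series(frac, index=bpm.columns, name="conservation")


def read_parasite_table(path) -> pd.DataFrame:
    """TSV with columns species_id, is_parasite, clade, reference_clade."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"species_id", "is_parasite", "clade"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parasite table missing columns: {sorted(missing)}")
    df["is_parasite"] = df["is_parasite"].map(
        {"1": True, "0": False, "True": True, "False": False,
         "true": True, "false": False})
    if df["is_parasite"].isna().any():
        raise ValueError("is_parasite column must be boolean (0/1/True/False)")
    return df.set_index("species_id")


def parasite_loss_genes(
    bpm: pd.DataFrame,
    parasite_table: pd.DataFrame,
    parasitic_clades: list[str] | None = None,
    eukaryote_frac_min: float = EUKARYOTE_FRAC_MIN,
    parasite_frac_max: float = PARASITE_FRAC_MAX,
) -> list[str]:
    """Genes conserved across eukaryotes but lost in a parasitic clade.

    Keeps genes present in more than ``eukaryote_frac_min`` of all
    (unmasked) species AND present in less than ``parasite_frac_max``
    of the parasitic organisms of at least one listed clade.  Clades
    without parasitic members are skipped with a warning.
    """
    overall = conservation_by_gene(bpm)
    conserved = overall > eukaryote_frac_min

    if parasitic_clades is None:
        parasitic_clades = sorted(
            parasite_table.loc[parasite_table["is_parasite"], "clade"].unique()
        )
    lost_somewhere = pd.Series(False, index=bpm.index)
    for clade in parasitic_clades:
        members = parasite_table.index[
            (parasite_table["clade"] == clade) & parasite_table["is_parasite"]
        ]
        members = [s for s in members if s in bpm.columns]
        if not members:
            warnings.warn(f"clade {clade!r} has no parasitic species; skipped",
                          stacklevel=2)
            continue
        frac = conservation_by_gene(bpm[members])
        lost_somewhere |= frac < parasite_frac_max
    return sorted(bpm.index[conserved & lost_somewhere])


def conservation_by_gene(bpm: pd.DataFrame) -> pd.Series:
    """Per-gene fraction of (unmasked) species with a present ortholog."""
    vals = bpm.to_numpy(dtype=float)
    ok = np.isfinite(vals)
    with np.errstate(invalid="ignore"):
        frac = np.where(ok, vals, 0.0).sum(axis=1) / ok.sum(axis=1)
    return pd.Series(frac, index=bpm.index)


def clade_occurrence(
    bpm: pd.DataFrame,
    genes: list[str],
    clades,
    found_frac: float = CLADE_FOUND_FRAC,
) -> pd.DataFrame:
    """Boolean genes x clades matrix: found iff present in >= 50% of the clade.

    ``clades`` is a CladeSet or mapping name -> species; only species
    present in the matrix columns count.
    """
    if hasattr(clades, "kept"):
        clades = {c.name: c.species for c in clades.kept}
    missing = [g for g in genes if g not in bpm.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    sub = bpm.loc[genes]
    out = {}
    for name, species in clades.items():
        cols = [s for s in species if s in bpm.columns]
        if not cols:
            continue
        out[name] = conservation_by_gene(sub[cols]) >= found_frac
    return pd.DataFrame(out, index=pd.Index(genes, name="gene"))


def intersections(com: pd.DataFrame, top_n: int | None = None) -> pd.DataFrame:
    """Exact combination counts of the occurrence matrix (UpSet-style).

    Each gene belongs to exactly one combination — the pattern of
    clades where it is found.  Rows are sorted by descending count,
    ties broken by the combination bitmask for determinism; membership
    lists are included.  ``top_n`` keeps the largest combinations.
    """
    clade_names = list(com.columns)
    rows = []
    patterns = com.astype(bool).apply(tuple, axis=1)
    for pattern, group in patterns.groupby(patterns):
        genes = sorted(group.index)
        bitmask = sum(1 << i for i, f in enumerate(pattern) if f)
        rows.append({
            "combination": "&".join(
                n for n, f in zip(clade_names, pattern) if f) or "(none)",
            "present_in": [n for n, f in zip(clade_names, pattern) if f],
            "count": len(genes),
            "genes": genes,
            "_bitmask": bitmask,
        })
    out = pd.DataFrame(rows).sort_values(
        ["count", "_bitmask"], ascending=[False, True]
    ).drop(columns="_bitmask").reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out


def intersections_to_gmt(table: pd.DataFrame) -> dict[str, set[str]]:
    """Per-combination gene lists in GMT-ready form."""
    return {row["combination"]: set(row["genes"]) for _, row in table.iterrows()}


def compare_conservation(
    profile: pd.Series,
    group_a: list[str],
    group_b: list[str],
) -> dict:
    """Two-sided Mann-Whitney comparison of conservation between groups.

    Uses the exact null distribution for small samples (combined
    n <= 20, no ties) and the tie-corrected normal approximation
    otherwise.  Returns the U statistic, p-value and medians.
    """
    a = profile.loc[list(group_a)].to_numpy(dtype=float)
    b = profile.loc[list(group_b)].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) + len(b) <= EXACT_TEST_MAX_N and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "n_a": len(a),
        "n_b": len(b),
    }
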