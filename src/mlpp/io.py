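"""Readers and writers for the tabular formats the pipeline consumes.

BLAST tabular (outfmt-6-like) best-hit output, gene x species matrices
as TSV (NA = masked), self-hit vectors, and prediction tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "bitscore", "evalue"]


def read_blast_hits(
    path,
    species_map: dict[str, str] | pd.Series | None = None,
    columns: list[str] | None = None,
) -> pd.DataFrame:
    """Read BLAST tabular output into a (gene, species, bitscore, evalue) table.

    ``columns`` names the input columns (default qseqid, sseqid,
    bitscore, evalue).  ``species_map`` maps subject ids to species
    ids; without it the subject id is taken to be the species id
    (one database per species).  Duplicate (gene, species) hits are
    reduced to the best (max bitscore).
    """
    columns = columns or OUTFMT6_COLUMNS
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=columns, usecols=range(len(columns)))
    out = pd.DataFrame({
        "gene": df["qseqid"].astype(str),
        "subject": df["sseqid"].astype(str),
        "bitscore": df["bitscore"].astype(float),
        "evalue": df["evalue"].astype(float),
    })
    if species_map is not None:
        mapping = pd.Series(species_map)
        unknown = set(out["subject"]) - set(mapping.index)
        if unknown:
            raise ValueError(
                f"subjects missing from species map: {sorted(unknown)[:5]}"
            )
        out["species"] = out["subject"].map(mapping)
    else:
        out["species"] = out["subject"]
    out = (
        out.sort_values("bitscore", ascending=False)
        .drop_duplicates(["gene", "species"])
        .reset_index(drop=True)
    )
    return out[["gene", "species", "bitscore", "evalue"]]


def read_matrix(path) -> pd.DataFrame:
    """Gene x species TSV with NA for masked entries."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path, float_format: str = "%.6f") -> None:
    matrix.to_csv(path, sep="\t", float_format=float_format, na_rep="NA")


def read_self_hits(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def write_pair_table(table: pd.DataFrame, path, float_format: str = "%.8g") -> None:
    """Write a pair-indexed table (MultiIndex gene_a/gene_b) as TSV."""
    table.reset_index().to_csv(path, sep="\t", index=False,
                               float_format=float_format)


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["gene_a", "gene_b"])


def write_predictions(probs: pd.Series, path, label: str = "probability") -> None:
    df = probs.rename(label).reset_index()
    df.columns = ["gene_a", "gene_b", label]
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def matrix_hash(matrix: pd.DataFrame) -> str:
    """Stable content hash for provenance manifests."""
    import hashlib

    h = hashlib.sha256()
    h.update("\x1f".join(map(str, matrix.index)).encode())
    h.update("\x1f".join(map(str, matrix.columns)).encode())
    vals = np.ascontiguousarray(matrix.to_numpy(dtype=float))
    h.update(vals.tobytes())
    return h.hexdigest()[:16]
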