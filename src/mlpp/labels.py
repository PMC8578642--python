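"""Gene-set labels, negative sampling and leakage-safe CV splits.

Positive pairs are derived from curated gene sets (GMT files) by
treating each filtered set (3..50 genes) as a fully connected clique.
Unlabeled "negative" pairs are sampled so that the number of distinct
genes they touch approximately matches the positives (preserving the
network topology).  Cross-validation uses Park–Marcotte gene-level
holdout: 30% of genes become test-exclusive per fold (together with
all their high-sequence-similarity partners, bitscore > 60, to prevent
paralog leakage), and test pairs are stratified C1/C2/C3 by how many
of their genes still occur in training pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

Pair = tuple[str, str]

GENE_SET_MIN = 3
GENE_SET_MAX = 50
PATHWAY_TYPE_MIN_PAIRS = 5000
TEST_GENE_FRACTION = 0.3
PARALOG_BITSCORE = 60.0


def canonical_pair(g_a: str, g_b: str) -> Pair:
    return (g_a, g_b) if g_a <= g_b else (g_b, g_a)


# ---------------------------------------------------------------------------
# GMT gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions and top-level mapping."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    hierarchy: dict[str, str] = field(default_factory=dict)  # set -> top level

    def __len__(self) -> int:
        return len(self.sets)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.sets.values():
            out |= s
        return out


def read_gmt(path, uppercase: bool = False) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> ...

    Duplicate genes within a set are deduplicated.  Malformed lines
    (fewer than two columns) raise with the line number.
    """
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: malformed GMT line")
            name, desc, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if uppercase:
                genes = [g.upper() for g in genes]
            sets[name] = set(genes)
            descriptions[name] = desc
    if not sets:
        warnings.warn(f"empty GMT file: {path}", stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(gsc.sets):
            desc = gsc.descriptions.get(name, "")
            genes = "\t".join(sorted(gsc.sets[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def filter_gene_sets(
    gsc: GeneSetCollection,
    min_size: int = GENE_SET_MIN,
    max_size: int = GENE_SET_MAX,
) -> GeneSetCollection:
    """Keep sets with min_size <= |set| <= max_size (both inclusive)."""
    keep = {n: s for n, s in gsc.sets.items() if min_size <= len(s) <= max_size}
    return GeneSetCollection(
        sets=keep,
        descriptions={n: gsc.descriptions.get(n, "") for n in keep},
        hierarchy={n: gsc.hierarchy[n] for n in keep if n in gsc.hierarchy},
    )


def pairs_from_sets(gsc: GeneSetCollection) -> tuple[set[Pair], dict[Pair, list[str]]]:
    """All unordered within-set pairs, with per-set provenance.

    Each gene set is treated as fully connected; a pair shared by
    several sets appears once, its provenance listing every set.
    """
    provenance: dict[Pair, list[str]] = {}
    for name in sorted(gsc.sets):
        for a, b in itertools.combinations(sorted(gsc.sets[name]), 2):
            provenance.setdefault(canonical_pair(a, b), []).append(name)
    return set(provenance), provenance


def select_pathway_types(
    gsc: GeneSetCollection,
    min_pairs: int = PATHWAY_TYPE_MIN_PAIRS,
) -> dict[str, set[Pair]]:
    """Contexts (top-level pathway types) with enough gene pairs.

    Sets are grouped by their top-level mapping; a context is kept iff
    the union of its within-set pairs has at least ``min_pairs``
    members.  Sets without a mapping are counted under "unmapped" and
    excluded.
    """
    by_context: dict[str, set[Pair]] = {}
    n_unmapped = 0
    for name, members in gsc.sets.items():
        context = gsc.hierarchy.get(name)
        if context is None:
            n_unmapped += 1
            continue
        pairs = by_context.setdefault(context, set())
        for a, b in itertools.combinations(sorted(members), 2):
            pairs.add(canonical_pair(a, b))
    if n_unmapped:
        warnings.warn(f"{n_unmapped} gene set(s) lack a top-level mapping",
                      stacklevel=2)
    return {c: p for c, p in sorted(by_context.items()) if len(p) >= min_pairs}


# ---------------------------------------------------------------------------
# Negative sampling


def sample_negatives(
    positives: set[Pair],
    universe_genes,
    ratio: float = 1.0,
    seed: int = 0,
    gene_count_tolerance: float = 0.10,
    max_attempts: int = 1000,
) -> set[Pair]:
    """Random non-positive pairs matched in distinct-gene count.

    Pairs are drawn uniformly from the genes touched by positive pairs
    (so the negatives' topology matches) until the distinct-gene count
    of the negatives lies within ``gene_count_tolerance`` of the
    positives'; after ``max_attempts`` draws the constraint is relaxed
    with a warning.  Reproducible under ``seed``.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(set(universe_genes))
    pos_genes = sorted({g for p in positives for g in p})
    pool = [g for g in pos_genes if g in set(universe)] or universe
    n_target = int(round(ratio * len(positives)))
    if n_target == 0:
        return set()
    max_pairs = len(pool) * (len(pool) - 1) // 2
    if max_pairs - len(positives) < n_target:
        raise ValueError("not enough non-positive pairs in the universe")

    lo = (1 - gene_count_tolerance) * len(pos_genes)
    hi = (1 + gene_count_tolerance) * len(pos_genes)
    best: set[Pair] | None = None
    for _ in range(max_attempts):
        chosen: set[Pair] = set()
        while len(chosen) < n_target:
            k = n_target - len(chosen)
            idx = rng.integers(0, len(pool), size=(2 * k + 8, 2))
            for i, j in idx:
                if i == j:
                    continue
                pair = canonical_pair(pool[i], pool[j])
                if pair not in positives:
                    chosen.add(pair)
                    if len(chosen) == n_target:
                        break
        n_genes = len({g for p in chosen for g in p})
        if lo <= n_genes <= hi:
            return chosen
        best = chosen
    warnings.warn(
        "gene-count matching constraint infeasible; returning last draw",
        stacklevel=2,
    )
    return best if best is not None else set()


# ---------------------------------------------------------------------------
# Paralogs and Park–Marcotte splits


def paralog_pairs_from_bitscores(
    gene_vs_gene: pd.DataFrame, threshold: float = PARALOG_BITSCORE
) -> set[Pair]:
    """Symmetric high-sequence-similarity relation (bitscore > 60).

    Expects a gene x gene bitscore table; the relation is symmetrized
    by the maximum of the two directions and the diagonal is ignored.
    """
    vals = gene_vs_gene.to_numpy(dtype=float)
    vals = np.maximum(vals, vals.T)
    out: set[Pair] = set()
    ii, jj = np.nonzero(vals > threshold)
    genes = list(gene_vs_gene.index)
    for i, j in zip(ii, jj):
        if i < j:
            out.add(canonical_pair(genes[i], genes[j]))
    return out


@dataclass
class Fold:
    """One Park–Marcotte CV fold."""

    train_pairs: list[Pair]
    test_pairs: list[Pair]
    strata: dict[Pair, str]           # pair -> C1 / C2 / C3
    test_exclusive_genes: set[str]


def _paralog_closure(genes: set[str], paralog_pairs: set[Pair]) -> set[str]:
    """Genes plus every gene linked to them by the paralog relation
    (transitively, since grouping is applied to the whole group)."""
    adj: dict[str, set[str]] = {}
    for a, b in paralog_pairs:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    out = set(genes)
    frontier = list(genes)
    while frontier:
        g = frontier.pop()
        for nb in adj.get(g, ()):
            if nb not in out:
                out.add(nb)
                frontier.append(nb)
    return out


def park_marcotte_split(
    pairs: list[Pair] | set[Pair],
    test_gene_frac: float = TEST_GENE_FRACTION,
    n_folds: int = 5,
    paralog_pairs: set[Pair] | None = None,
    seed: int = 0,
) -> list[Fold]:
    """Gene-level holdout CV with C1/C2/C3 stratification.

    Per fold: a fresh random 30% of the genes occurring in the pairs
    becomes test-exclusive; paralogs (bitscore > 60 partners) of
    test-exclusive genes are made test-exclusive too; every pair
    touching a test-exclusive gene goes to test, the rest to train.
    Test pairs are graded by training-gene overlap: C1 both genes occur
    in some training pair, C2 exactly one, C3 neither.
    """
    pairs = sorted({canonical_pair(*p) for p in pairs})
    paralog_pairs = paralog_pairs or set()
    genes = sorted({g for p in pairs for g in p})
    rng = np.random.default_rng(seed)
    folds: list[Fold] = []
    for _ in range(n_folds):
        n_test = max(1, int(round(test_gene_frac * len(genes))))
        test_seed = set(rng.choice(genes, size=n_test, replace=False).tolist())
        test_genes = _paralog_closure(test_seed, paralog_pairs)
        train_pairs = [p for p in pairs if p[0] not in test_genes and p[1] not in test_genes]
        test_pairs = [p for p in pairs if p not in set(train_pairs)]
        train_gene_set = {g for p in train_pairs for g in p}
        strata = {}
        for a, b in test_pairs:
            seen = (a in train_gene_set) + (b in train_gene_set)
            strata[(a, b)] = {2: "C1", 1: "C2", 0: "C3"}[seen]
        if not any(s == "C3" for s in strata.values()):
            warnings.warn("fold has an empty C3 stratum (small universe)",
                          stacklevel=2)
        folds.append(Fold(train_pairs, test_pairs, strata, test_genes))
    return folds


def labeled_pair_table(
    positives: set[Pair],
    negatives: set[Pair],
    contexts: dict[str, set[Pair]] | None = None,
    paralog_pairs: set[Pair] | None = None,
) -> pd.DataFrame:
    """Assemble the labeled-pair table (one row per pair).

    Columns: label (1 positive / 0 unlabeled-negative), one 0/1 column
    per context, and a paralog flag.
    """
    contexts = contexts or {}
    paralog_pairs = paralog_pairs or set()
    rows = []
    for pair in sorted(positives | negatives):
        row = {
            "gene_a": pair[0],
            "gene_b": pair[1],
            "label": int(pair in positives),
            "paralog": int(pair in paralog_pairs),
        }
        for name, cpairs in sorted(contexts.items()):
            row[f"ctx_{name}"] = int(pair in cpairs)
        rows.append(row)
    return pd.DataFrame(rows).set_index(["gene_a", "gene_b"])
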