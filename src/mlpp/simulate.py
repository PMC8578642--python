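"""Synthetic gene x species bitscore matrices with planted co-evolution.

The generator emulates the evolutionary structure that clade-wise
profiling exploits, without any sequence simulation:

* the species panel is partitioned into clades nested under a single
  root clade; each species carries an evolutionary distance from the
  reference organism that grows with its clade index;
* every gene has its own evolutionary rate and loss propensity, so
  bitscores decay as exp(-rate * distance) and retention probability
  shrinks with distance.  This reproduces the phylogeny confound of
  real profiles: all gene pairs share the tree-wide conservation
  trend, and genes with similar rates correlate over the whole tree
  whether or not they are functionally related;
* gene modules additionally share a latent retention pattern inside a
  small number of "signal" clades (correlated Bernoulli presence with
  per-species flip noise) — the signal a per-clade covariance feature
  isolates but a whole-tree similarity dilutes into the confound;
* parasitic species suffer accelerated gene loss, plus a set of
  planted loss genes that are broadly conserved yet specifically lost
  in one parasitic clade;
* paralog pairs are near-duplicate rows (correlated profiles without a
  pathway label), and young genes exist only inside an origin clade.

Ground truth (module membership, signal clades, paralogs, parasites,
loss genes, gene ages) is returned alongside the matrix so every
downstream module is testable without external data.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import GeneSetCollection, write_gmt

ROOT_CLADE = "Eukaryota"


@dataclass
class SimConfig:
    """Study conditions for the synthetic co-evolution fixture."""

    n_species: int = 60
    n_clades: int = 10
    n_modules: int = 8
    module_size_range: tuple[int, int] = (5, 12)
    signal_clades_per_module: int = 2
    latent_retention_p: float = 0.5      # per-species retention in signal clades
    retention_flip_prob: float = 0.05    # member deviation from the latent pattern
    retention_q_range: tuple[float, float] = (0.70, 0.98)  # per-gene loss propensity
    retention_exponent_range: tuple[float, float] = (1.0, 4.0)  # grows with distance
    n_background_genes: int = 200
    n_parasitic_clades: int = 2
    parasite_species_fraction: float = 0.5   # within a parasitic clade
    parasite_extra_loss: float = 0.5         # accelerated loss in parasites
    n_parasite_loss_genes_per_clade: int = 25
    parasite_loss_rate: float = 0.9          # planted loss genes, in-clade parasites
    n_paralog_pairs: int = 10
    paralog_flip_prob: float = 0.05
    n_young_genes: int = 5
    young_origin_clade: int = 0
    bitscore_baseline: tuple[float, float] = (150.0, 300.0)
    evolutionary_rate_range: tuple[float, float] = (0.1, 0.7)  # per gene
    species_distance_range: tuple[float, float] = (0.2, 1.6)   # by clade index
    bitscore_noise_scale: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_species % self.n_clades:
            raise ValueError("n_species must be divisible by n_clades")
        lo, hi = self.module_size_range
        if not (0 < lo <= hi):
            raise ValueError("invalid module size range")
        if self.signal_clades_per_module > self.n_clades:
            raise ValueError("more signal clades than clades")
        for p in (self.latent_retention_p, self.retention_flip_prob,
                  *self.retention_q_range, self.parasite_species_fraction,
                  self.parasite_extra_loss, self.parasite_loss_rate,
                  self.paralog_flip_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth consistent with the emitted matrix by construction."""

    modules: dict[str, set[str]]
    signal_clades: dict[str, list[str]]
    paralog_pairs: set[tuple[str, str]]
    parasite_species: list[str]
    parasitic_clades: list[str]
    parasite_loss_genes: dict[str, list[str]]
    young_genes: dict[str, str]
    background_genes: list[str]


@dataclass
class SimResult:
    hits: pd.DataFrame                # gene, species, bitscore, evalue
    bitscore_matrix: pd.DataFrame     # raw dense matrix (0 = no hit)
    self_hits: pd.Series
    taxonomy: pd.Series               # species -> "Eukaryota;clade_XX"
    parasite_table: pd.DataFrame
    truth: SimTruth
    config: SimConfig

    @property
    def clade_species(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {ROOT_CLADE: set(self.taxonomy.index)}
        for sp, lineage in self.taxonomy.items():
            out.setdefault(lineage.split(";")[-1], set()).add(sp)
        return out


def simulate(cfg: SimConfig | None = None) -> SimResult:
    """Generate a clade-structured bitscore matrix plus ground truth.

    Deterministic under ``cfg.seed``.
    """
    cfg = cfg or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    per_clade = cfg.n_species // cfg.n_clades
    species = [f"s{i:03d}" for i in range(cfg.n_species)]
    clade_names = [f"clade_{c:02d}" for c in range(cfg.n_clades)]
    clade_of = np.repeat(np.arange(cfg.n_clades), per_clade)
    taxonomy = pd.Series(
        [f"{ROOT_CLADE};{clade_names[clade_of[i]]}" for i in range(cfg.n_species)],
        index=pd.Index(species, name="species"),
    )

    # --- gene roster -------------------------------------------------------
    modules: dict[str, set[str]] = {}
    signal_clades: dict[str, list[str]] = {}
    gene_ids: list[str] = []

    def new_gene() -> str:
        g = f"g{len(gene_ids):04d}"
        gene_ids.append(g)
        return g

    module_members: dict[str, list[str]] = {}
    for m in range(cfg.n_modules):
        name = f"module_{m + 1:02d}"
        size = int(rng.integers(cfg.module_size_range[0],
                                cfg.module_size_range[1] + 1))
        members = [new_gene() for _ in range(size)]
        module_members[name] = members
        modules[name] = set(members)
        picks = rng.choice(cfg.n_clades, size=cfg.signal_clades_per_module,
                           replace=False)
        signal_clades[name] = [clade_names[c] for c in sorted(picks)]

    background = [new_gene() for _ in range(cfg.n_background_genes)]
    young = {new_gene(): clade_names[cfg.young_origin_clade]
             for _ in range(cfg.n_young_genes)}

    # --- retention matrix --------------------------------------------------
    # Per-species normalized distance in [0, 1] by clade index (with jitter)
    # drives both retention decay and bitscore decay; per-gene loss
    # propensity q and retention exponent create the phylogeny confound.
    n_genes_core = len(gene_ids)
    dist_frac = clade_of / max(cfg.n_clades - 1, 1)
    dist_frac = np.clip(
        dist_frac + rng.uniform(-0.04, 0.04, size=cfg.n_species), 0.0, 1.0
    )
    e_lo, e_hi = cfg.retention_exponent_range
    exponent = e_lo + (e_hi - e_lo) * dist_frac
    q_lo, q_hi = cfg.retention_q_range
    q_gene = rng.uniform(q_lo, q_hi, size=n_genes_core)
    p_retain = q_gene[:, None] ** exponent[None, :]
    retained = rng.random((n_genes_core, cfg.n_species)) < p_retain
    gene_index = {g: i for i, g in enumerate(gene_ids)}

    for name, members in module_members.items():
        for clade in signal_clades[name]:
            cols = np.flatnonzero(clade_of == clade_names.index(clade))
            latent = rng.random(len(cols)) < cfg.latent_retention_p
            for g in members:
                flips = rng.random(len(cols)) < cfg.retention_flip_prob
                retained[gene_index[g], cols] = latent ^ flips

    for g, clade in young.items():
        row = np.zeros(cfg.n_species, dtype=bool)
        cols = np.flatnonzero(clade_of == clade_names.index(clade))
        row[cols] = rng.random(len(cols)) < 0.8
        if not row.any():
            row[cols[0]] = True
        retained[gene_index[g]] = row

    # --- paralogs: near-duplicates of module genes -------------------------
    paralog_pairs: set[tuple[str, str]] = set()
    all_module_genes = [g for ms in module_members.values() for g in ms]
    parents = rng.choice(all_module_genes,
                         size=min(cfg.n_paralog_pairs, len(all_module_genes)),
                         replace=False)
    paralog_rows = []
    for parent in parents:
        copy = new_gene()
        flips = rng.random(cfg.n_species) < cfg.paralog_flip_prob
        paralog_rows.append(retained[gene_index[parent]] ^ flips)
        paralog_pairs.add((parent, copy) if parent <= copy else (copy, parent))
    if paralog_rows:
        retained = np.vstack([retained, np.array(paralog_rows)])

    # --- parasites ---------------------------------------------------------
    parasitic_clades = [clade_names[c] for c in
                        rng.choice(cfg.n_clades, size=cfg.n_parasitic_clades,
                                   replace=False)]
    parasite_species: list[str] = []
    for clade in parasitic_clades:
        cols = np.flatnonzero(clade_of == clade_names.index(clade))
        n_par = max(1, int(round(cfg.parasite_species_fraction * len(cols))))
        chosen = rng.choice(cols, size=n_par, replace=False)
        parasite_species.extend(species[i] for i in sorted(chosen))

    par_cols = np.array([species.index(s) for s in parasite_species])
    if par_cols.size:
        extra = rng.random((retained.shape[0], par_cols.size)) < cfg.parasite_extra_loss
        retained[:, par_cols] &= ~extra

    # planted loss genes: conserved everywhere, lost in one clade's parasites
    loss_genes: dict[str, list[str]] = {}
    bg_pool = list(background)
    for clade in parasitic_clades:
        chosen = [bg_pool.pop(0) for _ in range(
            min(cfg.n_parasite_loss_genes_per_clade, len(bg_pool)))]
        loss_genes[clade] = chosen
    conserved_loss_genes: set[str] = set()
    for clade, chosen in loss_genes.items():
        cols_all = np.flatnonzero(clade_of == clade_names.index(clade))
        cols_par = np.array([c for c in cols_all if species[c] in parasite_species])
        for g in chosen:
            i = gene_index[g]
            retained[i, :] = rng.random(cfg.n_species) < 0.97  # broadly conserved
            lost = rng.random(cols_par.size) < cfg.parasite_loss_rate
            retained[i, cols_par] = ~lost
            conserved_loss_genes.add(g)

    # --- bitscores ---------------------------------------------------------
    # exp(-rate_g * t_s) decay with lognormal noise; hits decaying below
    # the usual 60-bit threshold are effectively lost in distant clades.
    all_genes = list(gene_ids)
    lo, hi = cfg.bitscore_baseline
    self_hits = pd.Series(rng.uniform(lo, hi, size=len(all_genes)),
                          index=all_genes, name="self_hit")
    r_lo, r_hi = cfg.evolutionary_rate_range
    rate = rng.uniform(r_lo, r_hi, size=len(all_genes))
    # planted conserved loss genes evolve slowly so the thresholded
    # matrix keeps them broadly present outside the parasitic clade
    for g in conserved_loss_genes:
        rate[all_genes.index(g)] = r_lo
    t_lo, t_hi = cfg.species_distance_range
    t_s = t_lo + (t_hi - t_lo) * dist_frac
    noise = rng.normal(0.0, cfg.bitscore_noise_scale,
                       size=(len(all_genes), cfg.n_species))
    bits = (self_hits.to_numpy()[:, None]
            * np.exp(-rate[:, None] * t_s[None, :])
            * np.exp(noise))
    bits = np.clip(bits, 31.0, None)
    bits[~retained] = 0.0

    matrix = pd.DataFrame(bits, index=pd.Index(all_genes, name="gene"),
                          columns=species)

    gi, si = np.nonzero(retained)
    hits = pd.DataFrame({
        "gene": [all_genes[i] for i in gi],
        "species": [species[j] for j in si],
        "bitscore": bits[gi, si],
        "evalue": 10.0 ** (-bits[gi, si] / 10.0),
    })

    parasite_table = pd.DataFrame({
        "species_id": species,
        "is_parasite": [int(s in parasite_species) for s in species],
        "clade": [clade_names[clade_of[i]] for i in range(cfg.n_species)],
        "reference_clade": ROOT_CLADE,
    }).set_index("species_id")
    parasite_table["is_parasite"] = parasite_table["is_parasite"].astype(bool)

    truth = SimTruth(
        modules=modules,
        signal_clades=signal_clades,
        paralog_pairs=paralog_pairs,
        parasite_species=parasite_species,
        parasitic_clades=parasitic_clades,
        parasite_loss_genes=loss_genes,
        young_genes=young,
        background_genes=background,
    )
    return SimResult(hits=hits, bitscore_matrix=matrix, self_hits=self_hits,
                     taxonomy=taxonomy, parasite_table=parasite_table,
                     truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Fixture bundle IO


def write_fixture_bundle(result: SimResult, out_dir) -> dict[str, Path]:
    """Write the fixture as plain-text files that round-trip the readers.

    Emits: matrix.tsv (raw bitscores), self_hits.tsv, hits.tsv,
    taxonomy.tsv, modules.gmt, parasites.tsv, config.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "self_hits": out / "self_hits.tsv",
        "hits": out / "hits.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "gmt": out / "modules.gmt",
        "parasites": out / "parasites.tsv",
        "config": out / "config.json",
    }
    result.bitscore_matrix.to_csv(paths["matrix"], sep="\t", float_format="%.6f")
    result.self_hits.to_frame().to_csv(paths["self_hits"], sep="\t",
                                       float_format="%.6f")
    result.hits.to_csv(paths["hits"], sep="\t", index=False, float_format="%.6g")
    result.taxonomy.to_frame("lineage").to_csv(paths["taxonomy"], sep="\t",
                                               header=False)
    write_gmt(GeneSetCollection(sets=result.truth.modules,
                                descriptions={}), paths["gmt"])
    result.parasite_table.reset_index().to_csv(paths["parasites"], sep="\t",
                                               index=False)
    cfg = dataclasses.asdict(result.config)
    cfg["module_size_range"] = list(cfg["module_size_range"])
    cfg["bitscore_baseline"] = list(cfg["bitscore_baseline"])
    paths["config"].write_text(json.dumps(cfg, indent=2, sort_keys=True))
    return paths


def read_fixture_bundle(in_dir) -> dict:
    """Load a written bundle back through the package's readers."""
    from .labels import read_gmt
    from .parasites import read_parasite_table
    from .profiles import read_taxonomy

    d = Path(in_dir)
    return {
        "matrix": pd.read_csv(d / "matrix.tsv", sep="\t", index_col=0),
        "self_hits": pd.read_csv(d / "self_hits.tsv", sep="\t",
                                 index_col=0)["self_hit"],
        "hits": pd.read_csv(d / "hits.tsv", sep="\t"),
        "taxonomy": read_taxonomy(d / "taxonomy.tsv"),
        "gmt": read_gmt(d / "modules.gmt"),
        "parasites": read_parasite_table(d / "parasites.tsv"),
        "config": json.loads((d / "config.json").read_text()),
    }
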