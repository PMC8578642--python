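"""End-to-end pipeline runner with provenance manifests and caching.

Stages run in dependency order from a single YAML/dict config; every
stage writes its outputs plus a manifest (config hash, seed, input
hashes, tool version) sufficient to reproduce the run bit-identically.
A stage whose manifest hash matches the current config is skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, io
from .attribution import attribute, summarize_importance
from .features import build_pair_features
from .labels import (
    filter_gene_sets,
    labeled_pair_table,
    pairs_from_sets,
    paralog_pairs_from_bitscores,
    park_marcotte_split,
    read_gmt,
    sample_negatives,
)
from .models import cross_validate, make_classifier, prediction_matrix
from .parasites import (
    clade_occurrence,
    conservation_fraction,
    intersections,
    parasite_loss_genes,
    read_parasite_table,
)
from .pathscore import pathscore, precision_at_k
from .profiles import (
    binarize_by_evalue,
    read_taxonomy,
    select_clades,
    self_hit_normalize,
    threshold_bitscores,
)
from .simulate import SimConfig, simulate, write_fixture_bundle

logger = logging.getLogger(__name__)

STAGES = ["simulate", "profiles", "clades", "labels", "features", "cv",
          "shap", "pathscore", "parasites"]

DEFAULTS = {
    "seed": 0,
    "bitscore_min": 60.0,
    "evalue_max": 1e-3,
    "clade_min_size": 10,
    "clade_jaccard_max": 0.8,
    "gene_set_min": 3,
    "gene_set_max": 50,
    "pathway_type_min_pairs": 5000,
    "test_gene_frac": 0.3,
    "n_folds": 5,
    "framework": "rf",
    "sparsify_percentile": 75.0,
    "precision_k": 100,
    "min_precision": 0.10,
    "eukaryote_frac_min": 0.75,
    "parasite_frac_max": 0.25,
    "clade_found_frac": 0.5,
}


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


class Pipeline:
    def __init__(self, config: dict, out_dir):
        self.config = {**DEFAULTS, **(config or {})}
        unknown = set(self.config) - set(DEFAULTS) - {"stages", "sim", "inputs"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.seed = int(self.config["seed"])
        self._state: dict = {}

    # -- caching ------------------------------------------------------------

    def _stage_dir(self, stage: str) -> Path:
        d = self.out / stage
        d.mkdir(exist_ok=True)
        return d

    def _manifest_path(self, stage: str) -> Path:
        return self._stage_dir(stage) / "manifest.json"

    def _fresh(self, stage: str) -> bool:
        p = self._manifest_path(stage)
        if not p.exists():
            return False
        try:
            return json.loads(p.read_text())["config_hash"] == _config_hash(
                self.config
            )
        except (json.JSONDecodeError, KeyError):
            return False

    def _write_manifest(self, stage: str, outputs: dict[str, Path]) -> None:
        manifest = {
            "tool_version": __version__,
            "stage": stage,
            "config_hash": _config_hash(self.config),
            "seed": self.seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {
                k: hashlib.sha256(Path(v).read_bytes()).hexdigest()[:16]
                for k, v in outputs.items()
            },
        }
        self._manifest_path(stage).write_text(json.dumps(manifest, indent=2))

    # -- stages -------------------------------------------------------------

    def run(self, stages: list[str] | None = None) -> dict:
        stages = stages or self.config.get("stages") or STAGES
        bad = set(stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage(s): {sorted(bad)}")
        for stage in STAGES:
            if stage in stages:
                logger.info("stage %s", stage)
                getattr(self, f"stage_{stage}")()
        return self._state

    def stage_simulate(self):
        d = self._stage_dir("simulate")
        sim_cfg = SimConfig(**{**self.config.get("sim", {}),
                               "seed": self.seed})
        result = simulate(sim_cfg)
        self._state["sim"] = result
        if not self._fresh("simulate"):
            paths = write_fixture_bundle(result, d / "fixtures")
            self._write_manifest("simulate", paths)

    def _inputs(self) -> dict:
        """Resolve input files, preferring an in-memory simulation."""
        if "sim" in self._state:
            r = self._state["sim"]
            return {
                "matrix": r.bitscore_matrix,
                "self_hits": r.self_hits,
                "hits": r.hits,
                "taxonomy": r.taxonomy,
                "gmt": None,
                "gene_sets": r.truth.modules,
                "parasites": r.parasite_table,
            }
        paths = self.config.get("inputs", {})
        missing = [k for k in ("matrix", "self_hits", "taxonomy") if k not in paths]
        if missing:
            raise FileNotFoundError(
                f"stage needs input file(s) {missing}; configure 'inputs' or "
                "run the simulate stage first"
            )
        return {
            "matrix": io.read_matrix(paths["matrix"]),
            "self_hits": io.read_self_hits(paths["self_hits"]),
            "hits": pd.read_csv(paths["hits"], sep="\t") if "hits" in paths else None,
            "taxonomy": read_taxonomy(paths["taxonomy"]),
            "gmt": paths.get("gmt"),
            "gene_sets": None,
            "parasites": read_parasite_table(paths["parasites"])
            if "parasites" in paths else None,
        }

    def stage_profiles(self):
        d = self._stage_dir("profiles")
        inp = self._inputs()
        raw = threshold_bitscores(inp["matrix"], self.config["bitscore_min"])
        pm = self_hit_normalize(raw, inp["self_hits"])
        if inp["hits"] is not None:
            bpm = binarize_by_evalue(inp["hits"], list(pm.index),
                                     list(pm.columns), self.config["evalue_max"])
        else:
            bpm = (raw > 0).astype("int8")
        self._state.update(pm=pm, bpm=bpm)
        if not self._fresh("profiles"):
            io.write_matrix(pm, d / "normalized.tsv")
            io.write_matrix(bpm, d / "binary.tsv", float_format="%d")
            self._write_manifest("profiles", {
                "normalized": d / "normalized.tsv", "binary": d / "binary.tsv"})

    def stage_clades(self):
        d = self._stage_dir("clades")
        inp = self._inputs()
        clades = select_clades(inp["taxonomy"],
                               min_size=self.config["clade_min_size"],
                               jaccard_max=self.config["clade_jaccard_max"])
        self._state["clades"] = clades
        if not self._fresh("clades"):
            clades.to_frame().to_csv(d / "clades.tsv", sep="\t", index=False)
            self._write_manifest("clades", {"clades": d / "clades.tsv"})

    def stage_labels(self):
        d = self._stage_dir("labels")
        inp = self._inputs()
        if inp["gene_sets"] is not None:
            from .labels import GeneSetCollection

            gsc = GeneSetCollection(sets={k: set(v) for k, v in
                                          inp["gene_sets"].items()})
        else:
            gsc = read_gmt(inp["gmt"])
        gsc = filter_gene_sets(gsc, self.config["gene_set_min"],
                               self.config["gene_set_max"])
        positives, _ = pairs_from_sets(gsc)
        universe = sorted(self._state["pm"].index)
        negatives = sample_negatives(positives, universe, seed=self.seed)
        paralogs = (self._state["sim"].truth.paralog_pairs
                    if "sim" in self._state else set())
        table = labeled_pair_table(positives, negatives, paralog_pairs=paralogs)
        folds = park_marcotte_split(
            positives | negatives,
            test_gene_frac=self.config["test_gene_frac"],
            n_folds=self.config["n_folds"],
            paralog_pairs=paralogs,
            seed=self.seed,
        )
        self._state.update(pairs_table=table, folds=folds)
        if not self._fresh("labels"):
            io.write_pair_table(table, d / "pairs.tsv")
            self._write_manifest("labels", {"pairs": d / "pairs.tsv"})

    def stage_features(self):
        d = self._stage_dir("features")
        table = self._state["pairs_table"]
        feats = build_pair_features(self._state["pm"], self._state["clades"],
                                    list(table.index))
        self._state["features"] = feats
        if not self._fresh("features"):
            io.write_pair_table(feats, d / "features.tsv")
            (d / "clade_order.json").write_text(
                json.dumps(list(feats.columns), indent=0))
            self._write_manifest("features", {
                "features": d / "features.tsv",
                "clade_order": d / "clade_order.json"})

    def stage_cv(self):
        d = self._stage_dir("cv")
        feats = self._state["features"]
        table = self._state["pairs_table"]
        est = make_classifier(self.config["framework"], random_state=self.seed)
        cv = cross_validate(feats, table["label"], self._state["folds"],
                            estimator=est,
                            paralog_flags=table["paralog"],
                            keep_models=True, seed=self.seed)
        self._state["cv"] = cv
        if not self._fresh("cv"):
            io.write_predictions(cv.predictions, d / "predictions.tsv")
            summary = {
                "framework": self.config["framework"],
                "median_auroc": cv.median("auroc"),
                "median_auroc_C1": cv.median("auroc", "C1"),
                "median_auroc_C2": cv.median("auroc", "C2"),
                "median_auroc_C3": cv.median("auroc", "C3"),
                "median_ap": cv.median("average_precision"),
            }
            (d / "metrics.json").write_text(json.dumps(summary, indent=2))
            self._write_manifest("cv", {"predictions": d / "predictions.tsv",
                                        "metrics": d / "metrics.json"})

    def stage_shap(self):
        d = self._stage_dir("shap")
        if self.config["framework"] != "rf":
            logger.warning("attribution requires the rf framework; skipped")
            return
        feats = self._state["features"]
        table = self._state["pairs_table"]
        est = make_classifier("rf", random_state=self.seed)
        model = est.fit(feats.to_numpy(), table["label"].to_numpy())
        attr = attribute(model, feats)
        self._state["attributions"] = attr
        if not self._fresh("shap"):
            out = attr.contributions.copy()
            out.insert(0, "bias", attr.bias)
            out["probability"] = attr.probability
            io.write_pair_table(out, d / "attributions.tsv")
            summarize_importance(attr, "global").to_csv(
                d / "importance.tsv", sep="\t")
            self._write_manifest("shap", {
                "attributions": d / "attributions.tsv",
                "importance": d / "importance.tsv"})

    def stage_pathscore(self):
        d = self._stage_dir("pathscore")
        cv = self._state["cv"]
        pred = prediction_matrix(cv.predictions)
        ps = pathscore(pred, percentile=self.config["sparsify_percentile"])
        self._state["pathscore"] = ps
        if not self._fresh("pathscore"):
            ps.table.to_csv(d / "scores.tsv", sep="\t", float_format="%.8g",
                            na_rep="NA")
            self._write_manifest("pathscore", {"scores": d / "scores.tsv"})

    def stage_parasites(self):
        d = self._stage_dir("parasites")
        inp = self._inputs()
        bpm = self._state["bpm"]
        if inp["parasites"] is None:
            logger.warning("no parasite annotations; stage skipped")
            return
        cons = conservation_fraction(bpm)
        loss = parasite_loss_genes(
            bpm, inp["parasites"],
            eukaryote_frac_min=self.config["eukaryote_frac_min"],
            parasite_frac_max=self.config["parasite_frac_max"])
        clades = self._state["clades"]
        com = clade_occurrence(bpm, loss, clades,
                               found_frac=self.config["clade_found_frac"])
        inter = intersections(com, top_n=10)
        self._state.update(conservation=cons, loss_genes=loss,
                           loss_intersections=inter)
        if not self._fresh("parasites"):
            cons.to_frame().to_csv(d / "conservation.tsv", sep="\t",
                                   float_format="%.6f")
            pd.Series(loss, name="gene").to_csv(d / "loss_genes.tsv", sep="\t",
                                                index=False)
            inter.drop(columns=["genes", "present_in"]).to_csv(
                d / "intersections.tsv", sep="\t", index=False)
            self._write_manifest("parasites", {
                "conservation": d / "conservation.tsv",
                "loss_genes": d / "loss_genes.tsv",
                "intersections": d / "intersections.tsv"})


def run_pipeline(config: dict, out_dir, stages: list[str] | None = None) -> dict:
    """Run the configured stages; returns the in-memory state dict."""
    return Pipeline(config, out_dir).run(stages)
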