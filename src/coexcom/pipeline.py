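"""End-to-end orchestration: preprocess -> network -> communities ->
classification -> enrichment -> attribution, with a declarative config and a
machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from coexcom import __version__
from coexcom.communities import (DEFAULT_BETA_GRID, DEFAULT_GAMMA_GRID,
                                 hierarchical_detect)
from coexcom.enrichment import enrich_all, read_gmt
from coexcom.io import read_expression, read_metadata, write_expression
from coexcom.ml import (CVConfig, RFConfig, evaluate_community,
                        screen_communities)
from coexcom.network import build_network, graph_summary, write_edge_list
from coexcom.preprocess import DEFAULT_ORDER, preprocess_pipeline
from coexcom.xai import shap_tree, summarize, write_attribution, write_summary
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """Full declarative configuration of one pipeline run."""

    expression: str = ""
    metadata: str = ""
    annotation_gmt: str = ""           # optional; empty disables enrichment
    output_dir: str = "run"
    # preprocessing
    log2_offset: float = 1.0
    preprocess_order: tuple = DEFAULT_ORDER
    batch_adjust: bool = True
    # network
    alpha: float = 0.01
    # community detection
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    beta_grid: tuple = DEFAULT_BETA_GRID
    ensemble_runs: int = 100
    nmi_threshold: float = 0.80
    min_fraction: float = 0.05
    min_community_size: int = 4
    max_community_size: int = 100
    # classification
    n_folds: int = 5
    n_repetitions: int = 100
    rf_trees: int = 300
    rf_features_per_split: object = None
    boruta_trees: int = 30
    boruta_max_iter: int = 20
    accuracy_threshold: float = 0.85
    # enrichment
    enrichment_alpha_raw: float = 0.01
    enrichment_alpha_bonferroni: float = 0.05
    # attribution
    shap_background_cap: int = 100
    shap_top_k: int = 20
    base_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("preprocess_order", "gamma_grid", "beta_grid"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def validate_paths(self) -> None:
        for key in ("expression", "metadata"):
            path = getattr(self, key)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"config {key!r}: file not found: {path}")
        if self.annotation_gmt and not Path(self.annotation_gmt).exists():
            raise FileNotFoundError(
                f"config 'annotation_gmt': file not found: {self.annotation_gmt}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("preprocess_order", "gamma_grid", "beta_grid"):
            d[key] = list(d[key])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _timed(manifest, stage, fn):
    t0 = time.perf_counter()
    result = fn()
    manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
    logger.info("stage %s finished in %.1fs", stage, time.perf_counter() - t0)
    return result


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory.

    Artifacts: preprocessed.tsv, network_edges.tsv, network_summary.json,
    communities.tsv, stability/*.json, performance.tsv,
    gene_frequency/<id>.tsv, screened_communities.txt, enrichment.tsv,
    xai/<id>_attribution.tsv + _summary.tsv, manifest.json.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "config": config.to_dict(),
                "config_hash": config.digest(), "seed": config.base_seed,
                "stages": {}}
    try:
        matrix = read_expression(config.expression)
        metadata = read_metadata(config.metadata)

        processed = _timed(manifest, "preprocess", lambda: preprocess_pipeline(
            matrix, metadata, offset=config.log2_offset,
            order=config.preprocess_order, batch_adjust=config.batch_adjust))
        write_expression(processed, outdir / "preprocessed.tsv")

        graph = _timed(manifest, "network",
                       lambda: build_network(processed, alpha=config.alpha))
        write_edge_list(graph, outdir / "network_edges.tsv")
        (outdir / "network_summary.json").write_text(
            json.dumps(graph_summary(graph), indent=1))

        reports: dict = {}
        discarded: list = []
        records = _timed(manifest, "communities", lambda: hierarchical_detect(
            graph, min_size=config.min_community_size,
            max_size=config.max_community_size,
            gamma_grid=config.gamma_grid, beta_grid=config.beta_grid,
            L=config.ensemble_runs, nmi_threshold=config.nmi_threshold,
            min_fraction=config.min_fraction, base_seed=config.base_seed,
            reports=reports, discarded=discarded))
        _write_communities(records, discarded, outdir / "communities.tsv")
        stability_dir = outdir / "stability"
        stability_dir.mkdir(exist_ok=True)
        for path_tag, report in reports.items():
            fname = path_tag.replace("/", "_") + ".json"
            (stability_dir / fname).write_text(json.dumps(report.to_dict(), indent=1))

        cv = CVConfig(n_folds=config.n_folds, n_repetitions=config.n_repetitions,
                      base_seed=config.base_seed)
        rf = RFConfig(n_trees=config.rf_trees,
                      features_per_split=config.rf_features_per_split)

        def classify():
            out = []
            for rec in records:
                out.append(evaluate_community(
                    processed, metadata, rec, cv, rf,
                    boruta_trees=config.boruta_trees,
                    boruta_max_iter=config.boruta_max_iter))
            return out
        performances = _timed(manifest, "classify", classify)
        perf_table = pd.DataFrame([p.to_row() for p in performances])
        perf_table.to_csv(outdir / "performance.tsv", sep="\t", index=False,
                          float_format="%.6f")
        freq_dir = outdir / "gene_frequency"
        freq_dir.mkdir(exist_ok=True)
        for perf in performances:
            _write_gene_frequency(perf, freq_dir / f"{perf.community_id}.tsv")

        screened = screen_communities(performances,
                                      accuracy_threshold=config.accuracy_threshold)
        (outdir / "screened_communities.txt").write_text(
            "\n".join(screened) + ("\n" if screened else ""))
        manifest["n_final_communities"] = len(records)
        manifest["n_screened"] = len(screened)

        if config.annotation_gmt:
            collection = read_gmt(config.annotation_gmt)
            universe = graph.vs["name"]
            results = _timed(manifest, "enrichment", lambda: enrich_all(
                {r.community_id: r.genes for r in records}, collection, universe,
                alpha_raw=config.enrichment_alpha_raw,
                alpha_bonferroni=config.enrichment_alpha_bonferroni))
            pd.DataFrame([r.to_row() for r in results]).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False,
                float_format="%.6g")

        def explain():
            xai_dir = outdir / "xai"
            xai_dir.mkdir(exist_ok=True)
            by_id = {p.community_id: p for p in performances}
            rec_by_id = {r.community_id: r for r in records}
            for cid in screened:
                perf, rec = by_id[cid], rec_by_id[cid]
                genes = perf.top_genes if perf.top_genes else rec.genes
                X = processed.loc[genes].T  # samples x genes
                y = metadata.loc[X.index, "class"].to_numpy()
                model = RandomForestClassifier(
                    n_estimators=config.rf_trees,
                    max_features=config.rf_features_per_split,
                    random_state=config.base_seed % (2 ** 31), n_jobs=1)
                model.fit(X.to_numpy(), y)
                bg = X
                if len(bg) > config.shap_background_cap:
                    bg = bg.sample(n=config.shap_background_cap,
                                   random_state=config.base_seed % (2 ** 31))
                attr = shap_tree(model, X, bg)
                summary = summarize(attr, top_k=config.shap_top_k)
                write_attribution(attr, xai_dir / f"{cid}_attribution.tsv")
                write_summary(summary, xai_dir / f"{cid}_summary.tsv")
        _timed(manifest, "xai", explain)

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


def _write_communities(records, discarded, path) -> None:
    rows = []
    for rec in list(records) + list(discarded):
        for gene in rec.genes:
            rows.append({
                "gene_id": gene,
                "community_id": rec.community_id,
                "hierarchy_path": "/".join(map(str, rec.hierarchy_path)),
                "final": int(rec.final),
            })
    pd.DataFrame(rows, columns=["gene_id", "community_id", "hierarchy_path",
                                "final"]).to_csv(path, sep="\t", index=False)


def _write_gene_frequency(perf, path) -> None:
    top = set(perf.top_genes)
    rows = [{
        "gene_id": g,
        "selection_count": perf.gene_frequency[g],
        "mean_importance": perf.gene_mean_importance[g],
        "in_top_n": int(g in top),
    } for g in sorted(perf.gene_frequency,
                      key=lambda g: (-perf.gene_frequency[g], g))]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
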