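"""End-to-end orchestration: simulate -> preprocess -> train-eval -> explain
-> stratify -> interactions, as one seeded, logged run.

Every stage writes its numeric artifacts (TSV/JSON) into the output
directory, so any stage can also be re-run standalone from the previous
stage's files; the composed run equals the stage-by-stage run. A single
master seed spawns per-stage seeds deterministically, and identical
config + seed reproduce byte-identical numeric artifacts (the run report is
excluded: it records wall-clock times).
"""

from __future__ import annotations

import json
import pickle
import time
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .cohort_stats import cohort_comparison
from .containers import FeatureMatrix
from .explain import external_shap, global_importance, out_of_fold_shap, shap_summary_records
from .interactions import (
    ThresholdConfig,
    build_network,
    cv_interaction_matrix,
    export_network,
    network_metrics,
    select_interaction_features,
    subgroup_interaction_analysis,
)
from .modeling import CVConfig, predict_external_ensemble, run_repeated_cv
from .preprocess import (
    assemble_features,
    clr_transform,
    prevalence_filter,
    read_abundance_table,
    read_metadata,
    write_features,
)
from .stratify import (
    Embedding2D,
    cluster_risk_profiles,
    cluster_taxa_distributions,
    embed_shap,
    project_external,
    select_clustering,
)
from .synthetic import CohortSpec, generate_cohort, generate_external_cohort, write_study


class SimulateConfig(BaseModel):
    n_cases: int = 189
    n_controls: int = 264
    n_taxa: int = 462
    effect_log2fc: float = 2.0
    n_effect_taxa: int = 5
    interaction_coef: float = 1.5
    zero_inflation_prob: float = 0.10
    ext_n_cases: int = 34
    ext_n_controls: int = 9
    ext_shift_log: float = 0.693
    ext_shift_n_taxa: int = 50


class PipelineConfig(BaseModel):
    outdir: str
    seed: int = 0
    # input paths; when absent, the synthetic generator supplies the cohorts
    abundance_path: str | None = None
    metadata_path: str | None = None
    ext_abundance_path: str | None = None
    ext_metadata_path: str | None = None
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)
    # preprocessing
    min_prev: float = 0.10
    pseudocount: float = 1.0
    country_encoding: str = "codes"
    # modelling
    backend: str = "xgboost"
    n_folds: int = 5
    n_repeats: int = 20
    # explanation / stratification
    top_k: int = 20
    tsne_perplexity: float = 30.0
    tsne_max_iter: int = 1000
    k_min: int = 2
    k_max: int = 10
    knn_k: int = 5
    n_subgroup_networks: int = 2
    # interactions
    percentile: float = 95.0
    min_interactions: int = 10

    def validate_paths(self) -> None:
        for name in ("abundance_path", "metadata_path", "ext_abundance_path", "ext_metadata_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p}")
        if (self.abundance_path is None) != (self.metadata_path is None):
            raise ValueError("abundance_path and metadata_path must be given together")


class StageReport(BaseModel):
    name: str
    status: str = "ok"
    seconds: float = 0.0
    metrics: dict = Field(default_factory=dict)
    error: str | None = None


class RunReport(BaseModel):
    version: str = __version__
    config: dict
    stages: list[StageReport] = Field(default_factory=list)
    manifest: list[str] = Field(default_factory=list)

    def stage(self, name: str) -> StageReport:
        return next(s for s in self.stages if s.name == name)


def _stage_seeds(master_seed: int) -> dict:
    seqs = np.random.SeedSequence(master_seed).spawn(6)
    names = ("simulate", "preprocess", "train_eval", "explain", "stratify", "interactions")
    return {n: int(s.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))
            for n, s in zip(names, seqs)}


def _default_spec(sim: SimulateConfig, seed: int) -> CohortSpec:
    spec = CohortSpec(
        n_cases=sim.n_cases, n_controls=sim.n_controls, n_taxa=sim.n_taxa,
        zero_inflation_prob=sim.zero_inflation_prob, seed=seed,
    )
    base_effects = [(5, 1), (9, -1), (14, 1), (21, -1), (30, 1)]
    spec.effect_taxa = [
        (idx % sim.n_taxa, sign * sim.effect_log2fc)
        for idx, sign in base_effects[: sim.n_effect_taxa]
    ]
    if sim.interaction_coef:
        spec.interaction_pair = (5 % sim.n_taxa, 14 % sim.n_taxa, sim.interaction_coef)
    return spec


class PipelineRunner:
    """Runs the stages in workflow order, carrying artifacts in memory and on
    disk; each public ``stage_*`` method is also usable standalone."""

    def __init__(self, config: PipelineConfig):
        config.validate_paths()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seeds = _stage_seeds(config.seed)
        self.report = RunReport(config=json.loads(config.model_dump_json()))
        self.state: dict = {}

    # -- helpers ----------------------------------------------------------
    def _write(self, name: str, frame: pd.DataFrame, index_label: str = "id") -> Path:
        path = self.outdir / name
        frame.to_csv(path, sep="\t", index_label=index_label)
        self.report.manifest.append(str(path))
        return path

    def _write_json(self, name: str, payload) -> Path:
        path = self.outdir / name
        path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))
        self.report.manifest.append(str(path))
        return path

    # -- stages -----------------------------------------------------------
    def stage_simulate(self) -> dict:
        sim = self.config.simulate
        spec = _default_spec(sim, self.seeds["simulate"])
        study = generate_cohort(spec)
        rng = np.random.default_rng(self.seeds["simulate"] + 1)
        shift = np.zeros(sim.n_taxa)
        effect_idx = {i for i, _ in spec.effect_taxa}
        candidates = np.array([i for i in range(sim.n_taxa) if i not in effect_idx])
        shifted = rng.choice(candidates, size=min(sim.ext_shift_n_taxa, candidates.size),
                             replace=False)
        shift[shifted] = sim.ext_shift_log
        external = generate_external_cohort(spec, shift, sim.ext_n_cases, sim.ext_n_controls)
        paths = write_study(study, self.outdir, prefix="train")
        paths.update(write_study(external, self.outdir, prefix="external"))
        self.report.manifest.extend(paths.values())
        self.state.update(study=study, external=external, spec=spec)
        return {"n_train": study.abundance.n_samples, "n_external": external.abundance.n_samples,
                "n_taxa": study.abundance.n_taxa,
                "train_cases": int(study.labels.sum()),
                "external_cases": int(external.labels.sum())}

    def stage_preprocess(self) -> dict:
        cfg = self.config
        if cfg.abundance_path is not None:
            table = read_abundance_table(cfg.abundance_path)
            metadata = read_metadata(cfg.metadata_path)
        else:
            table = self.state["study"].abundance
            metadata = self.state["study"].metadata
        filtered = prevalence_filter(table, cfg.min_prev)
        clr = clr_transform(filtered, cfg.pseudocount)

        countries = sorted(metadata["country"].unique())
        ext_features = None
        if cfg.ext_abundance_path is not None or "external" in self.state:
            if cfg.ext_abundance_path is not None:
                ext_table = read_abundance_table(cfg.ext_abundance_path)
                ext_metadata = read_metadata(cfg.ext_metadata_path)
            else:
                ext_table = self.state["external"].abundance
                ext_metadata = self.state["external"].metadata
            countries = sorted(set(countries) | set(ext_metadata["country"].unique()))
            ext_sub = ext_table.counts.reindex(columns=filtered.taxon_names, fill_value=0)
            ext_clr = clr_transform(type(filtered)(ext_sub), cfg.pseudocount)
            ext_features = assemble_features(ext_clr, ext_metadata,
                                             country_encoding=cfg.country_encoding,
                                             country_categories=countries)
            self.state["ext_metadata"] = ext_metadata
            ext_comparison = cohort_comparison(ext_metadata)
            self._write("external_cohort_comparison.tsv", ext_comparison, "covariate")

        features = assemble_features(clr, metadata, country_encoding=cfg.country_encoding,
                                     country_categories=countries)
        comparison = cohort_comparison(metadata)
        self._write("cohort_comparison.tsv", comparison, "covariate")
        write_features(features, self.outdir / "features.tsv")
        self.report.manifest.append(str(self.outdir / "features.tsv"))
        if ext_features is not None:
            write_features(ext_features, self.outdir / "features_external.tsv")
            self.report.manifest.append(str(self.outdir / "features_external.tsv"))
        self.state.update(features=features, ext_features=ext_features, metadata=metadata)
        return {"n_taxa_prefilter": table.n_taxa,
                "n_taxa_retained": filtered.n_taxa,
                "n_features": features.n_features,
                "gender_p": float(comparison.loc["gender", "p_value"]),
                "country_p": float(comparison.loc["country", "p_value"]),
                "age_p": float(comparison.loc["age", "p_value"]),
                "bmi_p": float(comparison.loc["bmi", "p_value"])}

    def stage_train_eval(self) -> dict:
        cfg = self.config
        features = self.state["features"]
        metadata = self.state["metadata"]
        labels = (metadata.loc[features.sample_ids, "diagnosis"] == "CRC").astype(int)
        cv_config = CVConfig(n_folds=cfg.n_folds, n_repeats=cfg.n_repeats,
                             seed=self.seeds["train_eval"], backend=cfg.backend)
        cv = run_repeated_cv(features, labels, cv_config)
        self._write("cv_metrics.tsv", cv.metrics.reset_index(), "row")
        self._write("oof_probabilities.tsv", cv.oof_prob, "sample_id")
        self._write("fold_map.tsv", cv.fold_map, "sample_id")
        with open(self.outdir / "registry.pkl", "wb") as fh:
            pickle.dump({"registry": cv.registry, "config": cv_config}, fh)
        summary = cv.summary()
        metrics = {f"cv_{m}_{s}": float(summary.loc[m, s])
                   for m in summary.index for s in ("mean", "std")}
        metrics["registry_size"] = len(cv.registry)
        self.state["cv"] = cv
        if self.state.get("ext_features") is not None:
            ext = predict_external_ensemble(cv, self.state["ext_features"])
            ext_labels = (self.state["ext_metadata"].loc[ext.mean_probability.index,
                                                         "diagnosis"] == "CRC").astype(int)
            from .modeling import compute_binary_metrics

            ext_metrics = compute_binary_metrics(ext_labels, ext.mean_probability)
            ext_metrics["vote_accuracy"] = float((ext.labels == ext_labels).mean())
            metrics.update({f"external_{k}": v for k, v in ext_metrics.items()})
            self._write("external_predictions.tsv", pd.DataFrame({
                "votes_crc": ext.votes_crc, "mean_probability": ext.mean_probability,
                "label": ext.labels}), "sample_id")
            self.state["ext_prediction"] = ext
        self._write_json("cv_summary.json", metrics)
        return metrics

    def stage_explain(self) -> dict:
        cv = self.state["cv"]
        features = self.state["features"]
        shap = out_of_fold_shap(cv, features)
        shap.to_tsv(self.outdir / "shap_train.tsv")
        self.report.manifest.append(str(self.outdir / "shap_train.tsv"))
        imp = global_importance(shap, top_k=self.config.top_k)
        self._write("global_importance.tsv", imp.importance.to_frame("mean_abs_phi"), "feature")
        records = shap_summary_records(shap, features, top_k=self.config.top_k)
        self._write("shap_summary_records.tsv", records, "row")
        metrics = {"top_k_share": imp.cumulative_share(),
                   "local_accuracy_residual": shap.local_accuracy_residual,
                   "top_features": imp.ranking[: self.config.top_k]}
        self.state.update(shap=shap, importance=imp)
        if self.state.get("ext_features") is not None:
            ext_shap_m = external_shap(cv, self.state["ext_features"])
            ext_shap_m.to_tsv(self.outdir / "shap_external.tsv")
            self.report.manifest.append(str(self.outdir / "shap_external.tsv"))
            ext_imp = global_importance(ext_shap_m, top_k=self.config.top_k)
            metrics["external_top_k_share"] = ext_imp.cumulative_share()
            self.state["ext_shap"] = ext_shap_m
        self._write_json("importance_summary.json", metrics)
        return metrics

    def stage_stratify(self) -> dict:
        cfg = self.config
        shap = self.state["shap"]
        metadata = self.state["metadata"]
        embedding = embed_shap(shap, perplexity=cfg.tsne_perplexity,
                               max_iter=cfg.tsne_max_iter, seed=self.seeds["stratify"])
        self._write("tsne_embedding.tsv", embedding.coords, "subject_id")
        adenoma_ids = [s for s in shap.subject_ids
                       if metadata.loc[s, "diagnosis"] == "adenoma"]
        adenoma_embedding = Embedding2D(coords=embedding.coords.loc[adenoma_ids],
                                        params=embedding.params, source=embedding.source)
        clustering = select_clustering(adenoma_embedding,
                                       k_range=range(cfg.k_min, cfg.k_max + 1),
                                       seed=self.seeds["stratify"])
        self._write("cluster_labels.tsv", clustering.labels.to_frame(), "subject_id")
        self._write("silhouette_grid.tsv", clustering.grid, "method")
        oof_mean = self.state["cv"].mean_oof_probability()
        projection = None
        ext_prob = None
        if self.state.get("ext_shap") is not None:
            ext_shap_m = self.state["ext_shap"]
            ext_adenoma = [s for s in ext_shap_m.subject_ids
                           if self.state["ext_metadata"].loc[s, "diagnosis"] == "adenoma"]
            if ext_adenoma:
                from .explain import ShapMatrix

                sub = ShapMatrix(phi=ext_shap_m.phi.loc[ext_adenoma],
                                 baseline=ext_shap_m.baseline.loc[ext_adenoma],
                                 provenance=ext_shap_m.provenance)
                projection = project_external(shap, embedding, sub, clustering,
                                              k_neighbors=cfg.knn_k)
                self._write("external_projection.tsv",
                            projection.coords.join(projection.clusters.to_frame("cluster")),
                            "subject_id")
                ext_prob = self.state["ext_prediction"].mean_probability.loc[ext_adenoma]
        profile = cluster_risk_profiles(clustering, oof_mean, ext_prob, projection)
        self._write("cluster_risk_profiles.tsv", profile.table, "cluster")
        top_taxa = [f for f in self.state["importance"].ranking
                    if self.state["features"].feature_kind[f] == "taxon_clr"][:3]
        taxa_dist = cluster_taxa_distributions(clustering, self.state["features"], top_taxa)
        taxa_dist["outliers"] = taxa_dist["outliers"].map(lambda v: ";".join(f"{x:.6g}" for x in v))
        self._write("cluster_taxa_distributions.tsv", taxa_dist, "row")
        self.state.update(clustering=clustering, risk_profile=profile, embedding=embedding)
        return {"best_method": clustering.method, "best_k": clustering.k,
                "silhouette": clustering.silhouette,
                "cluster_sizes": clustering.cluster_sizes().to_dict(),
                "highest_risk_cluster": int(profile.table.index[0]),
                "highest_risk_median_probability": float(profile.table["median"].iloc[0])}

    def stage_interactions(self) -> dict:
        cfg = self.config
        cv = self.state["cv"]
        features = self.state["features"]
        tconf = ThresholdConfig(percentile=cfg.percentile, min_interactions=cfg.min_interactions)
        matrix = cv_interaction_matrix(cv, features)
        self._write("interaction_matrix.tsv", matrix.values, "feature")
        selection = select_interaction_features(matrix, tconf)
        self._write("interaction_grid.tsv", selection.grid, "min_interactions")
        network = build_network(matrix, selection)
        metrics_frame = network_metrics(network)
        self._write("network_metrics.tsv", metrics_frame, "feature")
        export_network(network, self.outdir / "network_global.gexf", fmt="gexf")
        export_network(network, self.outdir / "network_global.graphml", fmt="graphml")
        self.report.manifest += [str(self.outdir / "network_global.gexf"),
                                 str(self.outdir / "network_global.graphml")]
        # violin-plot data: the full off-diagonal value distribution
        pd.DataFrame({"interaction_value": matrix.upper_triangle()}).to_csv(
            self.outdir / "interaction_values.tsv", sep="\t", index=False)
        self.report.manifest.append(str(self.outdir / "interaction_values.tsv"))
        out = {"n_retained_features": len(selection.retained),
               "threshold": selection.threshold,
               "n_edges": network.number_of_edges()}
        clustering = self.state.get("clustering")
        profile = self.state.get("risk_profile")
        if clustering is not None and profile is not None:
            top_clusters = list(profile.table.index[: cfg.n_subgroup_networks])
            for cluster in top_clusters:
                members = clustering.labels.index[clustering.labels == cluster].tolist()
                sub_net, _m, sub_sel = subgroup_interaction_analysis(cv, features, members, tconf)
                export_network(sub_net, self.outdir / f"network_cluster{cluster}.gexf", fmt="gexf")
                self.report.manifest.append(str(self.outdir / f"network_cluster{cluster}.gexf"))
                out[f"cluster{cluster}_retained_features"] = len(sub_sel.retained)
        return out

    # -- driver ------------------------------------------------------------
    _ORDER = ("simulate", "preprocess", "train_eval", "explain", "stratify", "interactions")

    def run(self) -> RunReport:
        skip_simulate = self.config.abundance_path is not None
        failed = False
        for name in self._ORDER:
            if name == "simulate" and skip_simulate:
                continue
            stage = StageReport(name=name)
            if failed:
                stage.status = "skipped"
                self.report.stages.append(stage)
                continue
            start = time.perf_counter()
            try:
                stage.metrics = getattr(self, f"stage_{name}")()
            except Exception as exc:  # stage failure: mark, skip downstream
                stage.status = "failed"
                stage.error = f"{type(exc).__name__}: {exc}\n{traceback.format_exc()}"
                failed = True
            stage.seconds = time.perf_counter() - start
            self.report.stages.append(stage)
        (self.outdir / "report.json").write_text(self.report.model_dump_json(indent=1))
        return self.report


def run_pipeline(config: PipelineConfig) -> RunReport:
    return PipelineRunner(config).run()
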