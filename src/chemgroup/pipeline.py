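"""End-to-end pipeline runner producing a replayable run manifest.

Chains the stages — input, standardization, descriptors, filtering,
feature selection, grouping (structure-based or SHAP-based), and
interpretation — according to a :class:`PipelineConfig`, recording every
option, seed, and stage result in a :class:`~chemgroup.dataio.RunManifest`.

``STAGE_COUNTERS`` counts executions of the compute stages; the report
module's view mode asserts zero recomputation against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from chemgroup.dataio import (
    Dataset,
    RunManifest,
    integrity_check,
    read_dataset,
    summarize_dataset,
)
from chemgroup.descriptors import (
    FeatureMatrix,
    FingerprintSpec,
    compute_descriptors,
    compute_fingerprints,
    descriptor_set_version,
    scale_features,
)
from chemgroup.filters import (
    GAConfig,
    SAConfig,
    auto_threshold_search,
    correlation_filter,
    ga_select,
    rfe_select,
    sa_select,
    variance_filter,
)
from chemgroup.grouping import (
    ClusterSpec,
    ProjectionSpec,
    SearchSpace,
    default_search_space,
    project_2d,
    run_clustering,
    silhouette,
    SilhouetteUndefinedError,
    tune_grouping,
)
from chemgroup.learners import LearnerSpec
from chemgroup.shap_interpret import (
    interpret_clusters,
    shap_supervised_grouping,
    summarize_interpretation,
)
from chemgroup.standardize import standardize_dataset

#: executions of each compute stage in this process (view mode asserts on this)
STAGE_COUNTERS = {
    "standardize": 0,
    "descriptors": 0,
    "filter": 0,
    "selection": 0,
    "grouping": 0,
    "interpretation": 0,
}


@dataclass
class PipelineConfig:
    """Every page-level choice of the workflow, YAML-serializable."""

    format: str = "smiles"
    label_column: str | None = None
    label_kind: str = "none"
    smiles_column: str | None = None
    standardize: bool = True
    # descriptor stage
    descriptor_type: str = "fingerprint"  # fingerprint | descriptors
    fingerprint_family: str = "morgan"
    fingerprint_radius: int = 3
    fingerprint_n_bits: int = 2048
    descriptor_set: str = "compact"
    scaling: str = "default"  # default: none for binary, minmax for continuous
    # dimensionality reduction
    variance_filter_mode: str = "manual"  # manual | auto | off
    variance_threshold: float = 0.0
    correlation_filter_mode: str = "off"  # manual | auto | off
    correlation_threshold: float = 0.95
    filter_grid: list[float] | None = None
    filter_cv_mode: str = "holdout_80_20"
    # supervised feature selection
    selection_method: str = "none"  # none | rfe | ga | sa
    selection_params: dict = field(default_factory=dict)
    # learner used for all supervised steps
    learner_family: str = "gradient_boosted_trees"
    learner_params: dict = field(default_factory=dict)
    # grouping
    grouping_route: str = "unsupervised"  # unsupervised | shap
    cluster_method: str = "kmeans"
    projection_method: str = "umap"
    projected: bool = True
    n_trials: int = 50
    search_space: dict | None = None  # name -> [kind, low, high] / [kind, choices]
    # interpretation
    interpret: bool = True
    interpret_top_k: int = 5
    endpoint_description: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def _learner_spec(config: PipelineConfig, labeled_kind: str) -> LearnerSpec:
    task = "regression" if labeled_kind == "continuous" else "classification"
    return LearnerSpec(
        family=config.learner_family,
        task=task,
        hyperparameters=dict(config.learner_params),
        seed=config.seed,
    )


def _space_from_config(config: PipelineConfig) -> SearchSpace:
    if config.search_space:
        params = {}
        for name, dim in config.search_space.items():
            kind = dim[0]
            params[name] = (kind, dim[1]) if kind == "cat" else (kind, dim[1], dim[2])
        return SearchSpace(params=params, n_trials=config.n_trials, seed=config.seed)
    return default_search_space(
        config.cluster_method,
        config.projection_method,
        n_trials=config.n_trials,
        seed=config.seed,
    )


def run_pipeline(
    source: str | Path | Dataset,
    config: PipelineConfig,
    overrides: dict | None = None,
) -> RunManifest:
    """Execute the full grouping workflow and return its manifest.

    ``overrides`` (used by manifest replay) short-circuits search stages
    with previously selected values: keys ``variance_threshold``,
    ``correlation_threshold``, ``selected_columns``, ``grouping_config``.
    """
    overrides = overrides or {}
    manifest = RunManifest()
    manifest.set_option("config", config.to_dict())
    manifest.set_seed("master", config.seed)

    # ---- input ----
    if isinstance(source, Dataset):
        ds = source
        input_name = "<in-memory dataset>"
    else:
        ds = read_dataset(
            source,
            format=config.format,
            label_column=config.label_column,
            label_kind=config.label_kind,
            smiles_column=config.smiles_column,
        )
        input_name = str(source)
    n_input = ds.n
    ds, removed = integrity_check(ds)
    summary = summarize_dataset(ds, removed)
    manifest.set_input(
        name=input_name,
        format=config.format,
        label_column=config.label_column,
        label_kind=config.label_kind,
        label_map=ds.label_map,
    )
    manifest.set_stage(
        "input",
        n_input=n_input,
        n_retained=summary.n_retained,
        n_unreadable=summary.n_unreadable,
        n_missing=summary.n_missing,
        class_counts=summary.class_counts,
        histogram=summary.histogram,
        removed_rows=removed.rows,
    )

    # ---- standardization ----
    if config.standardize:
        STAGE_COUNTERS["standardize"] += 1
        ds, std_removed = standardize_dataset(ds)
        manifest.set_stage(
            "standardize",
            applied=True,
            n_retained=ds.n,
            removed_rows=std_removed.rows,
            tautomer_scheme="rdkit-canonical",
        )
    else:
        manifest.set_stage("standardize", applied=False, n_retained=ds.n, removed_rows=[])

    # ---- descriptors ----
    STAGE_COUNTERS["descriptors"] += 1
    if config.descriptor_type == "fingerprint":
        spec = FingerprintSpec(
            family=config.fingerprint_family,
            radius=config.fingerprint_radius,
            n_bits=config.fingerprint_n_bits,
        )
        fm = compute_fingerprints(ds, spec)
        desc_info = {
            "type": "fingerprint",
            "family": spec.family,
            "radius": spec.radius,
            "n_bits": spec.n_bits,
        }
    else:
        fm = compute_descriptors(ds, config.descriptor_set)
        desc_info = {"type": "descriptors", **descriptor_set_version(config.descriptor_set)}
        desc_info["dropped_nonfinite_columns"] = fm.dropped_columns

    scaling = config.scaling
    if scaling == "default":
        scaling = "none" if fm.column_kind == "binary" else "minmax"
    if scaling != "none" and fm.column_kind == "continuous":
        fm = scale_features(fm, scaling)
    smiles_by_id = {r.record_id: r.structure_text for r in ds.retained()}
    manifest.set_stage(
        "features",
        descriptor=desc_info,
        scaling=scaling,
        row_ids=fm.row_ids,
        smiles=[smiles_by_id.get(r, "") for r in fm.row_ids],
        column_names=fm.column_names,
        values=fm.values,
        column_kind=fm.column_kind,
    )

    labels = ds.labels()
    if labels is not None:
        id_to_label = {r.record_id: r.label for r in ds.retained()}
        labels = np.asarray([id_to_label[r] for r in fm.row_ids])

    # ---- dimensionality reduction ----
    filter_stages = []
    for kind, mode, thr_key in (
        ("variance", config.variance_filter_mode, "variance_threshold"),
        ("correlation", config.correlation_filter_mode, "correlation_threshold"),
    ):
        if mode == "off":
            continue
        STAGE_COUNTERS["filter"] += 1
        threshold = overrides.get(thr_key)
        apply_fn = variance_filter if kind == "variance" else correlation_filter
        if threshold is not None:
            res = apply_fn(fm, float(threshold))
        elif mode == "manual":
            res = apply_fn(fm, getattr(config, thr_key))
        else:
            if labels is None:
                raise ValueError("automated threshold search requires labeled data")
            res = auto_threshold_search(
                fm,
                labels,
                _learner_spec(config, ds.label_kind),
                kind,
                grid=config.filter_grid,
                cv_mode=config.filter_cv_mode,
                seed=config.seed,
            )
        fm = fm.select_columns(res.kept_columns)
        filter_stages.append(
            {
                "method": kind,
                "mode": mode,
                "threshold": res.threshold,
                "n_kept": len(res.kept_columns),
                "kept_columns": res.kept_columns,
                "removed_columns": res.removed_columns,
                "search_trace": res.search_trace,
                "cv_mode": res.cv_mode,
            }
        )
    manifest.set_stage("filter", filters=filter_stages, n_columns=fm.p)

    # ---- supervised feature selection ----
    if config.selection_method != "none":
        if labels is None:
            raise ValueError("supervised feature selection requires labeled data")
        STAGE_COUNTERS["selection"] += 1
        selected = overrides.get("selected_columns")
        if selected is not None:
            selected = [c for c in selected if c in fm.column_names]
            sel_payload = {"method": config.selection_method, "replayed": True,
                           "selected_columns": selected}
        else:
            lspec = _learner_spec(config, ds.label_kind)
            sp = dict(config.selection_params)
            if config.selection_method == "rfe":
                res = rfe_select(fm, labels, lspec, cv_folds=sp.get("cv_folds", 5),
                                 seed=config.seed)
            elif config.selection_method == "ga":
                res = ga_select(fm, labels, lspec,
                                GAConfig(seed=config.seed, **sp))
            elif config.selection_method == "sa":
                res = sa_select(fm, labels, lspec,
                                SAConfig(seed=config.seed, **sp))
            else:
                raise ValueError(f"unknown selection method {config.selection_method!r}")
            selected = res.selected_columns
            sel_payload = {
                "method": res.method,
                "replayed": False,
                "selected_columns": selected,
                "score_trace": res.score_trace,
                "final_score": res.final_score,
                "metric": res.metric,
            }
        fm = fm.select_columns(selected)
        manifest.set_stage("selection", **sel_payload)

    # ---- grouping ----
    STAGE_COUNTERS["grouping"] += 1
    grouping_cfg = overrides.get("grouping_config")
    if grouping_cfg is not None:
        # replay: one shot with the stored winning parameters and trial seed
        trial_seed = int(grouping_cfg["trial_seed"])
        X = fm.values
        if grouping_cfg.get("shap_based"):
            if labels is None:
                raise ValueError("replaying a supervised manifest needs labels")
            from chemgroup.learners import make_learner
            from chemgroup.shap_values import compute_shap

            lspec = LearnerSpec.from_dict(grouping_cfg["shap_learner"])
            fitted = make_learner(lspec).fit(fm.values, labels, fm.column_names)
            X = compute_shap(fitted, fm).values
        emb = project_2d(
            X,
            ProjectionSpec(
                grouping_cfg["projection_method"],
                grouping_cfg["projection_params"],
                seed=trial_seed,
            ),
        )
        labels_out = run_clustering(
            emb,
            ClusterSpec(
                grouping_cfg["cluster_method"],
                grouping_cfg["cluster_params"],
                seed=trial_seed,
            ),
        )
        try:
            sil = silhouette(emb, labels_out)
        except SilhouetteUndefinedError:
            sil = float("nan")
        result_config = dict(grouping_cfg)
        grouping_payload = {
            "labels": labels_out,
            "embedding": emb,
            "silhouette": sil,
            "config": result_config,
            "tuning_trace": [],
            "replayed": True,
        }
    else:
        space = _space_from_config(config)
        if config.grouping_route == "shap":
            if labels is None:
                raise ValueError("SHAP-based grouping requires labeled data")
            result = shap_supervised_grouping(
                fm,
                labels,
                _learner_spec(config, ds.label_kind),
                config.cluster_method,
                config.projection_method,
                space,
                projected=config.projected,
            )
        else:
            result = tune_grouping(
                fm, config.cluster_method, config.projection_method, space,
                projected=config.projected,
            )
        result_config = dict(result.config)
        result_config["shap_based"] = result.shap_based
        grouping_payload = {
            "labels": result.labels,
            "embedding": result.embedding,
            "silhouette": result.silhouette,
            "config": result_config,
            "tuning_trace": [
                {"params": p, "silhouette": s} for p, s in result.tuning_trace
            ],
            "replayed": False,
        }
    if labels is not None:
        grouping_payload["activity_labels"] = labels
    manifest.set_stage("grouping", **grouping_payload)

    # ---- interpretation ----
    if config.interpret:
        cluster_labels = np.asarray(grouping_payload["labels"])
        effective = cluster_labels[cluster_labels != -1]
        if len(np.unique(effective)) >= 2 and all(
            np.sum(effective == c) >= 4 for c in np.unique(effective)
        ):
            STAGE_COUNTERS["interpretation"] += 1
            lspec = LearnerSpec(
                family=config.learner_family,
                task="classification",
                hyperparameters=dict(config.learner_params),
                seed=config.seed,
            )
            ci = interpret_clusters(fm, cluster_labels, lspec, top_k=config.interpret_top_k)
            summary_text = summarize_interpretation(
                ci, endpoint_description=config.endpoint_description
            )
            manifest.set_stage(
                "interpretation",
                rankings={
                    str(c): [[n, v, s] for n, v, s in ranks]
                    for c, ranks in ci.rankings.items()
                },
                distributions={
                    str(c): d for c, d in ci.distributions.items()
                },
                top_k=ci.top_k,
                summary=summary_text,
            )

    return manifest
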