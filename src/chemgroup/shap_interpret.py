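"""SHAP-based supervised grouping and per-cluster interpretation.

Two uses of attribution values. First, endpoint-specific grouping: a learner
is fitted to the activity labels, its SHAP matrix replaces the raw
descriptors, and the usual projected/tuned clustering runs on it — chemicals
then group by how descriptors drive the prediction, not by raw structure.
Second, interpretation of any clustering: a classifier is fitted with
cluster labels as the target, per-class SHAP values are computed, and each
cluster's descriptors are ranked by mean |SHAP| of that cluster's
one-vs-rest attribution. Positive SHAP values denote a positive
contribution to cluster membership.

Natural-language summaries are produced by a deterministic template backend;
an external backend (e.g. a remote LLM) can be injected behind the same
signature and falls back to the template when unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from chemgroup.descriptors import FeatureMatrix
from chemgroup.grouping import GroupingResult, SearchSpace, tune_grouping
from chemgroup.learners import LearnerSpec, make_learner
from chemgroup.shap_values import ShapMatrix, compute_shap

__all__ = [
    "ShapMatrix",
    "ClusterInterpretation",
    "compute_shap",
    "shap_supervised_grouping",
    "interpret_clusters",
    "summarize_interpretation",
]


@dataclass
class ClusterInterpretation:
    """Ranked per-cluster descriptor attributions.

    ``rankings`` maps cluster id -> list of (descriptor, mean_abs_shap,
    sign) sorted by mean |SHAP| descending; ``distributions`` maps cluster
    id -> descriptor -> per-point SHAP values for the top_k descriptors.
    """

    rankings: dict[int, list[tuple[str, float, int]]]
    distributions: dict[int, dict[str, list[float]]]
    top_k: int
    learner_spec: dict
    summary: str = ""

    def top_descriptors(self, cluster: int, k: int | None = None) -> list[str]:
        k = self.top_k if k is None else k
        return [name for name, _, _ in self.rankings[cluster][:k]]


def shap_supervised_grouping(
    fm: FeatureMatrix,
    labels: np.ndarray | None,
    learner_spec: LearnerSpec,
    cluster_method: str,
    projection_method: str,
    space: SearchSpace,
    projected: bool = True,
) -> GroupingResult:
    """Endpoint-specific grouping on the SHAP matrix of a fitted learner.

    The learner is fitted on all rows (explanatory use, no holdout); its
    attribution matrix replaces the raw descriptors as tuning input.
    """
    if labels is None:
        raise ValueError("shap_supervised_grouping requires a labeled dataset")
    labels = np.asarray(labels)
    fitted = make_learner(learner_spec).fit(fm.values, labels, fm.column_names)
    shap = compute_shap(fitted, fm)
    shap_fm = FeatureMatrix(
        row_ids=list(fm.row_ids),
        column_names=list(shap.column_names),
        values=shap.values,
        column_kind="continuous",
    )
    result = tune_grouping(shap_fm, cluster_method, projection_method, space, projected)
    result.shap_based = True
    result.config["shap_learner"] = learner_spec.to_dict()
    return result


def interpret_clusters(
    fm: FeatureMatrix,
    cluster_labels: np.ndarray,
    learner_spec: LearnerSpec,
    top_k: int = 5,
) -> ClusterInterpretation:
    """One-vs-rest SHAP interpretation of a clustering.

    Fits a classifier with cluster labels as the target (noise rows
    excluded), computes per-class SHAP values, and ranks each cluster's
    descriptors by mean |SHAP| among that cluster's own rows.
    """
    cluster_labels = np.asarray(cluster_labels)
    mask = cluster_labels != -1
    X = fm.values[mask]
    y = cluster_labels[mask]
    clusters = np.unique(y)
    if len(clusters) < 2:
        raise ValueError("interpretation needs at least 2 clusters")
    for c in clusters:
        if np.sum(y == c) < 2:
            warnings.warn(f"cluster {c} has fewer than 2 members; attribution is fragile")
    if learner_spec.task != "classification":
        learner_spec = LearnerSpec(
            family=learner_spec.family,
            task="classification",
            hyperparameters=dict(learner_spec.hyperparameters),
            seed=learner_spec.seed,
        )

    sub_fm = FeatureMatrix(
        row_ids=[r for r, m in zip(fm.row_ids, mask) if m],
        column_names=list(fm.column_names),
        values=X,
        column_kind=fm.column_kind,
    )
    fitted = make_learner(learner_spec).fit(X, y, fm.column_names)
    shap = compute_shap(fitted, sub_fm)

    top_k_eff = min(top_k, fm.p)
    rankings: dict[int, list[tuple[str, float, int]]] = {}
    distributions: dict[int, dict[str, list[float]]] = {}
    class_index = {c: i for i, c in enumerate(shap.classes)}
    for c in clusters:
        block = shap.block(class_index[int(c)])
        rows = block[y == c]
        mean_abs = np.abs(rows).mean(axis=0)
        signs = np.sign(rows.mean(axis=0)).astype(int)
        order = np.argsort(-mean_abs, kind="stable")
        rankings[int(c)] = [
            (fm.column_names[j], float(mean_abs[j]), int(signs[j])) for j in order
        ]
        distributions[int(c)] = {
            fm.column_names[j]: [float(v) for v in rows[:, j]]
            for j in order[:top_k_eff]
        }

    ci = ClusterInterpretation(
        rankings=rankings,
        distributions=distributions,
        top_k=top_k_eff,
        learner_spec=learner_spec.to_dict(),
    )
    ci.summary = summarize_interpretation(ci)
    return ci


def _template_summary(ci: ClusterInterpretation, endpoint_description: str | None) -> str:
    lines = []
    if endpoint_description:
        lines.append(f"Endpoint under study: {endpoint_description}.")
        lines.append(
            "For each cluster, the descriptors below are those whose SHAP "
            "attributions most strongly drive membership, and may relate to "
            "this endpoint."
        )
    else:
        lines.append(
            "For each cluster, the descriptors below are those whose SHAP "
            "attributions most strongly drive membership."
        )
    for c in sorted(ci.rankings):
        parts = []
        for name, mean_abs, sign in ci.rankings[c][: ci.top_k]:
            direction = (
                "higher values favor membership"
                if sign > 0
                else "lower values favor membership"
                if sign < 0
                else "direction mixed"
            )
            parts.append(f"{name} (mean |SHAP| {mean_abs:.4g}; {direction})")
        lines.append(f"Cluster {c}: " + "; ".join(parts) + ".")
    return "\n".join(lines)


def summarize_interpretation(
    ci: ClusterInterpretation,
    backend: str = "template",
    endpoint_description: str | None = None,
    external_fn=None,
) -> str:
    """Natural-language summary of a cluster interpretation.

    The template backend is deterministic. The external backend is an
    injection point with the same signature (``external_fn(ci,
    endpoint_description) -> str``); when unavailable it falls back to the
    template with a warning.
    """
    if backend not in ("template", "external"):
        raise ValueError(f"unknown summarizer backend {backend!r}")
    if backend == "external":
        if external_fn is None:
            warnings.warn("external summarizer unavailable; falling back to template")
        else:
            try:
                return str(external_fn(ci, endpoint_description))
            except Exception as exc:
                warnings.warn(f"external summarizer failed ({exc}); using template")
    return _template_summary(ci, endpoint_description)
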