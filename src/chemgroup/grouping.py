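"""Clustering, 2-D projection, the silhouette objective, and TPE tuning.

Clusterers: K-means, K-medoids (PAM-style alternating optimization,
k-medoids++ seeding), agglomerative hierarchical clustering on a precomputed
Euclidean or Manhattan distance matrix, DBSCAN, and HDBSCAN. Density-based
methods may label points as noise (-1).

Projections: PCA, UMAP, and t-SNE, always to 2 dimensions.

The tuning objective is the mean silhouette coefficient
SI = (b - a) / max(a, b), with a the mean intra-cluster distance (0 for
singletons) and b the mean distance to the nearest other cluster, Euclidean
metric, noise points excluded. Hyperparameters are searched with a seeded
TPE sampler, either jointly over projection + clusterer ("projected"
clustering, objective evaluated on the 2-D embedding) or in two stages
(clusterer tuned in full descriptor space first, then the projection tuned
with cluster parameters frozen, re-clustering each trial embedding).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import DBSCAN, HDBSCAN, AgglomerativeClustering, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from chemgroup.descriptors import FeatureMatrix
from chemgroup.tpe import TPESampler

CLUSTER_METHODS = ("kmeans", "kmedoids", "hierarchical", "dbscan", "hdbscan")
PROJECTION_METHODS = ("pca", "umap", "tsne")

DEGENERATE_SCORE = -1.0


class SilhouetteUndefinedError(ValueError):
    """Raised when fewer than 2 effective clusters are present."""


@dataclass
class ProjectionSpec:
    method: str = "umap"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in PROJECTION_METHODS:
            raise ValueError(f"unknown projection method {self.method!r}")


@dataclass
class ClusterSpec:
    method: str = "kmeans"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in CLUSTER_METHODS:
            raise ValueError(f"unknown clustering method {self.method!r}")
        k = self.params.get("n_clusters")
        if k is not None and k < 2:
            raise ValueError("n_clusters must be >= 2")
        eps = self.params.get("eps")
        if eps is not None and eps <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class SearchSpace:
    """Hyperparameter ranges for tuning.

    ``params`` maps a prefixed name (``cluster__*`` or ``proj__*``) to a
    dimension tuple: ("float", low, high), ("int", low, high), or
    ("cat", [choices]).
    """

    params: dict[str, tuple]
    n_trials: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def subset(self, prefix: str) -> dict[str, tuple]:
        return {k: v for k, v in self.params.items() if k.startswith(prefix)}


@dataclass
class GroupingResult:
    labels: np.ndarray
    embedding: np.ndarray
    silhouette: float
    config: dict
    tuning_trace: list[tuple[dict, float]]
    shap_based: bool = False
    #: full-space labels from stage 1 of non-projected tuning, when applicable
    full_space_labels: np.ndarray | None = None


# ---------------------------------------------------------------------------
# silhouette (the tuning objective)


def silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient SI = (b - a) / max(a, b), Euclidean.

    a is the mean distance to the point's own cluster (0 for singletons);
    b is the minimum over other clusters of the mean distance to that
    cluster. Noise points (label -1) are excluded. Raises
    :class:`SilhouetteUndefinedError` with fewer than 2 effective clusters.
    """
    points = np.asarray(points, dtype=float)
    labels = np.asarray(labels)
    mask = labels != -1
    points, labels = points[mask], labels[mask]
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise SilhouetteUndefinedError(
            "silhouette undefined: fewer than 2 clusters among non-noise points"
        )
    dist = squareform(pdist(points))
    n = len(points)
    scores = np.empty(n)
    cluster_idx = {c: np.flatnonzero(labels == c) for c in uniq}
    for i in range(n):
        own = cluster_idx[labels[i]]
        if len(own) == 1:
            a = 0.0
        else:
            a = dist[i, own].sum() / (len(own) - 1)
        b = min(
            dist[i, cluster_idx[c]].mean() for c in uniq if c != labels[i]
        )
        denom = max(a, b)
        scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


# ---------------------------------------------------------------------------
# projection


def project_2d(data: FeatureMatrix | np.ndarray, spec: ProjectionSpec) -> np.ndarray:
    """Project to 2 dimensions with PCA, UMAP, or t-SNE; seeded and deterministic."""
    X = data.values if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("projection needs at least 3 points")
    p = spec.params
    if spec.method == "pca":
        return PCA(n_components=2, random_state=spec.seed).fit_transform(X)
    if spec.method == "tsne":
        perplexity = float(p.get("perplexity", 30.0))
        if n <= 3 * perplexity:
            raise ValueError("t-SNE requires n > 3 * perplexity")
        return TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=spec.seed,
            init="pca",
        ).fit_transform(X)
    # umap
    import umap  # deferred: numba compilation is slow at import time

    n_neighbors = int(p.get("n_neighbors", 15))
    min_dist = float(p.get("min_dist", 0.1))
    if not 0.0 < min_dist < 1.0:
        raise ValueError("min_dist must be in (0, 1)")
    if n_neighbors < 2 or n_neighbors >= n:
        raise ValueError("n_neighbors must be in [2, n)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=spec.seed,
            n_jobs=1,
        )
        return np.asarray(reducer.fit_transform(X), dtype=float)


# ---------------------------------------------------------------------------
# clustering


def _kmedoids(
    X: np.ndarray, k: int, seed: int, max_iter: int = 100
) -> np.ndarray:
    """PAM-style alternating K-medoids with k-medoids++ seeding."""
    n = X.shape[0]
    if k > n:
        raise ValueError("n_clusters exceeds number of points")
    dist = squareform(pdist(X))
    rng = np.random.default_rng(seed)

    # k-medoids++ initialization
    medoids = [int(rng.integers(n))]
    for _ in range(1, k):
        d2 = np.min(dist[:, medoids], axis=1) ** 2
        total = d2.sum()
        if total == 0:
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(int(rng.choice(remaining)))
            continue
        medoids.append(int(rng.choice(n, p=d2 / total)))

    medoids = np.asarray(sorted(set(medoids)))
    while len(medoids) < k:  # degenerate duplicates from zero-distance picks
        extra = [i for i in range(n) if i not in medoids]
        medoids = np.append(medoids, extra[: k - len(medoids)])

    for _ in range(max_iter):
        assign = np.argmin(dist[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(assign == c)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new_medoids[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(dist[:, medoids], axis=1)


def run_clustering(points: np.ndarray, spec: ClusterSpec) -> np.ndarray:
    """Cluster points; returns integer labels with -1 marking noise."""
    X = np.asarray(points, dtype=float)
    n = X.shape[0]
    p = spec.params
    if spec.method in ("kmeans", "kmedoids", "hierarchical"):
        k = int(p.get("n_clusters", 2))
        if k > n:
            raise ValueError(f"n_clusters={k} exceeds n={n}")
    if spec.method == "kmeans":
        km = KMeans(n_clusters=k, n_init=10, random_state=spec.seed)
        return km.fit_predict(X).astype(int)
    if spec.method == "kmedoids":
        return _kmedoids(X, k, spec.seed).astype(int)
    if spec.method == "hierarchical":
        metric = p.get("metric", "euclidean")
        if metric not in ("euclidean", "manhattan"):
            raise ValueError(f"unsupported hierarchical metric {metric!r}")
        linkage = p.get("linkage", "average")
        if linkage not in ("single", "complete", "average"):
            raise ValueError(f"unsupported linkage {linkage!r}")
        dist = squareform(pdist(X, metric="cityblock" if metric == "manhattan" else metric))
        model = AgglomerativeClustering(
            n_clusters=k, metric="precomputed", linkage=linkage
        )
        return model.fit_predict(dist).astype(int)
    if spec.method == "dbscan":
        eps = float(p.get("eps", 0.5))
        if eps <= 0:
            raise ValueError("epsilon must be > 0")
        model = DBSCAN(eps=eps, min_samples=int(p.get("min_samples", 5)))
        return model.fit_predict(X).astype(int)
    if spec.method == "hdbscan":
        model = HDBSCAN(min_cluster_size=int(p.get("min_cluster_size", 5)), copy=True)
        return model.fit_predict(X).astype(int)
    raise ValueError(spec.method)


# ---------------------------------------------------------------------------
# default search spaces (case-study ranges)


def default_search_space(
    cluster_method: str,
    projection_method: str | None = None,
    n_trials: int = 50,
    seed: int = 0,
) -> SearchSpace:
    """Default tuning ranges: k 2-25, UMAP min_dist 0.01-0.25 and
    n_neighbors 2-50, 50 trials; all configurable."""
    params: dict[str, tuple] = {}
    if cluster_method in ("kmeans", "kmedoids", "hierarchical"):
        params["cluster__n_clusters"] = ("int", 2, 25)
    if cluster_method == "hierarchical":
        params["cluster__linkage"] = ("cat", ["single", "complete", "average"])
        params["cluster__metric"] = ("cat", ["euclidean", "manhattan"])
    if cluster_method == "dbscan":
        params["cluster__eps"] = ("float", 0.05, 5.0)
        params["cluster__min_samples"] = ("int", 2, 20)
    if cluster_method == "hdbscan":
        params["cluster__min_cluster_size"] = ("int", 2, 25)
    if projection_method == "umap":
        params["proj__min_dist"] = ("float", 0.01, 0.25)
        params["proj__n_neighbors"] = ("int", 2, 50)
    if projection_method == "tsne":
        params["proj__perplexity"] = ("float", 5.0, 50.0)
    return SearchSpace(params=params, n_trials=n_trials, seed=seed)


# ---------------------------------------------------------------------------
# tuning


def _split_params(params: dict) -> tuple[dict, dict]:
    cl = {k.removeprefix("cluster__"): v for k, v in params.items() if k.startswith("cluster__")}
    pr = {k.removeprefix("proj__"): v for k, v in params.items() if k.startswith("proj__")}
    return cl, pr


def _objective_on(points: np.ndarray, labels: np.ndarray) -> float:
    """Silhouette with degeneracy penalties: trials with < 2 clusters or
    > 50% noise score -1."""
    labels = np.asarray(labels)
    noise_frac = float(np.mean(labels == -1))
    if noise_frac > 0.5:
        return DEGENERATE_SCORE
    try:
        return silhouette(points, labels)
    except SilhouetteUndefinedError:
        return DEGENERATE_SCORE


def _trial_seeds(master_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(master_seed).generate_state(n) % (2**31)


def tune_grouping(
    data: FeatureMatrix | np.ndarray,
    cluster_method: str,
    projection_method: str,
    space: SearchSpace,
    projected: bool = True,
) -> GroupingResult:
    """Silhouette-driven TPE search over clustering (and projection) params.

    projected=True: every trial samples projection + cluster parameters
    jointly, clusters the trial's 2-D embedding, and scores the silhouette
    on that embedding.

    projected=False: stage 1 tunes cluster parameters in the full feature
    space; stage 2 freezes them and tunes projection parameters,
    re-clustering each trial embedding. The returned labels come from the
    best stage-2 embedding; stage-1 full-space labels are kept alongside.
    """
    X = data.values if isinstance(data, FeatureMatrix) else np.asarray(data, dtype=float)
    if cluster_method not in CLUSTER_METHODS:
        raise ValueError(f"unknown clustering method {cluster_method!r}")
    if projection_method not in PROJECTION_METHODS:
        raise ValueError(f"unknown projection method {projection_method!r}")

    trace: list[tuple[dict, float]] = []
    failures: list[str] = []

    def run_trial(params: dict, seed: int) -> tuple[float, np.ndarray | None, np.ndarray | None]:
        cl_params, pr_params = _split_params(params)
        try:
            emb = project_2d(X, ProjectionSpec(projection_method, pr_params, seed=seed))
            labels = run_clustering(emb, ClusterSpec(cluster_method, cl_params, seed=seed))
            return _objective_on(emb, labels), labels, emb
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append(f"{params}: {exc}")
            return DEGENERATE_SCORE, None, None

    if projected:
        sampler = TPESampler(space.params, seed=space.seed)
        seeds = _trial_seeds(space.seed, space.n_trials)
        best = (DEGENERATE_SCORE - 1, None, None, None, 0)  # score, labels, emb, params, seed
        for t in range(space.n_trials):
            params = sampler.suggest(trace)
            score, labels, emb = run_trial(params, int(seeds[t]))
            trace.append((params, score))
            if labels is not None and score > DEGENERATE_SCORE and score > best[0]:
                best = (score, labels, emb, params, int(seeds[t]))
        if best[1] is None:
            raise ValueError(
                "every tuning trial was degenerate; failures: "
                + "; ".join(failures[:5])
            )
        score, labels, emb, params, trial_seed = best
        cl_params, pr_params = _split_params(params)
        return GroupingResult(
            labels=np.asarray(labels),
            embedding=np.asarray(emb),
            silhouette=float(score),
            config={
                "cluster_method": cluster_method,
                "projection_method": projection_method,
                "projected": True,
                "cluster_params": cl_params,
                "projection_params": pr_params,
                "seed": space.seed,
                "trial_seed": trial_seed,
            },
            tuning_trace=trace,
        )

    # non-projected: stage 1 — cluster params in full space
    cl_space = space.subset("cluster__")
    sampler1 = TPESampler(cl_space, seed=space.seed)
    seeds1 = _trial_seeds(space.seed, space.n_trials)
    stage1: list[tuple[dict, float]] = []
    best1 = (DEGENERATE_SCORE - 1, None, None)
    for t in range(space.n_trials):
        params = sampler1.suggest(stage1)
        cl_params, _ = _split_params(params)
        try:
            labels = run_clustering(X, ClusterSpec(cluster_method, cl_params, seed=int(seeds1[t])))
            score = _objective_on(X, labels)
        except (ValueError, np.linalg.LinAlgError) as exc:
            failures.append(f"{params}: {exc}")
            score, labels = DEGENERATE_SCORE, None
        stage1.append((params, score))
        if labels is not None and score > DEGENERATE_SCORE and score > best1[0]:
            best1 = (score, labels, params)
    if best1[1] is None:
        raise ValueError(
            "every stage-1 tuning trial was degenerate; failures: "
            + "; ".join(failures[:5])
        )
    full_labels = np.asarray(best1[1])
    frozen_cluster, _ = _split_params(best1[2])

    # stage 2 — projection params, re-clustering each trial embedding
    pr_space = space.subset("proj__")
    best2 = (DEGENERATE_SCORE - 1, None, None, None, 0)
    stage2: list[tuple[dict, float]] = []
    if pr_space:
        sampler2 = TPESampler(pr_space, seed=space.seed + 1)
        seeds2 = _trial_seeds(space.seed + 1, space.n_trials)
        for t in range(space.n_trials):
            params = sampler2.suggest(stage2)
            joint = dict(params)
            joint.update({f"cluster__{k}": v for k, v in frozen_cluster.items()})
            score, labels, emb = run_trial(joint, int(seeds2[t]))
            stage2.append((params, score))
            if labels is not None and score > DEGENERATE_SCORE and score > best2[0]:
                best2 = (score, labels, emb, params, int(seeds2[t]))
    if best2[1] is None:
        # no projection space to search: project once with defaults
        seed0 = int(_trial_seeds(space.seed + 1, 1)[0])
        emb = project_2d(X, ProjectionSpec(projection_method, {}, seed=seed0))
        labels = run_clustering(emb, ClusterSpec(cluster_method, frozen_cluster, seed=seed0))
        best2 = (_objective_on(emb, labels), labels, emb, {}, seed0)
        stage2.append(({}, best2[0]))

    score, labels, emb, pr_params_raw, trial_seed = best2
    _, pr_params = _split_params(pr_params_raw)
    trace = stage1 + stage2
    return GroupingResult(
        labels=np.asarray(labels),
        embedding=np.asarray(emb),
        silhouette=float(score),
        config={
            "cluster_method": cluster_method,
            "projection_method": projection_method,
            "projected": False,
            "cluster_params": frozen_cluster,
            "projection_params": pr_params,
            "seed": space.seed,
            "trial_seed": trial_seed,
        },
        tuning_trace=trace,
        full_space_labels=full_labels,
    )
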