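"""Dimensionality reduction and supervised feature selection.

Filters: a low-variance filter (population variance; a column is removed
when its variance is <= the threshold, so threshold 0 removes constants) and
a greedy Pearson-correlation filter (for each pair |r| above the threshold,
the later column in input order is removed). Both have an automated
threshold search for labeled data: thresholds on a grid (default 0.00-0.10
in steps of 0.01) are evaluated by training a learner on an 80/20 split or
by 5-fold cross-validation, and the best-scoring threshold is applied to the
full matrix.

Note: the printed 0-0.1 grid is sensible for the variance filter but removes
nearly everything when used as a correlation cutoff; the grid is therefore
configurable (see docs/methods.md).

Supervised selectors: recursive feature elimination dropping the 20% least
important columns per iteration, a genetic algorithm over feature bit-masks,
and simulated annealing with a Metropolis acceptance rule and geometric
cooling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

from chemgroup.descriptors import FeatureMatrix
from chemgroup.learners import (
    LearnerSpec,
    cv_score,
    default_metric,
    holdout_score,
    make_learner,
)

DEFAULT_THRESHOLD_GRID = [round(0.01 * i, 2) for i in range(11)]  # 0.00 .. 0.10


@dataclass
class FilterResult:
    kept_columns: list[str]
    removed_columns: list[str]
    method: str  # variance | correlation
    threshold: float
    search_trace: list[tuple[float, float | None]] | None = None
    cv_mode: str | None = None  # holdout_80_20 | cv5

    def apply(self, fm: FeatureMatrix) -> FeatureMatrix:
        return fm.select_columns([c for c in fm.column_names if c in set(self.kept_columns)])


@dataclass
class GAConfig:
    population_size: int = 50
    crossover_proba: float = 0.5
    mutation_prob: float = 0.2
    #: per-bit flip probability applied when an individual is mutated
    mutation_indpb: float = 0.05
    n_generations: int = 40
    tournament_size: int = 3
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.crossover_proba, self.mutation_prob, self.mutation_indpb):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if min(self.population_size, self.tournament_size, self.cv_folds) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")


@dataclass
class SAConfig:
    """Simulated-annealing schedule.

    The default initial temperature is derived from the schedule itself,
    min_temperature / cooling_factor**max_iterations (≈ 0.13): the geometric
    cooling then spans the full iteration budget and finishes at the stopping
    floor, with the Metropolis rule permissive early and selective late on
    the scale of typical cross-validated score changes.
    """

    init_fraction: float = 0.5
    cv_folds: int = 3
    cooling_factor: float = 0.95
    max_iterations: int = 50
    min_temperature: float = 0.01
    initial_temperature: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_factor < 1.0:
            raise ValueError("cooling_factor must be in (0, 1)")
        if not 0.0 < self.init_fraction <= 1.0:
            raise ValueError("init_fraction must be in (0, 1]")
        if self.initial_temperature is None:
            self.initial_temperature = (
                self.min_temperature / self.cooling_factor**self.max_iterations
            )


@dataclass
class SelectionResult:
    selected_columns: list[str]
    method: str  # manual | rfe | ga | sa
    score_trace: list[tuple[int, float]]
    final_score: float
    metric: str


@dataclass
class ColumnStats:
    frame: pd.DataFrame  # columns: mean, variance, skewness, kurtosis


# ---------------------------------------------------------------------------
# filters


def variance_filter(fm: FeatureMatrix, threshold: float) -> FilterResult:
    """Remove columns whose population variance is <= ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    variances = fm.values.var(axis=0, ddof=0)
    kept = [c for c, v in zip(fm.column_names, variances) if v > threshold]
    removed = [c for c, v in zip(fm.column_names, variances) if v <= threshold]
    if not kept:
        raise ValueError(
            f"variance filter at threshold {threshold} removed every column"
        )
    return FilterResult(kept, removed, "variance", float(threshold))


def correlation_filter(fm: FeatureMatrix, threshold: float) -> FilterResult:
    """Greedy Pearson-correlation filter.

    Scans ordered pairs (i < j); when |r| > threshold and both columns are
    still kept, the later column j is removed. Deterministic given column
    order. Constant columns have undefined r, treated as 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("correlation threshold must be in [0, 1]")
    if fm.p < 2:
        raise ValueError("correlation filter needs at least 2 columns")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(fm.values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    keep = np.ones(fm.p, dtype=bool)
    for i in range(fm.p):
        if not keep[i]:
            continue
        for j in range(i + 1, fm.p):
            if keep[j] and abs(corr[i, j]) > threshold:
                keep[j] = False
    kept = [c for c, k in zip(fm.column_names, keep) if k]
    removed = [c for c, k in zip(fm.column_names, keep) if not k]
    return FilterResult(kept, removed, "correlation", float(threshold))


def _apply_filter_to_values(
    values: np.ndarray, column_names: list[str], kind: str, threshold: float
) -> np.ndarray:
    """Column mask for a filter computed on raw values (used by the search)."""
    fm = FeatureMatrix(
        row_ids=[str(i) for i in range(values.shape[0])],
        column_names=column_names,
        values=values,
    )
    if kind == "variance":
        variances = values.var(axis=0, ddof=0)
        return variances > threshold
    res = correlation_filter(fm, threshold)
    kept = set(res.kept_columns)
    return np.array([c in kept for c in column_names])


def auto_threshold_search(
    fm: FeatureMatrix,
    labels: np.ndarray,
    learner_spec: LearnerSpec,
    filter_kind: str,
    grid: list[float] | None = None,
    cv_mode: str = "holdout_80_20",
    seed: int = 0,
) -> FilterResult:
    """Exhaustive grid search for the best filter threshold on labeled data.

    Each grid threshold is applied, a learner is trained and scored —
    accuracy for classification, R^2 for regression — on the held-out
    portion(s), and the best-scoring threshold is applied to the full
    matrix. Thresholds that leave zero columns are recorded in the trace
    with score None and skipped.
    """
    if filter_kind not in ("variance", "correlation"):
        raise ValueError(f"unknown filter kind {filter_kind!r}")
    if cv_mode not in ("holdout_80_20", "cv5"):
        raise ValueError(f"unknown cv_mode {cv_mode!r}")
    grid = DEFAULT_THRESHOLD_GRID if grid is None else list(grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are constant; automated search needs variation")
    metric = "accuracy" if learner_spec.task == "classification" else "r2"

    X = fm.values
    strat = labels if learner_spec.task == "classification" else None
    if cv_mode == "holdout_80_20":
        tr, te = train_test_split(
            np.arange(fm.n), test_size=0.2, random_state=seed, stratify=strat
        )

    trace: list[tuple[float, float | None]] = []
    best: tuple[float, float] | None = None
    for thr in grid:
        mask = _apply_filter_to_values(X, fm.column_names, filter_kind, thr)
        if not mask.any():
            trace.append((float(thr), None))
            continue
        Xf = X[:, mask]
        if cv_mode == "holdout_80_20":
            score = holdout_score(
                learner_spec, Xf[tr], labels[tr], Xf[te], labels[te], metric
            )
        else:
            score = cv_score(learner_spec, Xf, labels, metric, k_folds=5, seed=seed)
        trace.append((float(thr), float(score)))
        if best is None or score > best[1]:
            best = (float(thr), float(score))
    if best is None:
        raise ValueError("every grid threshold removed all columns")

    result = (
        variance_filter(fm, best[0])
        if filter_kind == "variance"
        else correlation_filter(fm, best[0])
    )
    result.search_trace = trace
    result.cv_mode = cv_mode
    return result


def column_stats(fm: FeatureMatrix) -> ColumnStats:
    """Per-column mean, population variance, skewness (g1), excess kurtosis.

    Undefined moments of constant columns are reported as 0 by convention.
    """
    X = fm.values
    var = X.var(axis=0, ddof=0)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(X, axis=0, bias=True)
        kurt = stats.kurtosis(X, axis=0, fisher=True, bias=True)
    const = var == 0
    skew = np.where(const, 0.0, np.nan_to_num(skew, nan=0.0))
    kurt = np.where(const, 0.0, np.nan_to_num(kurt, nan=0.0))
    frame = pd.DataFrame(
        {
            "mean": X.mean(axis=0),
            "variance": var,
            "skewness": skew,
            "kurtosis": kurt,
        },
        index=fm.column_names,
    )
    return ColumnStats(frame=frame)


# ---------------------------------------------------------------------------
# supervised selectors


def _selection_metric(spec: LearnerSpec, prefer: str) -> str:
    if spec.task == "regression":
        return "r2"
    return prefer  # auc for rfe/sa, accuracy for ga


def rfe_select(
    fm: FeatureMatrix,
    labels: np.ndarray,
    learner_spec: LearnerSpec,
    cv_folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination.

    Starting from all columns, each iteration refits the learner, ranks
    columns by importance, and drops the max(1, floor(0.2 * p_current))
    least-important ones. The subset with the best cross-validated AUC
    (classification) or R^2 (regression) along the path is returned.
    """
    labels = np.asarray(labels)
    metric = _selection_metric(learner_spec, "auc")
    learner = make_learner(learner_spec)

    current = list(fm.column_names)
    trace: list[tuple[int, float]] = []
    best_subset, best_score = None, -np.inf
    step = 0
    while True:
        idx = [fm.column_names.index(c) for c in current]
        X = fm.values[:, idx]
        score = cv_score(learner_spec, X, labels, metric, cv_folds, seed)
        trace.append((len(current), float(score)))
        if score > best_score:
            best_subset, best_score = list(current), float(score)
        if len(current) == 1:
            break
        fitted = learner.fit(X, labels, current)
        imp = fitted.importances(seed=seed)
        n_drop = max(1, math.floor(0.2 * len(current)))
        order = np.argsort(imp, kind="stable")  # ascending: least important first
        drop = {current[i] for i in order[:n_drop]}
        current = [c for c in current if c not in drop]
        step += 1
    return SelectionResult(best_subset, "rfe", trace, best_score, metric)


def rfe_size_path(p: int) -> list[int]:
    """Subset sizes visited by the elimination rule, for independent checking."""
    sizes = [p]
    while sizes[-1] > 1:
        sizes.append(sizes[-1] - max(1, math.floor(0.2 * sizes[-1])))
    return sizes


def ga_select(
    fm: FeatureMatrix,
    labels: np.ndarray,
    learner_spec: LearnerSpec,
    cfg: GAConfig,
) -> SelectionResult:
    """Genetic-algorithm feature selection over boolean column masks.

    Fitness is cross-validated accuracy (classification) or R^2
    (regression). Tournament selection picks parents; uniform crossover is
    applied with probability ``crossover_proba``; with probability
    ``mutation_prob`` an offspring is mutated, flipping each bit with
    probability ``mutation_indpb``. The best-ever mask is tracked
    elitistically, so the reported score trace is non-decreasing.
    """
    labels = np.asarray(labels)
    if cfg.population_size < cfg.tournament_size:
        raise ValueError("population smaller than tournament size")
    metric = _selection_metric(learner_spec, "accuracy")
    rng = np.random.default_rng(cfg.seed)
    p = fm.p

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        if not mask.any():
            return -np.inf
        key = mask.tobytes()
        if key not in cache:
            cache[key] = cv_score(
                learner_spec, fm.values[:, mask], labels, metric,
                cfg.cv_folds, cfg.seed,
            )
        return cache[key]

    def random_mask() -> np.ndarray:
        mask = rng.random(p) < 0.5
        if not mask.any():
            mask[rng.integers(p)] = True
        return mask

    pop = [random_mask() for _ in range(cfg.population_size)]
    scores = [fitness(m) for m in pop]
    best_idx = int(np.argmax(scores))
    best_mask, best_score = pop[best_idx].copy(), scores[best_idx]
    trace = [(0, float(best_score))]

    for gen in range(1, cfg.n_generations + 1):
        def tournament() -> np.ndarray:
            idx = rng.choice(len(pop), size=cfg.tournament_size, replace=False)
            return pop[max(idx, key=lambda i: scores[i])].copy()

        offspring = []
        while len(offspring) < cfg.population_size:
            a, b = tournament(), tournament()
            if rng.random() < cfg.crossover_proba:
                swap = rng.random(p) < 0.5
                a[swap], b[swap] = b[swap], a[swap].copy()
            for child in (a, b):
                if rng.random() < cfg.mutation_prob:
                    flips = rng.random(p) < cfg.mutation_indpb
                    child[flips] = ~child[flips]
                if not child.any():
                    child[rng.integers(p)] = True
                offspring.append(child)
        pop = offspring[: cfg.population_size]
        scores = [fitness(m) for m in pop]
        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_mask, best_score = pop[gen_best].copy(), scores[gen_best]
        trace.append((gen, float(best_score)))

    selected = [c for c, m in zip(fm.column_names, best_mask) if m]
    return SelectionResult(selected, "ga", trace, float(best_score), metric)


def sa_select(
    fm: FeatureMatrix,
    labels: np.ndarray,
    learner_spec: LearnerSpec,
    cfg: SAConfig,
) -> SelectionResult:
    """Simulated-annealing feature selection.

    Starts from a random subset of ceil(init_fraction * p) columns. Each
    iteration proposes one move (add, replace, or remove a column, uniform
    among feasible moves); improvements are always accepted, worse subsets
    with Metropolis probability exp((s_new - s_cur) / T). The temperature
    cools geometrically (T *= cooling_factor) after every iteration; the run
    stops at ``max_iterations`` or when T drops below ``min_temperature``.
    The best-ever subset is returned.
    """
    labels = np.asarray(labels)
    p = fm.p
    if p < 2:
        raise ValueError("simulated annealing needs at least 2 columns")
    metric = _selection_metric(learner_spec, "auc")
    rng = np.random.default_rng(cfg.seed)

    def score(mask: np.ndarray) -> float:
        return cv_score(
            learner_spec, fm.values[:, mask], labels, metric, cfg.cv_folds, cfg.seed
        )

    size0 = max(1, math.ceil(cfg.init_fraction * p))
    mask = np.zeros(p, dtype=bool)
    mask[rng.choice(p, size=size0, replace=False)] = True
    cur_score = score(mask)
    best_mask, best_score = mask.copy(), cur_score
    trace = [(0, float(cur_score))]

    T = cfg.initial_temperature
    for it in range(1, cfg.max_iterations + 1):
        if T < cfg.min_temperature:
            break
        inside = np.flatnonzero(mask)
        outside = np.flatnonzero(~mask)
        moves = []
        if outside.size:
            moves.append("add")
        if inside.size and outside.size:
            moves.append("replace")
        if inside.size >= 2:
            moves.append("remove")
        move = moves[rng.integers(len(moves))]
        new = mask.copy()
        if move == "add":
            new[outside[rng.integers(outside.size)]] = True
        elif move == "remove":
            new[inside[rng.integers(inside.size)]] = False
        else:
            new[inside[rng.integers(inside.size)]] = False
            new[outside[rng.integers(outside.size)]] = True
        new_score = score(new)
        if new_score > cur_score or rng.random() < math.exp(
            min(0.0, (new_score - cur_score) / T)
        ):
            mask, cur_score = new, new_score
        if cur_score > best_score:
            best_mask, best_score = mask.copy(), cur_score
        trace.append((it, float(cur_score)))
        T *= cfg.cooling_factor

    selected = [c for c, m in zip(fm.column_names, best_mask) if m]
    return SelectionResult(selected, "sa", trace, float(best_score), metric)
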