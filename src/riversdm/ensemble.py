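"""Ensemble distribution modeling with committee averaging.

The estimator is a committee of bagged-decision-tree (random forest)
runs.  Each run draws a fresh stratified 80/20 train/test partition of
the presence/pseudoabsence sites, fits a probabilistic classifier, and
is evaluated on its held-out 20% by the True Skill Statistic

    TSS(theta) = sensitivity(theta) + specificity(theta) - 1

maximized over a cutoff grid theta in {0.00, 0.01, ..., 1.00}, and by
the rank-sum (Mann-Whitney) AUC.  Runs with TSS >= 0.7 are selected;
each selected run then predicts on every river cell and is binarized at
its own TSS-optimal cutoff, and the committee average EMca is the mean
of those binary votes — so EMca takes values in {0, 1/k, ..., 1} for k
selected runs.

Variable importance is permutational: one minus the Pearson correlation
between reference predictions and predictions with the variable's column
shuffled, averaged over shuffles, clipped to [0, 1].  Response curves
use the evaluation-strip convention (vary one variable over its observed
range, hold the others at their site medians).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier

from .errors import ModelingError
from .synthetic import EnvStack

CUTOFF_GRID = np.round(np.arange(0, 101) / 100.0, 2)


@dataclass
class ModelRun:
    run_id: int
    seed: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    classifier: RandomForestClassifier = field(repr=False)
    feature_names: list[str] = field(default_factory=list)
    tss: float = float("nan")
    auc: float = float("nan")
    optimal_cutoff: float = float("nan")


@dataclass
class EnsembleModel:
    selected_runs: list[ModelRun]
    tss_threshold: float
    emca_map: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# Partitioning and fitting
# ---------------------------------------------------------------------------


def partition_data(labels: np.ndarray, frac: float = 0.8, seed: int = 0):
    """Stratified train/test split: per class, round-half-up of frac goes to
    train, the remainder to test.  Returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < 2:
            raise ModelingError(f"class {cls} has fewer than 2 members")
        n_train = int(math.floor(frac * len(idx) + 0.5))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


DEFAULT_HYPERPARAMS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


def fit_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> RandomForestClassifier:
    """Bootstrap-aggregated decision trees (500 by default, sqrt features)."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) < 2:
        raise ModelingError("training set contains a single class")
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        params.update(hyperparams)
    clf = RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    return clf


def predict_probability(clf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Probability of the presence class (label 1)."""
    proba = clf.predict_proba(np.asarray(X, dtype=float))
    pos = list(clf.classes_).index(1)
    return proba[:, pos]


# ---------------------------------------------------------------------------
# Evaluation metrics
# ---------------------------------------------------------------------------


def compute_tss(labels: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Maximum TSS over the 0.01 cutoff grid and the smallest maximizing
    cutoff.  Prediction is positive iff score >= cutoff."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ModelingError("TSS needs both classes in the labels")
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    best_tss, best_cut = -np.inf, None
    for theta in CUTOFF_GRID:
        pred = scores >= theta
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        tss = sens + spec - 1.0
        if tss > best_tss + 1e-12:
            best_tss, best_cut = tss, float(theta)
    return float(best_tss), best_cut


def compute_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-sum (Mann-Whitney) AUC with ties counted one half."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ModelingError("AUC needs both classes in the labels")
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# Run orchestration, selection, committee averaging
# ---------------------------------------------------------------------------


def fit_runs(
    table: pd.DataFrame,
    labels: np.ndarray,
    n_runs: int = 10,
    seed: int = 0,
    frac: float = 0.8,
    hyperparams: dict | None = None,
) -> list[ModelRun]:
    """Fit ``n_runs`` independent runs, each with a fresh stratified
    partition and classifier seed, evaluated on its held-out 20%."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    runs = []
    X = table.to_numpy(dtype=float)
    for run_id in range(n_runs):
        run_seed = int(rng.integers(2**31 - 1))
        train_idx, test_idx = partition_data(labels, frac=frac, seed=run_seed)
        clf = fit_classifier(X[train_idx], labels[train_idx], hyperparams, seed=run_seed)
        scores = predict_probability(clf, X[test_idx])
        tss, cutoff = compute_tss(labels[test_idx], scores)
        auc = compute_auc(labels[test_idx], scores)
        runs.append(
            ModelRun(
                run_id=run_id,
                seed=run_seed,
                train_idx=train_idx,
                test_idx=test_idx,
                classifier=clf,
                feature_names=list(table.columns),
                tss=tss,
                auc=auc,
                optimal_cutoff=cutoff,
            )
        )
    return runs


def select_models(runs: list[ModelRun], tss_threshold: float = 0.7) -> list[ModelRun]:
    """Keep runs with TSS >= threshold (inclusive)."""
    if not runs:
        raise ModelingError("no runs to select from")
    selected = [r for r in runs if r.tss >= tss_threshold]
    if not selected:
        raise ModelingError(
            f"no run reached TSS >= {tss_threshold}; "
            "increase the number of runs or supply more data"
        )
    return selected


def committee_average(selected_runs: list[ModelRun], env_stack: EnvStack) -> np.ndarray:
    """EMca map: mean of per-run presence votes (binarized at each run's
    TSS-optimal cutoff) over river cells with complete environmental data;
    NaN where any variable is missing."""
    if not selected_runs:
        raise ModelingError("committee_average needs at least one selected run")
    defined = env_stack.defined_mask()
    cells = np.argwhere(defined)
    if len(cells) == 0:
        raise ModelingError("no cell has complete environmental data")
    features = selected_runs[0].feature_names
    X = np.column_stack(
        [env_stack.variables[name][cells[:, 0], cells[:, 1]] for name in features]
    )
    votes = np.zeros(len(cells), dtype=int)
    for run in selected_runs:
        scores = predict_probability(run.classifier, X)
        votes += (scores >= run.optimal_cutoff).astype(int)
    emca = np.full(env_stack.grid_shape, np.nan)
    emca[cells[:, 0], cells[:, 1]] = votes / len(selected_runs)
    return emca


# ---------------------------------------------------------------------------
# Interpretation: importance, response curves, envelopes
# ---------------------------------------------------------------------------


def variable_importance(
    run: ModelRun,
    table: pd.DataFrame,
    variable: str,
    n_shuffles: int = 3,
    seed: int = 0,
) -> float:
    """Permutation importance: mean over shuffles of 1 - Pearson r between
    reference predictions and predictions after permuting the variable.

    Exactly 0 when shuffling leaves predictions unchanged (variable unused)
    or when either prediction vector is constant.
    """
    if variable not in table.columns:
        raise ModelingError(f"unknown variable {variable!r}")
    rng = np.random.default_rng(seed)
    X_ref = table[run.feature_names].to_numpy(dtype=float)
    ref = predict_probability(run.classifier, X_ref)
    vals = []
    for _ in range(n_shuffles):
        shuffled = table.copy()
        shuffled[variable] = rng.permutation(shuffled[variable].to_numpy())
        X_shuf = shuffled[run.feature_names].to_numpy(dtype=float)
        pred = predict_probability(run.classifier, X_shuf)
        if np.array_equal(pred, ref):
            vals.append(0.0)
            continue
        if np.std(ref) == 0 or np.std(pred) == 0:
            vals.append(0.0)
            continue
        r = float(np.corrcoef(ref, pred)[0, 1])
        vals.append(1.0 - r)
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def importance_table(
    runs: list[ModelRun],
    table: pd.DataFrame,
    n_shuffles: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean importance per variable over runs and shuffles, with ranks
    (1 = most important)."""
    rng = np.random.default_rng(seed)
    rows = {}
    for name in table.columns:
        per_run = [
            variable_importance(run, table, name, n_shuffles, seed=int(rng.integers(2**31 - 1)))
            for run in runs
        ]
        rows[name] = float(np.mean(per_run))
    out = pd.DataFrame({"importance": pd.Series(rows)})
    out["rank"] = out["importance"].rank(ascending=False, method="first").astype(int)
    return out.sort_values("rank")


def response_curve(
    runs: list[ModelRun] | ModelRun,
    table: pd.DataFrame,
    variable: str,
    n_points: int = 100,
) -> pd.DataFrame:
    """Evaluation-strip marginal response.

    The variable sweeps its observed range on an ``n_points`` grid while
    every other variable is held at its median over the sites.  For a
    single run the curve is the predicted probability; for a list of runs
    it is the EMca vote fraction (each run binarized at its own cutoff).
    """
    if variable not in table.columns:
        raise ModelingError(f"unknown variable {variable!r}")
    single = isinstance(runs, ModelRun)
    run_list = [runs] if single else list(runs)
    grid = np.linspace(table[variable].min(), table[variable].max(), n_points)
    medians = table.median(axis=0)
    features = run_list[0].feature_names
    strip = np.tile(medians[features].to_numpy(dtype=float), (n_points, 1))
    var_pos = features.index(variable)
    strip[:, var_pos] = grid
    if single:
        response = predict_probability(run_list[0].classifier, strip)
    else:
        votes = np.zeros(n_points)
        for run in run_list:
            scores = predict_probability(run.classifier, strip)
            votes += (scores >= run.optimal_cutoff).astype(float)
        response = votes / len(run_list)
    return pd.DataFrame({variable: grid, "response": response})


def high_probability_envelope(
    emca_map: np.ndarray,
    env_stack: EnvStack,
    p: float = 0.9,
) -> pd.DataFrame:
    """Per-variable min / q25 / q75 / max over cells with EMca strictly
    above ``p`` — the realized environmental envelope of the model's
    high-probability habitat."""
    with np.errstate(invalid="ignore"):
        high = np.isfinite(emca_map) & (emca_map > p)
    if not high.any():
        raise ModelingError(f"no cell has committee score > {p}")
    rows = {}
    for name, grid in env_stack.variables.items():
        vals = grid[high]
        vals = vals[np.isfinite(vals)]
        rows[name] = {
            "min": float(np.min(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
            "max": float(np.max(vals)),
        }
    return pd.DataFrame(rows).T[["min", "q25", "q75", "max"]]
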