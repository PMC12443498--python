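"""Partitioning, classifier fitting, TSS/AUC metrics, model selection,
committee averaging, importance, response curves, envelopes."""

import numpy as np
import pandas as pd
import pytest

from riversdm.ensemble import (
    committee_average,
    compute_auc,
    compute_tss,
    fit_classifier,
    fit_runs,
    high_probability_envelope,
    importance_table,
    partition_data,
    predict_probability,
    response_curve,
    select_models,
    variable_importance,
)
from riversdm.errors import ModelingError
from riversdm.synthetic import EnvStack


# --- independent metric oracles ------------------------------------------------


def tss_brute(labels, scores):
    best, best_cut = -2.0, None
    for k in range(101):
        theta = k / 100.0
        tp = fn = tn = fp = 0
        for y, s in zip(labels, scores):
            pred = s >= theta
            if y == 1:
                tp, fn = tp + pred, fn + (not pred)
            else:
                tn, fp = tn + (not pred), fp + pred
        tss = tp / (tp + fn) + tn / (tn + fp) - 1.0
        if tss > best + 1e-12:
            best, best_cut = tss, theta
    return best, best_cut


def auc_brute(labels, scores):
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


# --- partitioning ---------------------------------------------------------------


def test_partition_20_sites():
    labels = np.array([1] * 10 + [0] * 10)
    train, test = partition_data(labels, seed=1)
    assert (labels[train] == 1).sum() == 8 and (labels[train] == 0).sum() == 8
    assert (labels[test] == 1).sum() == 2 and (labels[test] == 0).sum() == 2
    assert set(train).isdisjoint(test)


def test_partition_84_plus_84_rounds_half_up():
    labels = np.array([1] * 84 + [0] * 84)
    train, test = partition_data(labels, seed=3)
    # 0.8 * 84 = 67.2 -> 67 train, 17 test per class
    assert (labels[train] == 1).sum() == 67 and (labels[test] == 1).sum() == 17
    assert (labels[train] == 0).sum() == 67 and (labels[test] == 0).sum() == 17


def test_partition_deterministic():
    labels = np.array([1] * 30 + [0] * 30)
    a = partition_data(labels, seed=9)
    b = partition_data(labels, seed=9)
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_partition_tiny_class_raises():
    with pytest.raises(ModelingError):
        partition_data(np.array([1, 0, 0, 0]), seed=1)


# --- classifier -------------------------------------------------------------------


def _separable_toy(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 3))
    y = (X[:, 0] > 0).astype(int)
    return X, y


def test_classifier_separable_case():
    X, y = _separable_toy()
    clf = fit_classifier(X[:150], y[:150], seed=1)
    p = predict_probability(clf, X[:150][y[:150] == 1])
    assert (p > 0.5).all()


def test_classifier_deterministic():
    X, y = _separable_toy()
    a = predict_probability(fit_classifier(X, y, seed=4), X)
    b = predict_probability(fit_classifier(X, y, seed=4), X)
    assert np.array_equal(a, b)


def test_classifier_single_class_raises():
    X = np.zeros((10, 2))
    with pytest.raises(ModelingError):
        fit_classifier(X, np.ones(10), seed=1)


def test_classifier_learns_threshold_rule():
    X, y = _separable_toy(n=200, seed=5)
    clf = fit_classifier(X[:160], y[:160], seed=2)
    scores = predict_probability(clf, X[160:])
    assert compute_auc(y[160:], scores) > 0.95


# --- TSS / AUC ---------------------------------------------------------------------


def test_tss_examples():
    tss, cut = compute_tss([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
    assert tss == pytest.approx(1.0)
    tss, _ = compute_tss([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
    assert tss == pytest.approx(0.0)
    # max TSS 0.5 is attained on the whole cutoff interval (0.1, 0.4];
    # the smallest grid cutoff attaining it is 0.11
    tss, cut = compute_tss([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
    assert tss == pytest.approx(0.5)
    assert cut == pytest.approx(0.11)
    assert (tss, cut) == tss_brute([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])


def test_auc_examples():
    assert compute_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == pytest.approx(1.0)
    assert compute_auc([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9]) == pytest.approx(0.0)
    assert compute_auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1]) == pytest.approx(0.75)


def test_metrics_single_class_raise():
    with pytest.raises(ModelingError):
        compute_tss([1, 1], [0.2, 0.4])
    with pytest.raises(ModelingError):
        compute_auc([0, 0], [0.2, 0.4])


def test_metrics_match_brute_force_enumeration():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(2, 21))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(size=n), 3)
        tss, cut = compute_tss(labels, scores)
        b_tss, b_cut = tss_brute(labels.tolist(), scores.tolist())
        assert tss == pytest.approx(b_tss, abs=1e-12)
        assert cut == pytest.approx(b_cut, abs=1e-12)
        assert compute_auc(labels, scores) == pytest.approx(
            auc_brute(labels.tolist(), scores.tolist()), abs=1e-12
        )


# --- selection and committee --------------------------------------------------------


def _dummy_run(tss, cutoff=0.5, clf=None, features=None):
    from riversdm.ensemble import ModelRun

    return ModelRun(
        run_id=0, seed=0, train_idx=np.array([0]), test_idx=np.array([1]),
        classifier=clf, feature_names=features or [], tss=tss, auc=0.9,
        optimal_cutoff=cutoff,
    )


def test_select_models_threshold_inclusive():
    runs = [_dummy_run(0.95), _dummy_run(0.70), _dummy_run(0.65)]
    assert len(select_models(runs)) == 2


def test_select_models_none_selected_raises():
    with pytest.raises(ModelingError, match="TSS"):
        select_models([_dummy_run(0.2)])


def _toy_stack_and_runs(k=2, seed=0):
    """Tiny 1-variable riverscape with classifiers that disagree."""
    rng = np.random.default_rng(seed)
    grid = np.full((6, 6), np.nan)
    vals = np.linspace(0, 1, 12)
    cells = [(r, c) for r in range(2) for c in range(6)]
    for (r, c), v in zip(cells, vals):
        grid[r, c] = v
    stack = EnvStack({"x": grid}, (6, 6), 1.0, {"x": (0.0, 1.0)})
    X = rng.random(size=(40, 1))
    runs = []
    for i in range(k):
        y = (X[:, 0] > 0.5).astype(int) if i % 2 == 0 else (X[:, 0] > 0.4).astype(int)
        clf = fit_classifier(X, y, seed=i)
        runs.append(_dummy_run(0.9, cutoff=0.5, clf=clf, features=["x"]))
    return stack, runs


def test_committee_single_run_is_binary():
    stack, runs = _toy_stack_and_runs(k=1)
    emca = committee_average(runs[:1], stack)
    vals = emca[np.isfinite(emca)]
    assert set(np.unique(vals)) <= {0.0, 1.0}


def test_committee_values_are_vote_fractions():
    stack, runs = _toy_stack_and_runs(k=2)
    emca = committee_average(runs, stack)
    vals = emca[np.isfinite(emca)]
    assert set(np.round(vals, 9)) <= {0.0, 0.5, 1.0}


def test_committee_preserves_nodata():
    stack, runs = _toy_stack_and_runs(k=2)
    emca = committee_average(runs, stack)
    assert np.array_equal(np.isfinite(emca), stack.defined_mask())


# --- importance, curves, envelopes ----------------------------------------------------


def _informative_table(n=300, seed=1):
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(
        {"driver": rng.normal(size=n), "noise": rng.normal(size=n)}
    )
    y = (table["driver"] > 0).astype(int).to_numpy()
    return table, y


def test_unused_variable_importance_is_exactly_zero():
    table, y = _informative_table()
    clf = fit_classifier(table[["driver"]].to_numpy(), y, seed=1)
    run = _dummy_run(0.9, clf=clf, features=["driver"])
    assert variable_importance(run, table, "noise", seed=2) == 0.0


def test_driver_importance_exceeds_noise():
    table, y = _informative_table()
    clf = fit_classifier(table.to_numpy(), y, seed=1)
    run = _dummy_run(0.9, clf=clf, features=["driver", "noise"])
    imp_driver = variable_importance(run, table, "driver", seed=3)
    imp_noise = variable_importance(run, table, "noise", seed=3)
    assert imp_driver > imp_noise
    assert 0.0 <= imp_noise <= 1.0


def test_unknown_variable_raises():
    table, y = _informative_table()
    clf = fit_classifier(table.to_numpy(), y, seed=1)
    run = _dummy_run(0.9, clf=clf, features=["driver", "noise"])
    with pytest.raises(ModelingError, match="unknown variable"):
        variable_importance(run, table, "bogus")


def test_importance_table_ranks_are_permutation():
    table, y = _informative_table(n=120)
    runs = fit_runs(table, y, n_runs=2, seed=5, hyperparams={"n_estimators": 50})
    imp = importance_table(runs, table, seed=6)
    assert sorted(imp["rank"]) == [1, 2]
    assert ((imp["importance"] >= 0) & (imp["importance"] <= 1)).all()


def test_response_curve_bounded_and_monotone_for_threshold_rule():
    table, y = _informative_table()
    runs = fit_runs(table, y, n_runs=3, seed=7, hyperparams={"n_estimators": 100})
    curve = response_curve(runs, table, "driver", n_points=50)
    assert ((curve["response"] >= 0) & (curve["response"] <= 1)).all()
    # single run variant returns probabilities
    single = response_curve(runs[0], table, "driver", n_points=50)
    assert ((single["response"] >= 0) & (single["response"] <= 1)).all()
    # responses low on the far negative side, high on the far positive side
    assert curve["response"].iloc[:5].mean() < curve["response"].iloc[-5:].mean()


def test_envelope_degenerate_and_ordering():
    emca = np.full((4, 4), np.nan)
    emca[0, 0] = emca[0, 1] = 1.0
    grid = np.full((4, 4), np.nan)
    grid[0, 0] = grid[0, 1] = 7.0
    stack = EnvStack({"v": grid}, (4, 4), 1.0, {"v": (0.0, 10.0)})
    env = high_probability_envelope(emca, stack)
    assert env.loc["v"].tolist() == [7.0, 7.0, 7.0, 7.0]


def test_envelope_without_qualifying_cells_raises():
    emca = np.full((4, 4), 0.5)
    grid = np.ones((4, 4))
    stack = EnvStack({"v": grid}, (4, 4), 1.0, {"v": (0.0, 10.0)})
    with pytest.raises(ModelingError):
        high_probability_envelope(emca, stack, p=0.9)
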