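"""Classifiers, splits, metrics, and the experiment protocol."""

import numpy as np
import pytest
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

import gwaswd.models as models
from gwaswd import (
    ConfusionCounts, DeepNNClassifier, RandomForestVoteClassifier, SplitSpec,
    WideDeepNetClassifier, WideNNClassifier, compute_metrics, confusion_counts,
    kfold_indices, majority_vote, pr_points, roc_points, stratified_split,
)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

def test_stratified_split_balanced():
    y = np.array([1] * 100 + [2] * 100)
    tr, te = stratified_split(y, SplitSpec(seed=0))
    assert len(tr) == 140 and len(te) == 60
    assert (y[tr] == 2).sum() == 70 and (y[te] == 2).sum() == 30


def test_stratified_split_deterministic():
    y = np.array([1, 2] * 30)
    a = stratified_split(y, SplitSpec(seed=5))
    b = stratified_split(y, SplitSpec(seed=5))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_stratified_split_cohort_proportions():
    # 174 cases / 214 controls: train size 271 or 272, case share preserved
    y = np.array([2] * 174 + [1] * 214)
    tr, te = stratified_split(y, SplitSpec(seed=1))
    assert len(tr) in (271, 272)
    case_frac = (y[tr] == 2).mean()
    assert abs(case_frac - 174 / 388) <= 1.5 / len(tr)


def test_stratified_split_single_class_errors():
    with pytest.raises(ValueError):
        stratified_split(np.ones(10, dtype=int))


def test_kfold_partition():
    y = np.array([1] * 25 + [2] * 25)
    folds = kfold_indices(y, 5, seed=0)
    assert all(len(f) == 10 for f in folds)
    union = np.sort(np.concatenate(folds))
    assert np.array_equal(union, np.arange(50))
    for f in folds:
        assert abs((y[f] == 2).sum() - 5) <= 1
    with pytest.raises(ValueError):
        kfold_indices(np.array([1, 1, 2]), 5)


# ---------------------------------------------------------------------------
# Majority vote and the RF
# ---------------------------------------------------------------------------

def test_majority_vote_examples():
    # 2/3 votes in favour of the control class elect control
    assert majority_vote(["control", "control", "case"]) == "control"
    assert majority_vote([1, 1, 2]) == 1
    assert majority_vote([2, 2, 2]) == 2
    assert majority_vote([1, 2, 1, 2], control_class=1) == 1  # tie -> control
    with pytest.raises(ValueError):
        majority_vote([])


def test_rf_vote_fraction_and_tie_behavior(rng):
    X = rng.random((40, 5))
    y = np.array([1, 2] * 20)
    rf = RandomForestVoteClassifier(n_estimators=11, random_state=0).fit(X, y)
    proba = rf.predict_proba(X)
    assert np.allclose(proba.sum(axis=1), 1.0)
    votes = proba * 11  # vote fractions over 11 trees are integer counts
    assert np.allclose(votes, np.round(votes))


def test_rf_separable_training_accuracy(rng):
    X = np.vstack([rng.normal(-3, 0.3, size=(30, 2)), rng.normal(3, 0.3, size=(30, 2))])
    y = np.array([1] * 30 + [2] * 30)
    rf = RandomForestVoteClassifier(n_estimators=25, random_state=0).fit(X, y)
    assert (rf.predict(X) == y).mean() == 1.0


def test_single_tree_equals_plain_decision_tree(rng):
    X = rng.integers(0, 2, size=(20, 6)).astype(float)
    y = rng.integers(1, 3, size=20)
    if len(np.unique(y)) < 2:
        y[0] = 1
        y[1] = 2
    rf = RandomForestVoteClassifier(
        n_estimators=1, bootstrap=False, max_features=None, random_state=3
    ).fit(X, y)
    tree = DecisionTreeClassifier(random_state=3).fit(X, y)
    assert np.array_equal(rf.predict(X), tree.predict(X))


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        # printed (accuracy, precision, recall, F1) rows as percentages
        (ConfusionCounts(tp=7776, tn=0, fp=324, fn=1824), (96, 81, 88)),
        (ConfusionCounts(tp=1683, tn=0, fp=17, fn=792), (99, 68, 81)),
        (ConfusionCounts(tp=8019, tn=0, fp=81, fn=1881), (99, 81, 89)),
    ],
)
def test_f1_identities_round_to_percent(counts, expected):
    m = compute_metrics(counts)
    p_pct, r_pct, f_pct = expected
    assert round(m.precision * 100) == p_pct
    assert round(m.recall * 100) == r_pct
    assert round(m.f1 * 100) == f_pct


def test_metrics_perfect_classifier():
    m = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
    assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)


def test_metrics_zero_denominators_flagged():
    m = compute_metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
    assert m.precision == 0.0 and "precision" in m.undefined


def test_f1_between_harmonic_bounds(rng):
    for _ in range(50):
        c = ConfusionCounts(*rng.integers(1, 100, size=4))
        m = compute_metrics(c)
        assert min(m.precision, m.recall) - 1e-12 <= m.f1 <= max(m.precision, m.recall) + 1e-12


def test_confusion_counts_total(rng):
    y = rng.integers(1, 3, size=30)
    pred = rng.integers(1, 3, size=30)
    c = confusion_counts(y, pred)
    assert c.total == 30


# ---------------------------------------------------------------------------
# ROC / PR
# ---------------------------------------------------------------------------

def test_roc_pr_perfect_ranking():
    y = np.array([1] * 5 + [2] * 5)
    s = np.concatenate([np.linspace(0, 0.4, 5), np.linspace(0.6, 1, 5)])
    _, _, roc_auc = roc_points(s, y)
    _, _, pr_auc = pr_points(s, y)
    assert roc_auc == 1.0 and pr_auc == 1.0


def test_roc_equals_mann_whitney_u(rng):
    y = rng.integers(1, 3, size=10)
    y[:2] = [1, 2]
    s = rng.random(10)
    _, _, roc_auc = roc_points(s, y)
    pos, neg = s[y == 2], s[y == 1]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    assert roc_auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)


def test_roc_random_scores_near_half(rng):
    y = np.array([1, 2] * 1000)
    _, _, roc_auc = roc_points(rng.random(2000), y)
    assert 0.47 < roc_auc < 0.53


def test_roc_single_class_errors():
    with pytest.raises(ValueError):
        roc_points(np.random.rand(5), np.ones(5, dtype=int) * 2)


# ---------------------------------------------------------------------------
# Neural networks
# ---------------------------------------------------------------------------

def test_wnn_learns_xor(rng):
    X = rng.integers(0, 2, size=(200, 2)).astype(float)
    y = (X[:, 0].astype(int) ^ X[:, 1].astype(int)) + 1
    net = WideNNClassifier(hidden_width=8, max_epochs=300, random_state=0).fit(X, y)
    assert (net.predict(X) == y).mean() >= 0.95


def test_nn_zero_epochs_is_chance(rng):
    X = rng.random((400, 10))
    y = np.array([1, 2] * 200)
    net = WideNNClassifier(max_epochs=0, random_state=0).fit(X, y)
    _, _, auc = roc_points(net.predict_proba(X)[:, 1], y)
    assert 0.35 < auc < 0.65


def test_nn_fixed_seed_identical_weights(rng):
    X = rng.random((80, 6))
    y = np.array([1, 2] * 40)
    nets = [
        DeepNNClassifier(hidden_layer_sizes=(8, 4), max_epochs=30, random_state=9).fit(X, y)
        for _ in range(2)
    ]
    for a, b in zip(nets[0].weights_[0], nets[1].weights_[0]):
        assert np.array_equal(a, b)
    assert np.array_equal(nets[0].weights_[2], nets[1].weights_[2])


def test_dnn_linearly_separable(rng):
    X = np.vstack([rng.normal(-2, 0.5, (60, 4)), rng.normal(2, 0.5, (60, 4))])
    y = np.array([1] * 60 + [2] * 60)
    order = rng.permutation(120)
    X, y = X[order], y[order]
    net = DeepNNClassifier(max_epochs=150, random_state=0).fit(X[:80], y[:80])
    assert (net.predict(X[80:]) == y[80:]).mean() >= 0.95


def test_nn_matches_sklearn_mlp_on_separable(rng):
    from sklearn.neural_network import MLPClassifier

    X = np.vstack([rng.normal(-2, 0.6, (60, 3)), rng.normal(2, 0.6, (60, 3))])
    y = np.array([1] * 60 + [2] * 60)
    order = rng.permutation(120)
    X, y = X[order], y[order]
    ours = WideNNClassifier(hidden_width=16, max_epochs=150, random_state=0).fit(X[:80], y[:80])
    ref = MLPClassifier(hidden_layer_sizes=(16,), max_iter=500, random_state=0).fit(X[:80], y[:80])
    assert (ours.predict(X[80:]) == y[80:]).mean() >= 0.95
    assert (ref.predict(X[80:]) == y[80:]).mean() >= 0.95


def test_wide_deep_shape_law(rng):
    X = rng.random((60, 10))
    y = np.array([1, 2] * 30)
    net = WideDeepNetClassifier(
        hidden_layer_sizes=(12, 6), n_wide=4, max_epochs=5, random_state=0
    ).fit(X, y)
    Ws, bs, w_out, b_out = net.weights_
    assert Ws[0].shape == (6, 12)  # 10 - 4 wide = 6 deep inputs
    assert len(w_out) == 6 + 4  # last deep width + wide block


def test_wide_deep_zero_wide_equals_dnn(rng):
    X = rng.random((50, 8))
    y = np.array([1, 2] * 25)
    a = WideDeepNetClassifier(hidden_layer_sizes=(8,), n_wide=0,
                              max_epochs=20, random_state=1).fit(X, y)
    b = DeepNNClassifier(hidden_layer_sizes=(8,), max_epochs=20, random_state=1).fit(X, y)
    assert np.allclose(a.decision_function(X), b.decision_function(X))


def test_wide_informative_beats_deep_noise(rng):
    n = 300
    informative = rng.integers(0, 2, size=(n, 4)).astype(float)
    logits = informative @ np.array([2.0, -2.0, 1.5, -1.5])
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int) + 1
    noise = rng.random((n, 30))
    X = np.hstack([informative, noise])
    tr, te = stratified_split(y, SplitSpec(seed=0))
    wd = WideDeepNetClassifier(n_wide=4, max_epochs=100, random_state=0).fit(X[tr], y[tr])
    deep_only = WideDeepNetClassifier(n_wide=0, max_epochs=100, random_state=0).fit(
        X[tr][:, 4:], y[tr]
    )
    _, _, auc_wd = roc_points(wd.predict_proba(X[te])[:, 1], y[te])
    _, _, auc_deep = roc_points(deep_only.predict_proba(X[te][:, 4:])[:, 1], y[te])
    assert auc_wd >= auc_deep


def test_nn_rejects_nonfinite():
    X = np.array([[0.0, np.nan], [1.0, 2.0]])
    with pytest.raises(ValueError, match="non-finite"):
        WideNNClassifier().fit(X, np.array([1, 2]))


# ---------------------------------------------------------------------------
# Experiments (small smoke; the planted-cohort run lives in acceptance)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tiny_qc_cohort():
    from gwaswd import SimulationConfig, run_qc, simulate_cohort

    cfg = SimulationConfig(
        n_cases=60, n_controls=60, n_snps_per_chrom={1: 150, 2: 150},
        causal_spec=[(30, 3.0), (200, 3.0)], maf_range=(0.1, 0.5),
        snp_missing_rate=0.0, seed=21,
    )
    G, truth = simulate_cohort(cfg)
    return G, truth


def test_run_experiment_exp5_uses_association_order(tiny_qc_cohort):
    G, _ = tiny_qc_cohort
    res = models.run_experiment(
        G, 5, top_k=60, seed=0, boruta_trees=30, boruta_iter=5,
        nn_params={"max_epochs": 20},
    )
    ranking = res.selection["logistic_ranking"].table
    table = res.selection["assoc_table"]
    p_of = dict(zip(table["SNP"], table["P"]))
    parents = [f.rsplit("_", 1)[0] for f in ranking["feature"]]
    ps = [p_of[s] for s in parents]
    assert ps == sorted(ps)
    assert set(res.reports) == {"rf", "wnn", "dnn"}


def test_run_experiment_exp4_k0_wide_parents_equal_deep(tiny_qc_cohort):
    G, _ = tiny_qc_cohort
    res = models.run_experiment(
        G, 4, top_k=60, k_neighbours=0, seed=0, boruta_trees=30, boruta_iter=5,
        nn_params={"max_epochs": 20},
    )
    expansion = res.selection["expansion"]
    assert set(expansion.deep_parent_snps) == set(expansion.wide.parent_snps)
    assert set(res.reports) == {"wdnn", "dnn_ablation"}


def test_run_experiment_reports_complete(tiny_qc_cohort):
    G, _ = tiny_qc_cohort
    res = models.run_experiment(
        G, 1, top_k=60, seed=0, boruta_trees=30, boruta_iter=5,
        nn_params={"max_epochs": 20},
    )
    for rep in res.reports.values():
        assert len(rep.fold_metrics) == 5
        assert 0 <= rep.roc_auc <= 1
        assert rep.counts.total > 0
    with pytest.raises(ValueError):
        models.run_experiment(G, 7)
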