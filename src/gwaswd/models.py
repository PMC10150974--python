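"""Classifiers, the 70/30 + 5-fold evaluation protocol, and metrics.

The four model families are a bagged random forest aggregated by
explicit per-tree majority vote (tie toward control), a wide neural
network, a deep neural network, and a wide-and-deep network whose
curated features bypass the deep stack.  Evaluation follows a fixed
protocol: a stratified 70/30 split, 5-fold cross-validation within the
training partition, a single final fit, and one evaluation on the
hold-out.  Metrics are confusion-matrix rates (accuracy, precision,
recall, F1 with case = positive class) plus ROC and PR curves.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc, precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from . import features as feat
from .assoc import run_association, select_top_k
from .nnet import DeepNNClassifier, WideDeepNetClassifier, WideNNClassifier
from .plink import CASE, GenotypeMatrix

__all__ = [
    "SplitSpec", "ConfusionCounts", "EvaluationReport", "stratified_split",
    "kfold_indices", "majority_vote", "RandomForestVoteClassifier",
    "compute_metrics", "confusion_counts", "roc_points", "pr_points",
    "evaluate_classifier", "run_experiment", "ExperimentResult",
]


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitSpec:
    train_fraction: float = 0.7
    seed: int = 0


def stratified_split(y: np.ndarray, spec: SplitSpec | None = None):
    """Stratified train/test indices (70/30 by default), seeded."""
    spec = spec or SplitSpec()
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("both classes need at least 2 samples")
    idx_train, idx_test = train_test_split(
        np.arange(len(y)), train_size=spec.train_fraction, stratify=y,
        random_state=spec.seed,
    )
    return np.sort(idx_train), np.sort(idx_test)


def kfold_indices(y: np.ndarray, folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Stratified, disjoint, exhaustive fold index arrays."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError("more folds than samples in the smallest class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


# ---------------------------------------------------------------------------
# Random forest with explicit majority vote
# ---------------------------------------------------------------------------

def majority_vote(votes, control_class=None):
    """Modal class of the votes; a tie falls to the control (negative) class."""
    votes = list(votes)
    if not votes:
        raise ValueError("no votes")
    counts = Counter(votes)
    top = max(counts.values())
    winners = sorted(c for c, n in counts.items() if n == top)
    if len(winners) == 1:
        return winners[0]
    if control_class is not None and control_class in winners:
        return control_class
    return winners[0]  # smallest label = negative class by our coding


class RandomForestVoteClassifier(BaseEstimator, ClassifierMixin):
    """Bagged decision trees aggregated by per-tree majority vote.

    Trees come from sklearn's forest (bootstrap sample per tree, random
    feature subset per split); aggregation is an explicit vote so the
    reported probability is the vote fraction and a 50/50 tie predicts
    the control class.
    """

    def __init__(self, n_estimators: int = 300, max_depth=None,
                 max_features="sqrt", bootstrap: bool = True,
                 random_state: int = 0):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classification only")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            max_features=self.max_features, bootstrap=self.bootstrap,
            random_state=self.random_state, n_jobs=1,
        ).fit(X, y)
        return self

    def _votes(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        X = np.asarray(X)
        # forest trees predict encoded class indices; map back to labels
        raw = np.stack([t.predict(X) for t in self.forest_.estimators_])
        return self.forest_.classes_.take(raw.astype(int))

    def predict_proba(self, X) -> np.ndarray:
        votes = self._votes(X)
        frac_pos = (votes == self.forest_.classes_[1]).mean(axis=0)
        return np.column_stack([1.0 - frac_pos, frac_pos])

    def predict(self, X) -> np.ndarray:
        frac_pos = self.predict_proba(X)[:, 1]
        # strict > 0.5 sends an exact tie to the control class
        return np.where(frac_pos > 0.5, self.classes_[1], self.classes_[0])

    @property
    def feature_importances_(self):
        check_is_fitted(self, "forest_")
        return self.forest_.feature_importances_


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class MetricSet:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: list[str]


@dataclasses.dataclass
class EvaluationReport:
    """Everything measured for one fitted model on one evaluation set."""

    counts: ConfusionCounts
    metrics: MetricSet
    roc_auc: float
    pr_auc: float
    roc_curve: tuple[np.ndarray, np.ndarray]
    pr_curve: tuple[np.ndarray, np.ndarray]
    fold_metrics: list[MetricSet] = dataclasses.field(default_factory=list)

    def summary(self) -> dict:
        return {
            "accuracy": self.metrics.accuracy,
            "precision": self.metrics.precision,
            "recall": self.metrics.recall,
            "f1": self.metrics.f1,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "confusion": dataclasses.asdict(self.counts),
        }


def confusion_counts(y_true, y_pred, positive=CASE) -> ConfusionCounts:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    pos, ppos = y_true == positive, y_pred == positive
    return ConfusionCounts(
        tp=int((pos & ppos).sum()), tn=int((~pos & ~ppos).sum()),
        fp=int((~pos & ppos).sum()), fn=int((pos & ~ppos).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F1 from confusion counts.

    A zero denominator yields 0 for that rate and is flagged in
    ``undefined`` rather than raising.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    undefined = []
    acc = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp > 0:
        prec = counts.tp / (counts.tp + counts.fp)
    else:
        prec, undefined = 0.0, undefined + ["precision"]
    if counts.tp + counts.fn > 0:
        rec = counts.tp / (counts.tp + counts.fn)
    else:
        rec, undefined = 0.0, undefined + ["recall"]
    if prec + rec > 0:
        f1 = 2.0 * prec * rec / (prec + rec)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    return MetricSet(acc, prec, rec, f1, undefined)


def roc_points(scores, y_true, positive=CASE):
    """ROC curve by threshold sweep and its trapezoidal area."""
    y = np.asarray(y_true) == positive
    if y.all() or not y.any():
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = roc_curve(y, scores)
    return fpr, tpr, float(auc(fpr, tpr))


def pr_points(scores, y_true, positive=CASE):
    """Precision-recall curve and its step-interpolated area."""
    y = np.asarray(y_true) == positive
    if y.all() or not y.any():
        raise ValueError("both classes required for a PR curve")
    prec, rec, _ = precision_recall_curve(y, scores)
    # step interpolation: sum P(recall step) heights
    area = float(-np.sum(np.diff(rec) * prec[:-1]))
    return rec, prec, area


def evaluate_classifier(model, X_test, y_test, positive=CASE) -> EvaluationReport:
    """Fit-free evaluation of a trained binary classifier."""
    y_pred = model.predict(X_test)
    scores = model.predict_proba(X_test)[:, 1]
    counts = confusion_counts(y_test, y_pred, positive)
    fpr, tpr, roc_auc = roc_points(scores, y_test, positive)
    rec, prec, pr_auc = pr_points(scores, y_test, positive)
    return EvaluationReport(
        counts, compute_metrics(counts), roc_auc, pr_auc, (fpr, tpr), (rec, prec)
    )


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ExperimentResult:
    exp: int
    feature_names: list[str]
    deep_feature_names: list[str] | None
    reports: dict[str, EvaluationReport]
    selection: dict[str, object] = dataclasses.field(default_factory=dict)


def _default_models(seed: int, nn_params: dict | None = None) -> dict:
    nn = nn_params or {}
    return {
        "rf": RandomForestVoteClassifier(n_estimators=300, random_state=seed),
        "wnn": WideNNClassifier(random_state=seed, **nn),
        "dnn": DeepNNClassifier(random_state=seed, **nn),
    }


def _cv_metrics(model, X, y, folds, seed) -> list[MetricSet]:
    out = []
    fold_sets = kfold_indices(y, folds, seed)
    all_idx = np.arange(len(y))
    for test in fold_sets:
        train = np.setdiff1d(all_idx, test)
        m = clone(model).fit(X[train], y[train])
        out.append(compute_metrics(confusion_counts(y[test], m.predict(X[test]))))
    return out


def select_features_for_experiment(
    exp: int, G_train: GenotypeMatrix, *, top_k: int = 1000,
    quartile: float = 0.25, k_neighbours: int = 6, seed: int = 0,
    boruta_trees: int = 300, boruta_iter: int = 100,
    assoc_table=None,
) -> dict:
    """Assemble the feature set of one experiment from a training cohort.

    EXP1 intersects the Boruta and PCA top quartiles; EXP2/3 use the
    Boruta / PCA quartile alone; EXP4 reuses EXP1 as the wide block and
    adds the neighbour-window one-hot union as the deep block; EXP5
    ranks one-hot features by their parent SNP's association p-value.
    """
    if exp not in (1, 2, 3, 4, 5):
        raise ValueError("experiment id must be 1..5")
    table = assoc_table if assoc_table is not None else run_association(G_train)
    top_snps = select_top_k(table, top_k)
    enc = feat.one_hot_encode(G_train, top_snps)
    parent_of = dict(zip(enc.feature_names, enc.parent_snp))
    map_order = G_train.variants["snp"].tolist()
    y = G_train.phenotype
    out = {"assoc_table": table, "top_snps": top_snps, "encoder_snps": top_snps}

    def pca_quartile():
        ranking = feat.pca_importance(enc.X, enc.feature_names)
        return feat.top_quartile(ranking, quartile, parent_of, map_order), ranking

    def boruta_quartile():
        ranking = feat.boruta_select(
            enc.X, y, enc.feature_names, n_estimators=boruta_trees,
            max_iter=boruta_iter, seed=seed,
        )
        return feat.top_quartile(ranking, quartile, parent_of, map_order), ranking

    if exp in (1, 4):
        sel_b, rank_b = boruta_quartile()
        sel_p, rank_p = pca_quartile()
        selected = feat.intersect_sets(sel_b, sel_p, parent_of, map_order)
        out.update(boruta_ranking=rank_b, pca_ranking=rank_p)
        if exp == 4:
            expansion = feat.neighbour_expand(selected, G_train, k_neighbours)
            out["expansion"] = expansion
    elif exp == 2:
        selected, rank_b = boruta_quartile()
        out["boruta_ranking"] = rank_b
    elif exp == 3:
        selected, rank_p = pca_quartile()
        out["pca_ranking"] = rank_p
    else:  # EXP5: association order mapped onto one-hot features
        p_of_snp = dict(zip(table["SNP"], table["P"]))
        order = sorted(
            range(len(enc.feature_names)),
            key=lambda i: (p_of_snp[enc.parent_snp[i]], enc.feature_names[i]),
        )
        names = [enc.feature_names[i] for i in order]
        ranking = feat.ImportanceRanking(
            "logistic",
            feat._rank_table(
                names, -np.log10([p_of_snp[parent_of[n]] for n in names])
            ),
        )
        selected = feat.top_quartile(ranking, quartile, parent_of, map_order)
        out["logistic_ranking"] = ranking
    out["selected"] = selected
    return out


def run_experiment(
    G: GenotypeMatrix, exp: int, *, top_k: int = 1000, quartile: float = 0.25,
    k_neighbours: int = 6, folds: int = 5, seed: int = 0,
    boruta_trees: int = 300, boruta_iter: int = 100,
    nn_params: dict | None = None, leakage: str = "fold-safe",
) -> ExperimentResult:
    """One full experiment: split, select, train, cross-validate, hold out.

    ``leakage="fold-safe"`` (default) fits the association screen and the
    feature selection on the 70% training partition only;
    ``"whole-dataset"`` performs selection on the full dataset before
    splitting — optimistic, but it reproduces the selection design many
    small-cohort studies report and is kept for comparability.
    """
    if leakage not in ("fold-safe", "whole-dataset"):
        raise ValueError("leakage must be 'fold-safe' or 'whole-dataset'")
    y_all = G.phenotype
    idx_train, idx_test = stratified_split(y_all, SplitSpec(seed=seed))
    G_sel = G if leakage == "whole-dataset" else G.take_samples(idx_train)

    sel = select_features_for_experiment(
        exp, G_sel, top_k=top_k, quartile=quartile, k_neighbours=k_neighbours,
        seed=seed, boruta_trees=boruta_trees, boruta_iter=boruta_iter,
    )
    selected: feat.SelectedFeatureSet = sel["selected"]
    if not selected.features:
        raise ValueError("empty feature set")

    enc_all = feat.one_hot_encode(G, sel["encoder_snps"])
    wide = enc_all.select(selected.features)
    X = wide.X.astype(np.float64)
    deep_names = None

    if exp == 4:
        expansion: feat.NeighbourExpansion = sel["expansion"]
        deep_enc = feat.one_hot_encode(G, expansion.deep_parent_snps)
        deep_names = deep_enc.feature_names
        X = np.hstack([X, deep_enc.X.astype(np.float64)])
        models = {
            "wdnn": WideDeepNetClassifier(
                n_wide=wide.X.shape[1], random_state=seed, **(nn_params or {})
            ),
            "dnn_ablation": WideDeepNetClassifier(
                n_wide=0, random_state=seed, **(nn_params or {})
            ),
        }
        # the ablation sees only the deep block
        ablation_cols = np.arange(wide.X.shape[1], X.shape[1])
    else:
        models = _default_models(seed, nn_params)
        ablation_cols = None

    y = y_all
    reports: dict[str, EvaluationReport] = {}
    for name, model in models.items():
        cols = ablation_cols if name == "dnn_ablation" else np.arange(X.shape[1])
        Xm = X[:, cols]
        fold_metrics = _cv_metrics(model, Xm[idx_train], y[idx_train], folds, seed)
        fitted = clone(model).fit(Xm[idx_train], y[idx_train])
        report = evaluate_classifier(fitted, Xm[idx_test], y[idx_test])
        report.fold_metrics = fold_metrics
        reports[name] = report
    return ExperimentResult(exp, selected.features, deep_names, reports, sel)
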