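"""Genotype feature engineering and the hybrid feature selection stage.

Genotypes are expanded to three binary indicators per SNP (one-hot,
named ``rsID_GT`` with the genotype spelled in bim alleles, e.g.
``rs2075650_AA``).  Two rankers score the encoded features: an
unsupervised PCA score (absolute sum of component rotations over the
components covering 95% of variance) and the Boruta all-relevant
wrapper (shadow features + binomial tests on a random forest).  The
hybrid selection intersects the two top quartiles; a neighbour
expansion adds the one-hot features of SNPs within k map positions of
every selected SNP for the deep half of a wide-and-deep model.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils.validation import check_is_fitted

from .plink import GenotypeMatrix

__all__ = [
    "EncodedFeatureMatrix", "one_hot_encode", "GenotypeOneHotEncoder",
    "ImportanceRanking", "SelectedFeatureSet", "NeighbourExpansion",
    "PCAImportance", "pca_importance", "BorutaSelector", "boruta_select",
    "top_quartile", "intersect_sets", "neighbour_expand",
]


@dataclasses.dataclass
class EncodedFeatureMatrix:
    """Binary one-hot genotype features with their SNP back-map."""

    X: np.ndarray  # samples x features, uint8
    feature_names: list[str]
    parent_snp: list[str]  # parent SNP id per feature

    def __post_init__(self) -> None:
        assert self.X.shape[1] == len(self.feature_names) == len(self.parent_snp)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.feature_names)

    def select(self, names: list[str]) -> "EncodedFeatureMatrix":
        pos = {n: i for i, n in enumerate(self.feature_names)}
        idx = [pos[n] for n in names]
        return EncodedFeatureMatrix(
            self.X[:, idx], [self.feature_names[i] for i in idx],
            [self.parent_snp[i] for i in idx],
        )


def one_hot_encode(G: GenotypeMatrix, snp_ids=None) -> EncodedFeatureMatrix:
    """Expand each SNP into three genotype indicators.

    Dosage 2 (hom A1) -> ``A1A1``, 1 -> ``A1A2``, 0 -> ``A2A2``; a
    missing genotype leaves all three indicators at 0.
    """
    if snp_ids is None:
        idx = np.arange(G.n_variants)
    else:
        idx = G.variant_index(snp_ids)
    names: list[str] = []
    parents: list[str] = []
    cols = np.zeros((G.n_samples, 3 * len(idx)), dtype=np.uint8)
    for k, j in enumerate(idx):
        v = G.variants.iloc[j]
        snp, a1, a2 = str(v["snp"]), str(v["a1"]), str(v["a2"])
        d = G.dosages[:, j]
        for slot, (dos, label) in enumerate(
            [(2, a1 + a1), (1, a1 + a2), (0, a2 + a2)]
        ):
            cols[:, 3 * k + slot] = d == dos
            names.append(f"{snp}_{label}")
            parents.append(snp)
    return EncodedFeatureMatrix(cols, names, parents)


class GenotypeOneHotEncoder(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper over :func:`one_hot_encode`.

    ``fit`` records the SNP list and feature names from a
    :class:`GenotypeMatrix`; ``transform`` encodes any matrix sharing
    that map into the same column order.
    """

    def __init__(self, snp_ids=None):
        self.snp_ids = snp_ids

    def fit(self, G: GenotypeMatrix, y=None):
        enc = one_hot_encode(G, self.snp_ids)
        self.feature_names_ = enc.feature_names
        self.parent_snp_ = enc.parent_snp
        return self

    def transform(self, G: GenotypeMatrix) -> np.ndarray:
        check_is_fitted(self, "feature_names_")
        return one_hot_encode(G, self.snp_ids).X

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "feature_names_")
        return np.asarray(self.feature_names_, dtype=object)


@dataclasses.dataclass
class ImportanceRanking:
    """A total order over features for one selection method."""

    method: str  # "pca" | "boruta" | "logistic"
    table: pd.DataFrame  # columns: feature, score, rank [, decision]

    def __post_init__(self) -> None:
        assert {"feature", "score", "rank"} <= set(self.table.columns)

    @property
    def features(self) -> list[str]:
        return self.table["feature"].tolist()

    def rank_of(self) -> dict[str, int]:
        return dict(zip(self.table["feature"], self.table["rank"]))


def _rank_table(names, scores, extra: dict | None = None) -> pd.DataFrame:
    df = pd.DataFrame({"feature": names, "score": scores})
    if extra:
        for k, v in extra.items():
            df[k] = v
    # non-increasing score, deterministic tie-break on the feature name
    df = df.sort_values(["score", "feature"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# PCA importance
# ---------------------------------------------------------------------------

def pca_importance(
    X: np.ndarray, feature_names, explained_variance: float = 0.95,
    weight_by_variance: bool = False,
) -> ImportanceRanking:
    """Score features by the absolute sum of principal-component rotations.

    Columns are centred; the rotation (loading) matrix comes from an SVD
    of the centred matrix.  Components are retained up to the requested
    cumulative explained variance and each feature scores the unweighted
    sum of its absolute loadings over those components (optionally
    weighted by the component variance share).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    Xc = X - X.mean(axis=0)
    if not Xc.any():
        raise ValueError("no variation")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    keep = var > 1e-12 * var[0]
    var, Vt = var[keep], Vt[keep]
    ratio = var / var.sum()
    n_keep = int(np.searchsorted(np.cumsum(ratio), explained_variance) + 1)
    n_keep = min(n_keep, len(ratio))
    V = Vt[:n_keep]  # components x features
    # deterministic sign convention (no effect on |.| sums)
    signs = np.sign(V[np.arange(n_keep), np.abs(V).argmax(axis=1)])
    V = V * signs[:, None]
    w = ratio[:n_keep][:, None] if weight_by_variance else 1.0
    scores = np.sum(np.abs(V) * w, axis=0)
    return ImportanceRanking("pca", _rank_table(list(feature_names), scores))


class PCAImportance(BaseEstimator, TransformerMixin):
    """Estimator facade for :func:`pca_importance` (fit computes ranking_)."""

    def __init__(self, explained_variance: float = 0.95,
                 weight_by_variance: bool = False, feature_names=None):
        self.explained_variance = explained_variance
        self.weight_by_variance = weight_by_variance
        self.feature_names = feature_names

    def fit(self, X, y=None):
        names = (self.feature_names if self.feature_names is not None
                 else [f"x{j}" for j in range(np.asarray(X).shape[1])])
        self.ranking_ = pca_importance(
            X, names, self.explained_variance, self.weight_by_variance
        )
        return self

    def transform(self, X):
        check_is_fitted(self, "ranking_")
        return np.asarray(X)


# ---------------------------------------------------------------------------
# Boruta
# ---------------------------------------------------------------------------

def boruta_select(
    X: np.ndarray, y: np.ndarray, feature_names, *,
    n_estimators: int = 300, max_iter: int = 100, alpha: float = 0.05,
    seed: int = 0,
) -> ImportanceRanking:
    """All-relevant feature selection against shuffled shadow probes.

    Every iteration appends a shuffled copy of each column, fits a
    random forest, and credits a real feature with a "hit" when its
    impurity importance exceeds the best shadow importance.  After each
    iteration two-sided binomial tests on the hit counts (Bonferroni
    corrected over all features) confirm clearly-relevant features and
    reject clearly-irrelevant ones; undecided features at ``max_iter``
    are reported tentative.  The reported score is the mean real-feature
    importance across iterations.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    names = list(feature_names)
    m = X.shape[1]
    rng = np.random.default_rng(seed)
    hits = np.zeros(m, dtype=int)
    imp_sum = np.zeros(m)
    decision = np.array(["tentative"] * m, dtype=object)

    for it in range(1, max_iter + 1):
        shadow = rng.permuted(X, axis=0)
        forest = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        forest.fit(np.hstack([X, shadow]), y)
        imp = forest.feature_importances_
        real, sh = imp[:m], imp[m:]
        hits += real > sh.max()
        imp_sum += real

        undecided = decision == "tentative"
        if undecided.any():
            # two-sided binomial tests vs Binomial(it, 0.5), Bonferroni over m
            p_confirm = stats.binom.sf(hits - 1, it, 0.5)
            p_reject = stats.binom.cdf(hits, it, 0.5)
            confirm = undecided & (p_confirm * m < alpha)
            reject = undecided & (p_reject * m < alpha)
            decision[confirm] = "confirmed"
            decision[reject] = "rejected"
        if not (decision == "tentative").any():
            break

    scores = imp_sum / it
    return ImportanceRanking(
        "boruta", _rank_table(names, scores, {"decision": decision})
    )


class BorutaSelector(BaseEstimator, TransformerMixin):
    """sklearn-style Boruta: ``fit`` ranks, ``transform`` keeps confirmed."""

    def __init__(self, n_estimators: int = 300, max_iter: int = 100,
                 alpha: float = 0.05, random_state: int = 0, feature_names=None):
        self.n_estimators = n_estimators
        self.max_iter = max_iter
        self.alpha = alpha
        self.random_state = random_state
        self.feature_names = feature_names

    def fit(self, X, y):
        names = (self.feature_names if self.feature_names is not None
                 else [f"x{j}" for j in range(np.asarray(X).shape[1])])
        self.ranking_ = boruta_select(
            X, y, names, n_estimators=self.n_estimators,
            max_iter=self.max_iter, alpha=self.alpha, seed=self.random_state,
        )
        tbl = self.ranking_.table.set_index("feature").loc[names]
        self.support_ = (tbl["decision"] == "confirmed").to_numpy()
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X)[:, self.support_]

    def get_support(self) -> np.ndarray:
        check_is_fitted(self, "support_")
        return self.support_


# ---------------------------------------------------------------------------
# Quartile selection / intersection / neighbour expansion
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectedFeatureSet:
    """Genotype-level features chosen by one (or two) rankers."""

    features: list[str]
    parent_snps: list[str]  # unique, in map order where known
    ranks: dict[str, float]  # feature -> rank used for ordering


@dataclasses.dataclass
class NeighbourExpansion:
    """Wide features plus the one-hot union of their neighbour windows."""

    wide: SelectedFeatureSet
    deep_feature_names: list[str]
    deep_parent_snps: list[str]
    k: int


def _parents_in_map_order(features: list[str], parent_of: dict[str, str],
                          map_order: list[str] | None) -> list[str]:
    parents = []
    seen = set()
    for f in features:
        p = parent_of[f]
        if p not in seen:
            seen.add(p)
            parents.append(p)
    if map_order is not None:
        pos = {s: i for i, s in enumerate(map_order)}
        parents.sort(key=lambda s: pos.get(s, math.inf))
    return parents


def top_quartile(
    ranking: ImportanceRanking, fraction: float = 0.25,
    parent_of: dict[str, str] | None = None, map_order: list[str] | None = None,
) -> SelectedFeatureSet:
    """The first ``ceil(fraction * m)`` features of the ranking."""
    feats = ranking.features
    if not feats:
        raise ValueError("empty ranking")
    k = math.ceil(fraction * len(feats))
    chosen = feats[:k]
    parent_of = parent_of or {f: f.rsplit("_", 1)[0] for f in chosen}
    return SelectedFeatureSet(
        chosen,
        _parents_in_map_order(chosen, parent_of, map_order),
        {f: float(i + 1) for i, f in enumerate(chosen)},
    )


def intersect_sets(
    A: SelectedFeatureSet, B: SelectedFeatureSet,
    parent_of: dict[str, str] | None = None, map_order: list[str] | None = None,
    level: str = "snp",
) -> SelectedFeatureSet:
    """Intersection of two selected sets, ordered by mean rank.

    With ``level="snp"`` (default) the intersection is taken over parent
    SNPs: a SNP survives when both rankers placed at least one of its
    genotype indicators in their top quartile, and every indicator either
    ranker selected for that SNP is kept.  The two rankers score
    different aspects of the same SNP (Boruta its phenotype relevance,
    PCA its variance structure) and routinely promote different
    indicators of one relevant SNP, so a strict feature-level
    intersection (``level="feature"``) discards most jointly supported
    SNPs; it remains available for comparison.
    """
    if level not in ("snp", "feature"):
        raise ValueError("level must be 'snp' or 'feature'")
    parent_of = parent_of or {
        f: f.rsplit("_", 1)[0] for f in set(A.features) | set(B.features)
    }
    if level == "feature":
        common = set(A.features) & set(B.features)
        mean_rank = {f: 0.5 * (A.ranks[f] + B.ranks[f]) for f in common}
    else:
        shared_parents = {parent_of[f] for f in A.features} & {
            parent_of[f] for f in B.features
        }
        common = {
            f for f in set(A.features) | set(B.features)
            if parent_of[f] in shared_parents
        }
        mean_rank = {}
        for f in common:
            ranks = [s.ranks[f] for s in (A, B) if f in s.ranks]
            mean_rank[f] = float(np.mean(ranks))
    if not common:
        warnings.warn("feature sets are disjoint; intersection is empty")
    ordered = sorted(common, key=lambda f: (mean_rank[f], f))
    return SelectedFeatureSet(
        ordered, _parents_in_map_order(ordered, parent_of, map_order), mean_rank
    )


def neighbour_expand(
    selected: SelectedFeatureSet, G: GenotypeMatrix, k: int = 6
) -> NeighbourExpansion:
    """Union of +-k map-adjacent windows around every selected parent SNP.

    Windows are taken in bim row order within the parent's chromosome and
    truncated at chromosome ends; the union is deduplicated, kept in map
    order and one-hot encoded as the deep feature space.
    """
    chrom = G.variants["chrom"].to_numpy()
    parent_idx = G.variant_index(selected.parent_snps)
    window = np.zeros(G.n_variants, dtype=bool)
    for j in parent_idx:
        lo, hi = max(0, j - k), min(G.n_variants - 1, j + k)
        same = chrom[lo : hi + 1] == chrom[j]
        window[np.arange(lo, hi + 1)[same]] = True
    union_idx = np.flatnonzero(window)
    deep_snps = G.variants["snp"].iloc[union_idx].tolist()
    enc = one_hot_encode(G, deep_snps)
    return NeighbourExpansion(selected, enc.feature_names, deep_snps, k)
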