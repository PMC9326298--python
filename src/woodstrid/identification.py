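"""Distance-stratified species identification from acoustic features.

Stridulations, described by five min-max-normalized features, are
separated into two species either without labels (k-means, fuzzy
c-means, Gaussian mixture, DBSCAN) or with labels via cross-validated
classifiers (decision tree, discriminant analyses, logistic
regression, kernel naive Bayes, SVMs with four kernels, three KNN
metrics, and bagged/random-subspace ensembles).  Performance is the
accuracy (Tp + Tn) / (Tp + Tn + Fp + Fn), in percent; unsupervised
labels are scored after aligning clusters to species by the best of
the two possible assignments.  One seed governs fold assignment,
clustering initialization and ensemble resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cluster import DBSCAN, KMeans
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import BaggingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from woodstrid.features import FeatureTable

CLUSTER_METHODS = ("kmeans", "fcm", "gmm", "dbscan")
CLASSIFIER_METHODS = (
    "tree",
    "lda",
    "qda",
    "logistic",
    "naive_bayes",
    "svm_linear",
    "svm_quadratic",
    "svm_cubic",
    "svm_rbf",
    "knn_euclidean",
    "knn_cosine",
    "knn_minkowski",
    "bag_tree",
    "subspace_lda",
    "subspace_knn",
)

#: DBSCAN label for unclustered points (scored as errors).
NOISE_LABEL = -1


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClusterConfig:
    """Settings for the unsupervised methods.

    ``min_points`` follows the published DBSCAN setting of 50, which
    presumes a dataset of several hundred calls; for smaller tables it
    is scaled to ``min(50, max(5, n // 10))`` (reported via
    ``effective_min_points``).
    """

    method: str = "kmeans"
    k: int = 2
    fuzzifier: float = 2.0
    epsilon: float = 0.25
    min_points: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in CLUSTER_METHODS:
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.k < 2 or self.fuzzifier <= 1 or self.epsilon <= 0 or self.min_points < 1:
            raise ValueError("invalid clustering hyperparameters")

    def effective_min_points(self, n: int) -> int:
        if n < 500:
            return min(self.min_points, max(5, n // 10))
        return self.min_points


@dataclass(frozen=True)
class ClassifierConfig:
    """Settings for the supervised battery (fivefold stratified CV)."""

    method: str = "tree"
    folds: int = 5
    seed: int = 0
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in CLASSIFIER_METHODS:
            raise ValueError(f"unknown classifier method {self.method!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def accuracy(conf: ConfusionCounts) -> float:
    """Percent accuracy ``100 * (tp + tn) / (tp + tn + fp + fn)``."""
    if conf.total == 0:
        raise ValueError("cannot compute accuracy of zero counts")
    return 100.0 * (conf.tp + conf.tn) / conf.total


class KernelNaiveBayes(BaseEstimator, ClassifierMixin):
    """Naive Bayes with a Gaussian kernel density estimate per feature.

    Class-conditional densities are modelled per feature with a 1-D
    Gaussian KDE (Scott's bandwidth) under the naive independence
    assumption, instead of the parametric Gaussian assumption.
    """

    def __init__(self, jitter: float = 1e-9):
        self.jitter = jitter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(0)
        self._kdes = {}
        self._priors = {}
        for cls in self.classes_:
            Xc = X[y == cls]
            self._priors[cls] = len(Xc) / len(X)
            kdes = []
            for j in range(X.shape[1]):
                col = Xc[:, j]
                if np.ptp(col) == 0:  # KDE needs spread; degenerate column
                    col = col + rng.normal(0, self.jitter, size=col.size)
                kdes.append(gaussian_kde(col))
            self._kdes[cls] = kdes
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        scores = np.empty((X.shape[0], len(self.classes_)))
        for i, cls in enumerate(self.classes_):
            logp = np.log(self._priors[cls])
            dens = np.zeros(X.shape[0])
            for j, kde in enumerate(self._kdes[cls]):
                dens += np.log(np.maximum(kde(X[:, j]), 1e-300))
            scores[:, i] = logp + dens
        return self.classes_[np.argmax(scores, axis=1)]


def _fuzzy_c_means(
    X: np.ndarray,
    k: int,
    m: float,
    seed: int,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fuzzy c-means memberships, defuzzified by maximal membership."""
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    u = rng.random((n, k))
    u /= u.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ X) / um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    return np.argmax(u, axis=1)


def cluster_features(table: FeatureTable, cfg: ClusterConfig) -> np.ndarray:
    """Cluster normalized feature rows; returns one integer label per row.

    DBSCAN may label points as noise (:data:`NOISE_LABEL`); the other
    methods always return ``k`` clusters.  Deterministic given
    ``cfg.seed``.
    """
    if not table.normalized:
        raise ValueError("cluster_features expects a normalized table")
    X = table.feature_matrix()
    n = X.shape[0]
    if cfg.method != "dbscan" and n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} rows, got {n}")
    if cfg.method == "kmeans":
        km = KMeans(n_clusters=cfg.k, n_init=10, random_state=cfg.seed)
        return km.fit_predict(X)
    if cfg.method == "fcm":
        return _fuzzy_c_means(X, cfg.k, cfg.fuzzifier, cfg.seed)
    if cfg.method == "gmm":
        gm = GaussianMixture(
            n_components=cfg.k, n_init=3, random_state=cfg.seed, covariance_type="full"
        )
        return gm.fit_predict(X)
    labels = DBSCAN(
        eps=cfg.epsilon, min_samples=cfg.effective_min_points(n)
    ).fit_predict(X)
    return labels


def align_cluster_labels(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Score cluster labels against two-species truth by best alignment.

    Truth must be binary (0/1 after factorization).  For two non-noise
    clusters the assignment maximizing accuracy over the two
    permutations is used; noise points always count as errors.  If more
    than two clusters were found, each cluster is independently mapped
    to its accuracy-maximizing species (the best of all cluster-to-
    2-class maps).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    t_codes, t_classes = pd.factorize(truth, sort=True)
    if len(t_classes) != 2:
        raise ValueError("truth must contain exactly 2 classes")

    cluster_ids = [c for c in np.unique(pred) if c != NOISE_LABEL]
    mapped = np.full(pred.shape, -1)  # -1 = unassigned/noise -> error
    if len(cluster_ids) <= 2:
        best = None
        for flip in (False, True):
            trial = np.full(pred.shape, -1)
            for idx, cid in enumerate(cluster_ids):
                trial[pred == cid] = (idx ^ flip) % 2
            correct = int(np.sum(trial == t_codes))
            if best is None or correct > best[0]:
                best = (correct, trial)
        mapped = best[1]
    else:
        for cid in cluster_ids:
            mask = pred == cid
            counts = [int(np.sum(t_codes[mask] == s)) for s in (0, 1)]
            mapped[mask] = int(np.argmax(counts))

    pos = 1  # second factorized class is "positive"
    # noise (mapped == -1) is an incorrect prediction on either class
    tp = int(np.sum((mapped == pos) & (t_codes == pos)))
    tn = int(np.sum((mapped == 0) & (t_codes == 0)))
    fp = int(np.sum((mapped != 0) & (t_codes == 0)))
    fn = int(np.sum((mapped != pos) & (t_codes == pos)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def make_classifier(cfg: ClassifierConfig):
    """Instantiate the scikit-learn estimator for a battery method."""
    seed = cfg.seed
    hp = cfg.hyperparams
    # "max splits 4" caps the tree at 5 leaves; the bagged tree's 712
    # splits cap at 713 leaves.
    if cfg.method == "tree":
        return DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=hp.get("max_splits", 4) + 1,
            random_state=seed,
        )
    if cfg.method == "lda":
        return LinearDiscriminantAnalysis()
    if cfg.method == "qda":
        return QuadraticDiscriminantAnalysis(reg_param=hp.get("reg_param", 1e-9))
    if cfg.method == "logistic":
        return LogisticRegression(C=np.inf, max_iter=1000)  # unregularized
    if cfg.method == "naive_bayes":
        return KernelNaiveBayes()
    if cfg.method == "svm_linear":
        return SVC(kernel="linear", random_state=seed)
    if cfg.method == "svm_quadratic":
        return SVC(kernel="poly", degree=2, random_state=seed)
    if cfg.method == "svm_cubic":
        return SVC(kernel="poly", degree=3, random_state=seed)
    if cfg.method == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed)
    if cfg.method == "knn_euclidean":
        return KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 10))
    if cfg.method == "knn_cosine":
        return KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 10), metric="cosine"
        )
    if cfg.method == "knn_minkowski":
        # conventional "cubic" Minkowski exponent, distinct from Euclidean
        return KNeighborsClassifier(
            n_neighbors=hp.get("n_neighbors", 10), metric="minkowski",
            p=hp.get("p", 3),
        )
    if cfg.method == "bag_tree":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(
                criterion="gini",
                max_leaf_nodes=hp.get("max_splits", 712) + 1,
                random_state=seed,
            ),
            n_estimators=hp.get("n_learners", 30),
            random_state=seed,
        )
    if cfg.method in ("subspace_lda", "subspace_knn"):
        base = (
            LinearDiscriminantAnalysis()
            if cfg.method == "subspace_lda"
            else KNeighborsClassifier(n_neighbors=hp.get("n_neighbors", 10))
        )
        return BaggingClassifier(
            estimator=base,
            n_estimators=hp.get("n_learners", 30),
            max_features=hp.get("subspace_dim", 3),
            bootstrap=False,
            bootstrap_features=False,
            random_state=seed,
        )
    raise ValueError(f"unknown classifier method {cfg.method!r}")


def classify_cv(
    table: FeatureTable,
    cfg: ClassifierConfig,
    label_column: str = "species",
    feature_columns: tuple[str, ...] | None = None,
) -> tuple[float, list[float]]:
    """Stratified k-fold cross-validated accuracy of one classifier.

    Returns ``(mean accuracy %, per-fold accuracies %)``; deterministic
    given ``cfg.seed``.  ``feature_columns`` restricts the input (e.g.
    duration only) for feature-ablation comparisons.
    """
    if not table.normalized:
        raise ValueError("classify_cv expects a normalized table")
    y = table.data[label_column].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both species must be present")
    if feature_columns is None:
        X = table.feature_matrix()
    else:
        X = table.data.loc[:, list(feature_columns)].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    fold_acc = []
    for train_idx, test_idx in skf.split(X, y):
        clf = make_classifier(cfg)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        fold_acc.append(100.0 * float(np.mean(pred == y[test_idx])))
    return float(np.mean(fold_acc)), fold_acc


def evaluate_by_distance(
    tables: dict[float, FeatureTable],
    cluster_methods: tuple[str, ...] = CLUSTER_METHODS,
    classifier_methods: tuple[str, ...] = CLASSIFIER_METHODS,
    seed: int = 0,
    label_column: str = "species",
) -> pd.DataFrame:
    """Accuracy of every algorithm at every distance.

    ``tables`` maps distance (cm) to a *normalized* two-species feature
    table.  Returns a DataFrame with algorithms as rows and distances
    as columns (accuracy %); a distance whose table has a single
    species yields NaN for that column.
    """
    distances = sorted(tables)
    algorithms = list(cluster_methods) + list(classifier_methods)
    out = pd.DataFrame(index=algorithms, columns=distances, dtype=float)
    for z in distances:
        table = tables[z]
        y = table.data[label_column].to_numpy()
        if len(np.unique(y)) < 2:
            continue  # flagged by the NaN column
        for method in cluster_methods:
            labels = cluster_features(table, ClusterConfig(method=method, seed=seed))
            out.loc[method, z] = accuracy(align_cluster_labels(labels, y))
        for method in classifier_methods:
            acc, _ = classify_cv(
                table, ClassifierConfig(method=method, seed=seed),
                label_column=label_column,
            )
            out.loc[method, z] = acc
    return out


def embed_2d(table: FeatureTable, seed: int = 0, perplexity: float | None = None):
    """2-D t-SNE ordination of normalized features (visualization only)."""
    X = table.feature_matrix()
    n = X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 rows to embed")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(
        n_components=2, random_state=seed, perplexity=perplexity, init="pca"
    )
    return tsne.fit_transform(X)
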