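"""Case subtyping on eigengene profiles.

Cases are clustered on their submodule eigengene vectors with four methods
(k-means, Ward, UPGMA, WPGMA). The number of clusters is chosen by majority
vote of nine cluster-validity indices across methods; the method is then
chosen by maximal mean silhouette width. Subtype centroids define the
"subtype specificity metric": every decedent's Euclidean distance to each
centroid, used downstream as a quantitative trait. Covariate balance across
subtypes is checked with chi-square (categorical) and Student's t
(quantitative) tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

METHODS = ("kmeans", "ward", "upgma", "wpgma")
_LINKAGE = {"ward": "ward", "upgma": "average", "wpgma": "weighted"}

# index name -> decision rule used by select_k
INDEX_RULES = {
    "calinski_harabasz": "max",
    "silhouette": "max",
    "davies_bouldin": "min",
    "dunn": "max",
    "c_index": "min",
    "gap": "gap",
    "hartigan": "hartigan",
    "krzanowski_lai": "kl",
    "ball_hall": "ball_hall",
}
DEFAULT_INDICES = tuple(INDEX_RULES)
GAP_B = 50  # uniform-box reference datasets for the gap statistic
HARTIGAN_THRESHOLD = 10.0


@dataclass
class SubtypeModel:
    method: str
    k: int
    case_labels: pd.Series  # case sample -> subtype id (1..k)
    centroids: pd.DataFrame  # k x n_submodules
    mean_silhouette: float
    votes: dict[tuple[str, str], int]


def cluster(
    eigengenes: pd.DataFrame, method: str, k: int, seed: int = 0
) -> np.ndarray:
    """Partition samples (rows) into k clusters; labels are 1..k.

    k-means uses k-means++ with 50 restarts under ``seed``; the hierarchical
    methods cut the dendrogram into exactly k groups. Euclidean throughout.
    """
    X = eigengenes.to_numpy(dtype=float)
    if k < 1 or k > len(X):
        raise ValueError(f"k={k} out of range for {len(X)} samples")
    if k == 1:
        return np.ones(len(X), dtype=int)
    if method == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=seed)
        return km.fit_predict(X) + 1
    if method in _LINKAGE:
        Z = linkage(X, method=_LINKAGE[method])
        return fcluster(Z, t=k, criterion="maxclust")
    raise ValueError(f"unknown clustering method {method!r}")


# ---------------------------------------------------------------------------
# validity indices
# ---------------------------------------------------------------------------


def _silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width s_i = (b_i - a_i) / max(a_i, b_i).

    a_i is the mean distance to the point's own cluster (excluding itself),
    b_i the smallest mean distance to another cluster; singletons score 0.
    """
    D = cdist(X, X)
    labs = np.unique(labels)
    if len(labs) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    n = len(X)
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == lab].mean() for lab in labs if lab != labels[i])
        s[i] = (b - a) / max(a, b)
    return float(s.mean())


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to centroids."""
    w = 0.0
    for lab in np.unique(labels):
        pts = X[labels == lab]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def _davies_bouldin(X: np.ndarray, labels: np.ndarray) -> float:
    labs = np.unique(labels)
    cents = np.array([X[labels == lab].mean(axis=0) for lab in labs])
    scatters = np.array(
        [
            np.mean(np.linalg.norm(X[labels == lab] - cents[i], axis=1))
            for i, lab in enumerate(labs)
        ]
    )
    db = 0.0
    for i in range(len(labs)):
        worst = -np.inf
        for j in range(len(labs)):
            if i == j:
                continue
            d = np.linalg.norm(cents[i] - cents[j])
            r = (scatters[i] + scatters[j]) / d if d > 0 else np.inf
            worst = max(worst, r)
        db += worst
    return db / len(labs)


def _dunn(X: np.ndarray, labels: np.ndarray) -> float:
    labs = np.unique(labels)
    max_diam = 0.0
    for lab in labs:
        pts = X[labels == lab]
        if len(pts) > 1:
            max_diam = max(max_diam, pdist(pts).max())
    min_sep = np.inf
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            min_sep = min(
                min_sep, cdist(X[labels == labs[i]], X[labels == labs[j]]).min()
            )
    if max_diam == 0:
        return np.inf
    return min_sep / max_diam


def _c_index(X: np.ndarray, labels: np.ndarray) -> float:
    d = pdist(X)
    n = len(X)
    within_mask = pdist(labels[:, None], metric=lambda a, b: float(a[0] == b[0]))
    nw = int(within_mask.sum())
    if nw == 0:
        return 0.0
    s_w = d[within_mask.astype(bool)].sum()
    d_sorted = np.sort(d)
    s_min = d_sorted[:nw].sum()
    s_max = d_sorted[-nw:].sum()
    if s_max == s_min:
        return 0.0
    return (s_w - s_min) / (s_max - s_min)


def _gap(
    X: np.ndarray,
    labels: np.ndarray,
    method: str = "kmeans",
    seed: int = 0,
    return_se: bool = False,
):
    """Tibshirani gap statistic with B uniform-box references."""
    k = len(np.unique(labels))
    rng = np.random.default_rng(seed)
    log_w = np.log(max(_wss(X, labels), 1e-300))
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref_logs = np.empty(GAP_B)
    for b in range(GAP_B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_labels = _cheap_cluster(ref, method, k, seed=int(rng.integers(2**31)))
        ref_logs[b] = np.log(max(_wss(ref, ref_labels), 1e-300))
    gap = ref_logs.mean() - log_w
    se = ref_logs.std(ddof=0) * np.sqrt(1 + 1 / GAP_B)
    return (gap, se) if return_se else gap


def _cheap_cluster(X: np.ndarray, method: str, k: int, seed: int = 0) -> np.ndarray:
    """Single-restart clustering used only for gap-statistic references."""
    if k == 1:
        return np.ones(len(X), dtype=int)
    if method == "kmeans":
        km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
        return km.fit_predict(X) + 1
    Z = linkage(X, method=_LINKAGE[method])
    return fcluster(Z, t=k, criterion="maxclust")


def cluster_index(
    eigengenes: pd.DataFrame,
    labels: np.ndarray,
    index_name: str,
    seed: int = 0,
    method: str = "kmeans",
) -> float:
    """Compute one named validity index for a given partition.

    ``gap`` draws its uniform references under ``seed`` and clusters them
    with ``method``; ``ball_hall`` is W_k / k. Sequence-based decision rules
    (gap, hartigan, krzanowski_lai, ball_hall elbow) are applied by
    :func:`select_k` over the k range.
    """
    X = eigengenes.to_numpy(dtype=float)
    labels = np.asarray(labels)
    if index_name not in INDEX_RULES:
        raise ValueError(f"unknown index {index_name!r}")
    k = len(np.unique(labels))
    if index_name == "calinski_harabasz":
        return float(calinski_harabasz_score(X, labels))
    if index_name == "silhouette":
        return float(_silhouette(X, labels))
    if index_name == "davies_bouldin":
        return float(_davies_bouldin(X, labels))
    if index_name == "dunn":
        return float(_dunn(X, labels))
    if index_name == "c_index":
        return float(_c_index(X, labels))
    if index_name == "gap":
        return float(_gap(X, labels, method=method, seed=seed))
    if index_name == "hartigan":
        raise ValueError("hartigan is a sequence rule; use select_k")
    if index_name == "krzanowski_lai":
        raise ValueError("krzanowski_lai is a sequence rule; use select_k")
    if index_name == "ball_hall":
        return float(_wss(X, labels) / k)
    raise AssertionError


def _votes_for_method(
    X: np.ndarray,
    method: str,
    k_range: range,
    indices: tuple[str, ...],
    seed: int,
) -> dict[str, int]:
    """One vote per index for one clustering method."""
    k_lo, k_hi = k_range.start, k_range.stop - 1
    ks_ext = list(range(max(1, k_lo - 1), k_hi + 2))
    labels_by_k = {k: cluster(pd.DataFrame(X), method, k, seed) for k in ks_ext}
    W = {k: _wss(X, labels_by_k[k]) for k in ks_ext}
    n, p = X.shape
    votes: dict[str, int] = {}
    df = pd.DataFrame(X)
    for name in indices:
        rule = INDEX_RULES[name]
        if rule in ("max", "min"):
            scores = {
                k: cluster_index(df, labels_by_k[k], name, seed=seed, method=method)
                for k in k_range
            }
            pick = max if rule == "max" else min
            best = pick(scores, key=lambda k: (scores[k], -k) if rule == "max" else (scores[k], k))
            # ties toward smaller k
            target = scores[best]
            best = min(k for k, v in scores.items() if v == target)
            votes[name] = best
        elif rule == "gap":
            gaps, ses = {}, {}
            for k in range(k_lo, k_hi + 2):
                if k not in labels_by_k:
                    continue
                g, s = _gap(X, labels_by_k[k], method=method, seed=seed + k, return_se=True)
                gaps[k], ses[k] = g, s
            chosen = None
            for k in k_range:
                if k + 1 in gaps and gaps[k] >= gaps[k + 1] - ses[k + 1]:
                    chosen = k
                    break
            if chosen is None:
                chosen = max(k_range, key=lambda k: (gaps[k], -k))
            votes[name] = chosen
        elif rule == "hartigan":
            chosen = None
            for k in k_range:
                if W[k + 1] <= 0:
                    continue
                h = (W[k] / W[k + 1] - 1.0) * (n - k - 1)
                if h <= HARTIGAN_THRESHOLD:
                    chosen = k
                    break
            votes[name] = chosen if chosen is not None else k_hi
        elif rule == "kl":
            def diff(k: int) -> float:
                return (k - 1) ** (2 / p) * W[k - 1] - k ** (2 / p) * W[k]

            scores = {}
            for k in k_range:
                d_next = diff(k + 1)
                scores[k] = abs(diff(k)) / abs(d_next) if d_next != 0 else np.inf
            best_val = max(scores.values())
            votes[name] = min(k for k, v in scores.items() if v == best_val)
        elif rule == "ball_hall":
            # largest drop of W_k / k relative to the previous k
            drops = {k: W[k - 1] / (k - 1) - W[k] / k if k > 1 else -np.inf for k in k_range}
            best_val = max(drops.values())
            votes[name] = min(k for k, v in drops.items() if v == best_val)
        else:
            raise AssertionError(rule)
    return votes


def select_k(
    eigengenes_cases: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
    k_range: range = range(2, 7),
    indices: tuple[str, ...] = DEFAULT_INDICES,
    seed: int = 0,
) -> tuple[int, dict[tuple[str, str], int]]:
    """Majority-rule cluster-number selection across methods and indices.

    Every (method, index) pair casts one vote for a k in ``k_range``; the
    modal k wins, ties broken toward smaller k.
    """
    if len(indices) < 2:
        raise ValueError("need at least 2 indices to poll")
    X = eigengenes_cases.to_numpy(dtype=float)
    votes: dict[tuple[str, str], int] = {}
    for method in methods:
        mv = _votes_for_method(X, method, k_range, tuple(indices), seed)
        for name, k in mv.items():
            votes[(method, name)] = k
    counts = pd.Series(list(votes.values())).value_counts()
    top = counts.max()
    k_star = int(min(k for k, c in counts.items() if c == top))
    return k_star, votes


def select_method(
    eigengenes_cases: pd.DataFrame,
    k_star: int,
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    votes: dict[tuple[str, str], int] | None = None,
    min_cluster_frac: float = 0.05,
) -> SubtypeModel:
    """Fit every method at k_star; keep the one with maximal mean silhouette.

    Ties break by fixed precedence: kmeans, ward, upgma, wpgma. Partitions
    with a cluster smaller than ``min_cluster_frac`` of the cases are set
    aside first — average-linkage methods can win the silhouette contest
    with a near-singleton outlier split, and a subtype holding one decedent
    supports neither mapping nor differential expression. If every method
    produces such a partition the guard is waived.
    """
    X = eigengenes_cases.to_numpy(dtype=float)
    floor = max(2, int(np.ceil(min_cluster_frac * len(X))))
    fits = []
    for method in methods:
        labels = cluster(eigengenes_cases, method, k_star, seed)
        sil = float(_silhouette(X, labels))
        smallest = np.bincount(labels).astype(int)[1:].min()
        fits.append((sil, method, labels, smallest))
    eligible = [f for f in fits if f[3] >= floor] or fits
    best = None
    for sil_m, method_m, labels_m, _ in eligible:
        if best is None or sil_m > best[0] + 1e-12:
            best = (sil_m, method_m, labels_m)
    sil, method, labels = best
    case_labels = pd.Series(labels, index=eigengenes_cases.index, name="subtype")
    centroids = (
        eigengenes_cases.groupby(case_labels).mean().sort_index()
    )
    return SubtypeModel(
        method=method,
        k=k_star,
        case_labels=case_labels,
        centroids=centroids,
        mean_silhouette=sil,
        votes=votes or {},
    )


def fit_subtypes(
    eigengenes_cases: pd.DataFrame,
    methods: tuple[str, ...] = METHODS,
    k_range: range = range(2, 7),
    indices: tuple[str, ...] = DEFAULT_INDICES,
    seed: int = 0,
) -> SubtypeModel:
    """select_k then select_method in one call."""
    k_star, votes = select_k(eigengenes_cases, methods, k_range, indices, seed)
    return select_method(eigengenes_cases, k_star, methods, seed, votes)


def specificity_metric(
    eigengenes_all: pd.DataFrame, model: SubtypeModel
) -> pd.DataFrame:
    """Euclidean distance of every decedent to each subtype centroid.

    Computed for all samples (cases, controls, others); one column per
    subtype, used downstream as separate quantitative traits.
    """
    if list(eigengenes_all.columns) != list(model.centroids.columns):
        raise ValueError("eigengene columns do not match centroid columns")
    D = cdist(
        eigengenes_all.to_numpy(dtype=float),
        model.centroids.to_numpy(dtype=float),
    )
    return pd.DataFrame(
        D,
        index=eigengenes_all.index,
        columns=[f"subtype_{j}" for j in model.centroids.index],
    )


def covariate_balance(
    model: SubtypeModel,
    cov: pd.DataFrame,
    categorical_vars: list[str],
    quantitative_vars: list[str],
) -> pd.DataFrame:
    """Chi-square / Student's-t covariate balance tests across subtypes.

    Categorical variables get a subtype x category chi-square (skipped with a
    reason when any expected count is zero); quantitative variables get
    two-sample t-tests for k=2 and all pairwise t-tests otherwise.
    """
    cov = cov.loc[model.case_labels.index]
    rows = []
    for var in categorical_vars:
        table = pd.crosstab(model.case_labels, cov[var])
        exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.values.sum()
        if (exp == 0).any():
            rows.append((var, "chi_square", np.nan, np.nan, "zero expected cell"))
            continue
        chi2, p, _, _ = stats.chi2_contingency(table.values, correction=False)
        rows.append((var, "chi_square", chi2, p, ""))
    subtypes = sorted(model.case_labels.unique())
    for var in quantitative_vars:
        for i in range(len(subtypes)):
            for j in range(i + 1, len(subtypes)):
                a = cov.loc[model.case_labels == subtypes[i], var].astype(float)
                b = cov.loc[model.case_labels == subtypes[j], var].astype(float)
                t, p = stats.ttest_ind(a, b, equal_var=True)
                name = var if len(subtypes) == 2 else f"{var}[{subtypes[i]}v{subtypes[j]}]"
                rows.append((name, "t_test", t, p, ""))
    return pd.DataFrame(
        rows, columns=["variable", "test", "statistic", "p", "note"]
    )
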