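"""Iterative refinement of coarse co-expression modules into submodules.

Within each coarse module: build a soft-thresholded correlation network,
derive the topological overlap matrix (TOM), cluster genes by average-linkage
on 1-TOM with a static height cut, and repeatedly prune members whose
eigengene connectivity (kME, the correlation of a gene with its set's
eigengene) falls below ``kme_min`` until membership converges. A final pass
tries to reclassify residual genes into the submodule where their |kME|
clears the threshold. Eigengenes — first principal components of the
standardized member expression, unit variance, sign-aligned with the mean
member profile — are the composite quantitative phenotypes mapped downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import RunConfig

MAX_ITER = 20
CUT_HEIGHT_FRACTION = 0.99


@dataclass
class Submodule:
    """A refined gene set with its eigengene and member connectivities."""

    label: str
    genes: frozenset[str]
    eigengene: pd.Series  # per-sample, unit variance
    kme: pd.Series  # per member gene, in [-1, 1]
    converged: bool = True

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)


def soft_adjacency(
    expr_std: pd.DataFrame, beta: float, signed: bool = False
) -> np.ndarray:
    """Unsigned soft-threshold adjacency a_ij = |cor(x_i, x_j)|^beta.

    In signed mode a_ij = ((1 + cor)/2)^beta. Diagonal is 1.
    """
    if beta < 1:
        raise ValueError("soft power must be >= 1")
    C = np.corrcoef(expr_std.to_numpy(dtype=float))
    C = np.clip(C, -1.0, 1.0)
    A = ((1 + C) / 2) ** beta if signed else np.abs(C) ** beta
    np.fill_diagonal(A, 1.0)
    return A


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij).

    l_ij sums shared-neighbour adjacency products excluding i and j;
    k_i is the connectivity excluding the self-loop. Diagonal is 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    A = A.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=0)
    # with a_ii = 0, (A@A)_ij = sum_{u != i,j} a_iu a_uj exactly
    L = A @ A
    num = L + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip((tom + tom.T) / 2, 0.0, 1.0)


def detect_gene_sets(
    tom: np.ndarray, gene_ids: list[str], min_size: int
) -> tuple[list[frozenset[str]], frozenset[str]]:
    """Average-linkage clustering on 1-TOM with a static height cut.

    The dendrogram is cut at 0.99 x the maximum merge height; clusters
    smaller than ``min_size`` dissolve into the residual pool. Returned sets
    are ordered by decreasing size, ties by smallest member id.
    """
    n = len(gene_ids)
    if n < 2:
        return [], frozenset(gene_ids)
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    Z = linkage(squareform(diss, checks=False), method="average")
    cut = CUT_HEIGHT_FRACTION * Z[:, 2].max() if Z[:, 2].max() > 0 else 0.0
    labels = fcluster(Z, t=cut, criterion="distance")
    sets: list[frozenset[str]] = []
    residual: set[str] = set()
    ids = np.asarray(gene_ids)
    for lab in np.unique(labels):
        members = frozenset(ids[labels == lab])
        if len(members) >= min_size:
            sets.append(members)
        else:
            residual.update(members)
    if not sets and n >= min_size:
        # the height cut always severs the top merge, so a single homogeneous
        # set would otherwise dissolve; offer the whole set and let kME
        # pruning judge it
        return [frozenset(gene_ids)], frozenset()
    sets.sort(key=lambda s: (-len(s), min(s)))
    return sets, frozenset(residual)


def eigengene(expr_std_subset: pd.DataFrame) -> pd.Series:
    """First principal component of a gene x sample standardized block.

    Returned as per-sample scores rescaled to unit variance, with sign
    aligned so the correlation with the mean member profile is nonnegative.
    """
    X = expr_std_subset.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("eigengene needs at least 2 genes")
    if X.shape[1] < 3:
        raise ValueError("eigengene needs at least 3 samples")
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    scores = vt[0]
    scores = scores / scores.std(ddof=1)
    mean_profile = X.mean(axis=0)
    if np.dot(scores, mean_profile - mean_profile.mean()) < 0:
        scores = -scores
    return pd.Series(scores, index=expr_std_subset.columns)


def kme(expr_std: pd.DataFrame, eg: pd.Series) -> pd.Series:
    """Eigengene connectivity: per-gene Pearson correlation with ``eg``."""
    e = eg.to_numpy(dtype=float)
    if e.std(ddof=0) == 0:
        raise ValueError("eigengene has zero variance")
    X = expr_std.loc[:, eg.index].to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    ec = e - e.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (ec**2).sum())
    vals = np.where(denom > 0, Xc @ ec / denom, 0.0)
    return pd.Series(vals, index=expr_std.index)


def _prune_stable(
    expr_std: pd.DataFrame, genes: frozenset[str], kme_min: float
) -> tuple[frozenset[str], pd.Series | None, pd.Series | None]:
    """Prune |kME| < kme_min, recomputing the eigengene, until stable."""
    members = set(genes)
    for _ in range(MAX_ITER):
        if len(members) < 2:
            return frozenset(), None, None
        sub = expr_std.loc[sorted(members)]
        eg = eigengene(sub)
        k = kme(sub, eg)
        keep = set(k.index[k.abs() >= kme_min])
        if keep == members:
            return frozenset(members), eg, k
        members = keep
    return frozenset(members), None, None


def iterative_refine(
    expr_module_std: pd.DataFrame,
    config: RunConfig,
    parent_label: str = "module",
) -> tuple[list[Submodule], frozenset[str]]:
    """Refine one coarse module into tight submodules.

    Loop: detect gene sets on the TOM of the surviving genes; prune each set
    by |kME| >= kme_min (eigengene recomputed after each prune); repeat until
    the partition is unchanged or 20 iterations. Residual genes are then
    reclassified into the submodule maximizing |kME| where that value clears
    the threshold, minimum size is enforced, and submodules are labelled
    ``parent_ordinal`` by decreasing size. Never-assigned genes are returned
    as dropped.
    """
    all_genes = list(expr_module_std.index)
    active = set(all_genes)
    prev_partition: frozenset[frozenset[str]] | None = None
    sets: list[frozenset[str]] = []
    converged = False
    for _ in range(MAX_ITER):
        if len(active) < 2:
            sets = []
            converged = True
            break
        sub_expr = expr_module_std.loc[sorted(active)]
        adj = soft_adjacency(sub_expr, config.soft_power, config.network_signed)
        tom = topological_overlap(adj)
        raw_sets, _ = detect_gene_sets(tom, list(sub_expr.index), config.min_module_size)
        pruned = []
        for s in raw_sets:
            kept, _, _ = _prune_stable(expr_module_std, s, config.kme_min)
            if len(kept) >= config.min_module_size:
                pruned.append(kept)
        partition = frozenset(pruned)
        if partition == prev_partition:
            converged = True
            sets = pruned
            break
        prev_partition = partition
        sets = pruned
        active = set().union(*pruned) if pruned else set()

    # reclassify residual genes by best |kME|
    if sets:
        assigned = set().union(*sets)
        residual = [g for g in all_genes if g not in assigned]
        if residual:
            egs = [eigengene(expr_module_std.loc[sorted(s)]) for s in sets]
            kmat = np.column_stack(
                [kme(expr_module_std.loc[residual], eg) for eg in egs]
            )
            best = np.argmax(np.abs(kmat), axis=1)
            grown = [set(s) for s in sets]
            for gi, g in enumerate(residual):
                if abs(kmat[gi, best[gi]]) >= config.kme_min:
                    grown[best[gi]].add(g)
            # re-prune to restore the kME invariant after growth
            final_sets = []
            for s in grown:
                kept, _, _ = _prune_stable(
                    expr_module_std, frozenset(s), config.kme_min
                )
                if len(kept) >= config.min_module_size:
                    final_sets.append(kept)
            sets = final_sets

    sets = sorted(sets, key=lambda s: (-len(s), min(s) if s else ""))
    submodules = []
    for rank, s in enumerate(sets, start=1):
        sub = expr_module_std.loc[sorted(s)]
        eg = eigengene(sub)
        submodules.append(
            Submodule(
                label=f"{parent_label}_{rank}",
                genes=s,
                eigengene=eg,
                kme=kme(sub, eg),
                converged=converged,
            )
        )
    assigned = set().union(*[s.genes for s in submodules]) if submodules else set()
    dropped = frozenset(g for g in all_genes if g not in assigned)
    return submodules, dropped


def refine_all_modules(
    expr_std: pd.DataFrame, modules: pd.Series, config: RunConfig
) -> tuple[list[Submodule], dict[str, frozenset[str]]]:
    """Run iterative refinement independently per coarse module."""
    submodules: list[Submodule] = []
    dropped: dict[str, frozenset[str]] = {}
    for label in sorted(modules.unique()):
        genes = [g for g in expr_std.index if modules.get(g) == label]
        if len(genes) < 2:
            dropped[label] = frozenset(genes)
            continue
        subs, drop = iterative_refine(expr_std.loc[genes], config, parent_label=label)
        submodules.extend(subs)
        dropped[label] = drop
    return submodules, dropped


def eigengene_matrix(
    expr_std: pd.DataFrame, submodules: list[Submodule]
) -> pd.DataFrame:
    """Samples x submodules eigengene matrix, columns ordered by label."""
    for sub in submodules:
        missing = [g for g in sub.genes if g not in expr_std.index]
        if missing:
            raise KeyError(
                f"submodule {sub.label} genes absent from expression: {missing}"
            )
    cols = {}
    for sub in sorted(submodules, key=lambda s: s.label):
        cols[sub.label] = eigengene(expr_std.loc[sorted(sub.genes)])
    E = pd.DataFrame(cols)
    E.index.name = "sample_id"
    return E
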