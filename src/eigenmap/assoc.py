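"""Variance-component mixed-model association for eigengene traits.

The model is y = X b + g + e with g ~ N(0, sigma_g^2 K) and
e ~ N(0, sigma_e^2 I). The null variance components are estimated once by
REML, profiling delta = sigma_e^2 / sigma_g^2 through a single spectral
decomposition of the projected kinship (the EMMA form), on a log10 grid over
[-5, 5] refined by bounded scalar optimization. Per-variant tests then fix
the variance components (the EMMAX approximation): trait, covariates and
dosages are whitened by V^{-1/2} and an ordinary t-test is applied to the
dosage coefficient. Genomic inflation (lambda_GC), suggestive/significant
hit classification, positional locus clumping, cross-region replication,
GWAS-catalog overlap and the phenotype->locus network round out the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import cdist

from .io import GenotypeMatrix

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45493642311957...


@dataclass
class NullModelFit:
    """REML variance components plus the cached spectral data for the scan."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    eigenvalues: np.ndarray  # of K (full), for V^{-1/2}
    eigenvectors: np.ndarray
    boundary: bool = False


def kinship(genotypes: GenotypeMatrix | np.ndarray, method: str = "ibs") -> np.ndarray:
    """Pairwise relatedness from dosages.

    ``ibs``: K_ij = mean over variants of (2 - |g_i - g_j|) / 2 (identity by
    state; diagonal 1). ``grm``: K = Z Z^T / L with Z the per-variant
    standardized dosages (monomorphic variants excluded).
    """
    G = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
    if G.shape[0] < 2 or G.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 variant")
    if method == "ibs":
        D = cdist(G, G, metric="cityblock")
        return 1.0 - D / (2.0 * G.shape[1])
    if method == "grm":
        p = G.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        if not keep.any():
            raise ValueError("all variants monomorphic; GRM undefined")
        Z = (G[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        return Z @ Z.T / keep.sum()
    raise ValueError(f"unknown kinship method {method!r}")


def _reml_loglik(log10_delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    """EMMA restricted log-likelihood profiled over delta."""
    delta = 10.0**log10_delta
    q = len(xi)
    denom = xi + delta
    s = float(np.sum(eta2 / denom))
    return 0.5 * (
        q * (np.log(q / (2 * np.pi)) - 1 - np.log(s)) - float(np.sum(np.log(denom)))
    )


def fit_null(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> NullModelFit:
    """REML fit of the variance components via the EMMA spectral form.

    delta = sigma_e^2/sigma_g^2 is profiled on a log10 grid from -5 to 5
    (100 intervals) and refined by bounded minimization in the best bracket.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("covariate design is rank deficient")

    # project out fixed effects, decompose S K S
    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    w, U = np.linalg.eigh((S @ K @ S + (S @ K @ S).T) / 2)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        raise ValueError("projected kinship has substantially negative eigenvalues")
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    xi, Ur = np.clip(w[: n - p], 0.0, None), U[:, : n - p]
    eta2 = (Ur.T @ y) ** 2

    grid = np.linspace(-5.0, 5.0, 101)
    ll = np.array([_reml_loglik(g, xi, eta2) for g in grid])
    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda g: -_reml_loglik(g, xi, eta2), bounds=(lo, hi), method="bounded"
    )
    best = res.x if -res.fun >= ll[i] else grid[i]
    boundary = i in (0, len(grid) - 1)
    delta = 10.0**best
    sigma_g2 = float(np.sum(eta2 / (xi + delta)) / (n - p))
    sigma_e2 = float(delta * sigma_g2)

    wk, Uk = np.linalg.eigh((K + K.T) / 2)
    return NullModelFit(
        sigma_g2=sigma_g2,
        sigma_e2=sigma_e2,
        delta=float(delta),
        reml_loglik=float(_reml_loglik(best, xi, eta2)),
        eigenvalues=np.clip(wk, 0.0, None),
        eigenvectors=Uk,
        boundary=boundary,
    )


def scan(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    genotypes: GenotypeMatrix,
    null: NullModelFit,
    trait_id: str = "trait",
) -> pd.DataFrame:
    """EMMAX single-variant scan with variance components fixed at the null.

    y, X and every dosage vector are whitened by V^{-1/2} from the cached
    eigendecomposition; each variant gets an OLS t-test on the dosage
    coefficient with df = n - rank(X) - 1. Returns one row per variant with
    beta, se, stat, p; ``lambda_gc`` is attached in ``DataFrame.attrs``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    n, p = X.shape
    d = null.sigma_g2 * null.eigenvalues + null.sigma_e2
    W = null.eigenvectors / np.sqrt(d)  # columns scaled: W^T whitens
    yt = W.T @ y
    Xt = W.T @ X
    Gt = W.T @ genotypes.dosages

    # project out fixed effects from whitened data
    Q, _ = np.linalg.qr(Xt)
    yr = yt - Q @ (Q.T @ yt)
    Gr = Gt - Q @ (Q.T @ Gt)

    gg = (Gr**2).sum(axis=0)
    df = n - p - 1
    const = gg < 1e-12 * max(1.0, float(np.abs(Gt).max()) ** 2)
    gg_safe = np.where(const, 1.0, gg)
    beta = (Gr.T @ yr) / gg_safe
    rss = (yr**2).sum() - beta**2 * gg_safe
    rss = np.clip(rss, 0.0, None)
    se = np.sqrt(rss / df / gg_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    beta[const] = 0.0
    tstat[const] = 0.0
    pvals[const] = 1.0

    out = genotypes.variants[["id", "chrom", "pos"]].copy()
    out.insert(0, "trait_id", trait_id)
    out["beta"] = beta
    out["se"] = se
    out["stat"] = tstat
    out["p"] = pvals
    out["constant_dosage"] = const
    out.attrs["lambda_gc"] = genomic_inflation(pvals)
    return out


def ols_scan(
    y: np.ndarray, X: np.ndarray, genotypes: GenotypeMatrix, trait_id: str = "trait"
) -> pd.DataFrame:
    """Plain OLS scan (no kinship); the uncorrected comparator."""
    n = len(np.asarray(y).ravel())
    ident = NullModelFit(
        sigma_g2=0.0,
        sigma_e2=1.0,
        delta=np.inf,
        reml_loglik=0.0,
        eigenvalues=np.ones(n),
        eigenvectors=np.eye(n),
    )
    return scan(y, X, np.eye(n), genotypes, ident, trait_id=trait_id)


def genomic_inflation(pvals: np.ndarray) -> float:
    """lambda_GC: median association chi^2 over the null chi^2_1 median."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def qq_points(pvals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected vs observed -log10 p for a QQ plot."""
    p = np.sort(np.asarray(pvals, dtype=float))
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)[::-1]
    observed = -np.log10(p)[::-1]
    return expected, observed


def classify_hits(
    results: pd.DataFrame,
    suggestive_p: float = 1e-5,
    significant_p: float = 5e-8,
    pool_traits: bool = False,
) -> pd.DataFrame:
    """Label suggestive (p < 1e-5) and genome-wide significant (p < 5e-8) rows.

    Returns only rows at suggestive level or better. With ``pool_traits``
    the minimum p per variant is kept, the source trait recorded.
    """
    if results.empty:
        raise ValueError("empty association results")
    hits = results[results["p"] < suggestive_p].copy()
    hits["label"] = np.where(hits["p"] < significant_p, "significant", "suggestive")
    if pool_traits and not hits.empty:
        hits = hits.sort_values("p").drop_duplicates(subset="id", keep="first")
    return hits.sort_values("p").reset_index(drop=True)


def clump_loci(hits: pd.DataFrame, window_bp: int = 1_000_000) -> pd.DataFrame:
    """Greedy positional clumping into loci.

    Repeatedly the most significant unassigned hit becomes a locus index;
    unassigned hits on the same chromosome within +/- window_bp join it.
    The locus is named by its index variant.
    """
    hits = hits.copy().reset_index(drop=True)
    locus = np.array([None] * len(hits), dtype=object)
    order = np.argsort(hits["p"].to_numpy(), kind="stable")
    for i in order:
        if locus[i] is not None:
            continue
        idx_id = hits.at[i, "id"]
        same = (
            (locus == None)  # noqa: E711  (elementwise on object array)
            & (hits["chrom"] == hits.at[i, "chrom"]).to_numpy()
            & (np.abs(hits["pos"].to_numpy() - hits.at[i, "pos"]) <= window_bp)
        )
        locus[same] = idx_id
    hits["locus_id"] = locus
    return hits


def replicate(
    discovery: pd.DataFrame,
    other_scans: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag discovery hits replicated in other regions' scans.

    A hit replicates in a region when the minimum p over that region's
    traits is below ``alpha``; variants absent from a region are 'untested'.
    """
    out = discovery.copy()
    for region, res in other_scans.items():
        best = res.groupby("id").agg(p=("p", "min"))
        best_trait = res.loc[res.groupby("id")["p"].idxmin()].set_index("id")["trait_id"]
        ps, flags, traits = [], [], []
        for vid in out["id"]:
            if vid in best.index:
                pv = float(best.loc[vid, "p"])
                ps.append(pv)
                flags.append("replicated" if pv < alpha else "not_replicated")
                traits.append(best_trait.loc[vid])
            else:
                ps.append(np.nan)
                flags.append("untested")
                traits.append("")
        out[f"{region}_p"] = ps
        out[f"{region}_trait"] = traits
        out[f"{region}_status"] = flags
    return out


def catalog_overlap(
    hits: pd.DataFrame, catalog: pd.DataFrame, catalog_p: float = 5e-8
) -> pd.DataFrame:
    """Join hits against prior-study summary rows significant at 5e-8."""
    cat = catalog.copy()
    cat["p"] = pd.to_numeric(cat["p"], errors="coerce")
    n_bad = int(cat["p"].isna().sum())
    if n_bad:
        cat = cat.dropna(subset=["p"])
    cat = cat[cat["p"] < catalog_p]
    merged = hits.merge(
        cat.rename(columns={"trait": "catalog_trait", "p": "catalog_p"}),
        left_on="id",
        right_on="variant_id" if "variant_id" in cat.columns else "id",
    )
    merged.attrs["malformed_catalog_rows"] = n_bad
    return merged


def build_network(hit_tables: dict[str, pd.DataFrame]) -> nx.DiGraph:
    """Directed phenotype -> locus graph from clumped hit tables.

    ``hit_tables`` maps a phenotype class (diagnostic, module, submodule,
    subtype) to a clumped HitTable; one node per trait and per locus, edges
    tagged with the phenotype class. Duplicate edges collapse.
    """
    G = nx.DiGraph()
    for pclass, table in hit_tables.items():
        if "locus_id" not in table.columns:
            raise ValueError(f"hit table for {pclass!r} is not clumped")
        for _, row in table.iterrows():
            trait = str(row["trait_id"])
            locus = f"locus:{row['locus_id']}"
            G.add_node(trait, role="phenotype", phenotype_class=pclass)
            if locus not in G:
                G.add_node(locus, role="locus")
            G.add_edge(trait, locus, association_class=pclass)
    return G
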