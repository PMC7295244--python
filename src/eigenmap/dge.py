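"""Moderated-t differential expression of case subtypes versus controls.

Each subtype is compared to the control decedents (cognitively normal plus,
by default, the MCI-like OTHER group) on residualized log2 expression with a
two-group design. Per-gene variances are shrunk toward a common prior by
empirical Bayes: the prior degrees of freedom d0 and prior variance s0^2 are
moment-estimated from the distribution of log sample variances, and the
posterior variance s~^2 = (d0 s0^2 + df s^2) / (d0 + df) feeds a moderated
t-statistic with df + d0 degrees of freedom. Genes are called up/down at
BH-adjusted p < 0.05 and |logFC| > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma


@dataclass
class ModerationFit:
    d0: float  # prior degrees of freedom, may be inf
    s0_2: float  # prior variance
    s2_post: np.ndarray  # per-gene posterior variance


def define_controls(cov: pd.DataFrame, include_other: bool = True) -> list[str]:
    """Control sample ids: CONTROL plus OTHER (MCI analog) unless excluded."""
    keep = ["CONTROL", "OTHER"] if include_other else ["CONTROL"]
    controls = cov.index[cov["diagnosis"].isin(keep)].tolist()
    if not controls:
        raise ValueError("no control samples under the given definition")
    return controls


def fit_two_group(
    expr: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Per-gene logFC (mean_a - mean_b), pooled variance s2 and df."""
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)}")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    A = expr.loc[:, group_a].to_numpy(dtype=float)
    B = expr.loc[:, group_b].to_numpy(dtype=float)
    na, nb = A.shape[1], B.shape[1]
    logfc = A.mean(axis=1) - B.mean(axis=1)
    ssa = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssb = ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df = na + nb - 2
    s2 = (ssa + ssb) / df
    out = pd.DataFrame({"logFC": logfc, "s2": s2}, index=expr.index)
    out.attrs["df"] = df
    out.attrs["n_a"] = na
    out.attrs["n_b"] = nb
    return out


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def moderate(s2: np.ndarray, df: float) -> ModerationFit:
    """Moment-estimate the variance prior from log sample variances.

    With s^2 | sigma^2 ~ sigma^2 chi2_df / df and sigma^2 from a scaled
    inverse chi-square prior (d0, s0^2), e_g = log s_g^2 - digamma(df/2) +
    log(df/2) has mean log s0^2 + log(d0/2) - digamma(d0/2) and variance
    trigamma(df/2) + trigamma(d0/2); d0 comes from inverting the trigamma
    term, with d0 = inf when the observed spread is no larger than the
    sampling floor.
    """
    s2 = np.asarray(s2, dtype=float)
    eps = np.finfo(float).eps
    if np.any(s2 <= 0):
        s2 = np.clip(s2, eps, None)
    small = len(s2) < 10
    e = np.log(s2) - digamma(df / 2.0) + np.log(df / 2.0)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0)) if len(s2) > 1 else 0.0
    if small or evar <= 0:
        # no detectable spread beyond sampling noise: infinite prior df,
        # common variance estimated by the plain mean (limma convention)
        d0 = np.inf
        s0_2 = float(np.mean(s2))
    else:
        x = _trigamma_inverse(evar)
        d0 = 2.0 * x
        s0_2 = float(np.exp(np.mean(e) + digamma(x) - np.log(x)))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
    return ModerationFit(d0=d0, s0_2=s0_2, s2_post=s2_post)


def moderated_t(
    logfc: np.ndarray,
    s2_post: np.ndarray,
    n_a: int,
    n_b: int,
    df: float,
    d0: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated t and two-sided p with df + d0 degrees of freedom."""
    logfc = np.asarray(logfc, dtype=float)
    s2_post = np.asarray(s2_post, dtype=float)
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    df_total = df + d0  # scipy handles df = inf as a normal
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return t, np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q <= 1, monotone)."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def call_de(
    table: pd.DataFrame, de_fdr: float = 0.05, de_lfc: float = 0.5
) -> pd.DataFrame:
    """Add up/down/ns calls at q < de_fdr and |logFC| > de_lfc."""
    out = table.copy()
    sig = out["q"] < de_fdr
    out["call"] = np.where(
        sig & (out["logFC"] > de_lfc),
        "up",
        np.where(sig & (out["logFC"] < -de_lfc), "down", "ns"),
    )
    out.attrs["n_up"] = int((out["call"] == "up").sum())
    out.attrs["n_down"] = int((out["call"] == "down").sum())
    return out


def run_dge(
    expr: pd.DataFrame,
    subtype_samples: list[str],
    control_samples: list[str],
    de_fdr: float = 0.05,
    de_lfc: float = 0.5,
) -> pd.DataFrame:
    """Full moderated-t DGE of one subtype against the controls."""
    fit = fit_two_group(expr, subtype_samples, control_samples)
    df = fit.attrs["df"]
    mod = moderate(fit["s2"].to_numpy(), df)
    t, p = moderated_t(
        fit["logFC"].to_numpy(),
        mod.s2_post,
        fit.attrs["n_a"],
        fit.attrs["n_b"],
        df,
        mod.d0,
    )
    table = fit.assign(t_mod=t, p=p, q=bh_adjust(p), df=df)
    table.attrs.update(fit.attrs)
    table.attrs["d0"] = mod.d0
    table.attrs["s0_2"] = mod.s0_2
    return call_de(table, de_fdr, de_lfc)
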