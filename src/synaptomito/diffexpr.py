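"""Two-group differential expression with empirical-Bayes moderated t.

Per protein g with pooled two-group residual variance s2_g on df_g degrees of
freedom, the across-protein distribution of variances is modeled as scaled-F:
s2_g | sigma2_g ~ sigma2_g * chi2(df_g)/df_g with a scaled inverse-chi2 prior
sigma2_g ~ s0^2 * d0 / chi2(d0).  The prior (d0, s0^2) is estimated by the
method of moments on e_g = log s2_g - psi(df_g/2) + log(df_g/2), and the
posterior variance

    s2_post = (d0 * s0^2 + df_g * s2_g) / (d0 + df_g)

replaces s2_g in the t-statistic, which then has d0 + df_g degrees of freedom.
At d0 = 0 this is the ordinary pooled two-sample t; at d0 = +inf every protein
uses the common variance s0^2.  Following the source analysis convention, the
per-protein p-values are used at a fixed threshold (default p < 0.01) with no
multiple-testing correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .quantify import GroupDesign, ProteinMatrix


@dataclass
class PriorEstimate:
    """Empirical-Bayes prior: d0 degrees of freedom (may be +inf) and prior
    variance s0_sq."""

    d0: float
    s0_sq: float

    def __post_init__(self):
        if not (self.d0 >= 0):
            raise ValueError("d0 must be >= 0")
        if not (self.s0_sq > 0):
            raise ValueError("s0_sq must be > 0")


def fit_group_stats(
    pm: ProteinMatrix,
    design: GroupDesign,
    g1: str,
    g2: str,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-protein group means, log2 fold-change (g2 - g1) and pooled
    residual variance.

    Proteins with fewer than ``min_per_group`` finite values in either group
    are excluded; proteins measured in only one group are reported separately
    by :func:`absent_protein_calls`.
    """
    s1 = [s for s in design.samples_in(g1) if s in pm.samples]
    s2 = [s for s in design.samples_in(g2) if s in pm.samples]
    if len(s1) < min_per_group or len(s2) < min_per_group:
        raise ValueError("need at least two samples per group")
    x1 = pm.log2[s1].to_numpy(float)
    x2 = pm.log2[s2].to_numpy(float)
    n1 = np.isfinite(x1).sum(axis=1)
    n2 = np.isfinite(x2).sum(axis=1)
    ok = (n1 >= min_per_group) & (n2 >= min_per_group)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(x1, axis=1)
        m2 = np.nanmean(x2, axis=1)
        ss1 = np.nansum((x1 - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((x2 - m2[:, None]) ** 2, axis=1)
        avg = np.nanmean(np.concatenate([x1, x2], axis=1), axis=1)
    df_g = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_pooled = (ss1 + ss2) / df_g
    out = pd.DataFrame(
        {
            "mean_g1": m1,
            "mean_g2": m2,
            "log2fc": m2 - m1,
            "avg_abundance": avg,
            "s2_g": s2_pooled,
            "df_g": df_g.astype(float),
            "n1": n1,
            "n2": n2,
        },
        index=pm.log2.index,
    )
    return out[ok]


def absent_protein_calls(
    pm: ProteinMatrix,
    design: GroupDesign,
    g1: str,
    g2: str,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Proteins quantified in one group only (e.g., a knocked-out gene
    product absent from KO samples).

    Such proteins carry no within-group variance contrast, so no p-value is
    assigned; the reported log2 fold-change is computed against a floor equal
    to the minimum abundance observed anywhere in the absent group's samples
    (an explicit convention, flagged in the ``absent_in`` column).
    """
    s1 = [s for s in design.samples_in(g1) if s in pm.samples]
    s2 = [s for s in design.samples_in(g2) if s in pm.samples]
    x1 = pm.log2[s1]
    x2 = pm.log2[s2]
    n1 = np.isfinite(x1.to_numpy(float)).sum(axis=1)
    n2 = np.isfinite(x2.to_numpy(float)).sum(axis=1)
    rows = []
    floor1 = np.nanmin(x1.to_numpy(float)) if np.isfinite(x1.to_numpy(float)).any() else np.nan
    floor2 = np.nanmin(x2.to_numpy(float)) if np.isfinite(x2.to_numpy(float)).any() else np.nan
    for i, pid in enumerate(pm.log2.index):
        if n1[i] >= min_per_group and n2[i] < min_per_group:
            fc = floor2 - x1.iloc[i].mean()
            rows.append((pid, g2, fc))
        elif n2[i] >= min_per_group and n1[i] < min_per_group:
            fc = x2.iloc[i].mean() - floor1
            rows.append((pid, g1, fc))
    return pd.DataFrame(rows, columns=["protein_id", "absent_in", "log2fc_vs_floor"])


def _trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x_new = x - step
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * x:
            return x_new
        x = x_new
    return x


def estimate_prior(s2: np.ndarray, df: np.ndarray | float) -> PriorEstimate:
    """Method-of-moments fit of the scaled-F prior on residual variances.

    Works on e_g = log s2_g - psi(df_g/2) + log(df_g/2), whose mean equals
    log s0^2 + psi(d0/2) - log(d0/2) and whose excess variance over the
    sampling term trigamma(df_g/2) equals trigamma(d0/2).  Non-positive
    excess variance yields d0 = +inf (all proteins share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() == 0:
        raise ValueError("no positive finite variances to estimate prior from")
    if (~ok).any() and (s2[np.isfinite(s2)] <= 0).all():
        raise ValueError("all variances are zero")
    s2, df = s2[ok], df[ok]
    n = len(s2)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    if n < 2:
        return PriorEstimate(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    excess = np.mean(
        (e - e_mean) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0)
    )
    if excess <= 0:
        return PriorEstimate(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    d0 = 2.0 * _trigamma_inverse(excess)
    if np.isinf(d0):
        return PriorEstimate(d0=np.inf, s0_sq=float(np.exp(e_mean)))
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return PriorEstimate(d0=float(d0), s0_sq=float(s0_sq))


def moderated_t(
    group_stats: pd.DataFrame,
    prior: PriorEstimate,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """Moderated t-statistics and regulation calls at ``p_threshold``
    (two-sided, uncorrected)."""
    d0, s0 = prior.d0, prior.s0_sq
    s2 = group_stats["s2_g"].to_numpy(float)
    df = group_stats["df_g"].to_numpy(float)
    n1 = group_stats["n1"].to_numpy(float)
    n2 = group_stats["n2"].to_numpy(float)
    fc = group_stats["log2fc"].to_numpy(float)
    if np.any(d0 + df <= 0):
        raise ValueError("total degrees of freedom must be positive")
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.full_like(df, np.inf)
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = np.where(se > 0, fc / np.where(se > 0, se, 1.0), np.where(fc == 0, 0.0, np.inf * np.sign(fc)))
    finite_df = np.where(np.isinf(df_total), 1e12, df_total)
    p = 2.0 * stats.t.sf(np.abs(t), finite_df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    regulated = np.where(
        p < p_threshold, np.where(fc > 0, "up", "down"), "none"
    )
    out = group_stats.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t
    out["df_total"] = df_total
    out["p"] = p
    out["regulated"] = regulated
    return out


def differential_expression(
    pm: ProteinMatrix,
    design: GroupDesign,
    g1: str,
    g2: str,
    p_threshold: float = 0.01,
    prior: PriorEstimate | None = None,
) -> pd.DataFrame:
    """Full moderated-t analysis of g2 vs g1; returns the DE result table
    indexed by protein_id."""
    gs = fit_group_stats(pm, design, g1, g2)
    if prior is None:
        prior = estimate_prior(gs["s2_g"].to_numpy(), gs["df_g"].to_numpy())
    return moderated_t(gs, prior, p_threshold=p_threshold)


def volcano_data(de: pd.DataFrame) -> pd.DataFrame:
    """log2 fold-change vs -log10 p table for volcano plots."""
    return pd.DataFrame(
        {
            "protein_id": de.index,
            "log2fc": de["log2fc"].values,
            "neg_log10_p": -np.log10(de["p"].values),
            "regulated": de["regulated"].values,
        }
    )
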