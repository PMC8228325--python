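"""Electron-microscopy mitochondrial morphometry.

Operates on nested measurement records (animal -> synapse -> mitochondrial
profile) with per-profile area (um^2), perimeter (um) and distance to the
active zone / postsynaptic density (nm).  Provides:

* shape metrics: circularity = 4*pi*A/P^2 and elongation index = 1/circularity
  (1 for a circle, larger for elongated or complex profiles);
* the 500 nm proximity rule (profiles farther from the synapse are not
  counted as synaptic mitochondria);
* ROUT-style robust outlier removal (robust location/scale fit, per-point t
  p-values, FDR-controlled step-down starting from the largest residuals);
* nested genotype inference via a random-intercept linear mixed model
  (REML), with Wald p-values on conservative between-animal degrees of
  freedom (n_animals - 2) to avoid pseudoreplication across profiles from
  the same animal;
* the per-animal mito-containing synapse fraction with a Student t-test
  across animals.

The intended pipeline order is outlier removal -> proximity filter -> shape
metrics -> nested tests (see :func:`analyze`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

RESPONSES = ("area_um2", "perimeter_um", "elongation", "distance_nm")

#: number of parameters of the robust location fit (ROUT-style delta)
_ROUT_DELTA = 1.0


class DataError(ValueError):
    """Measurement inconsistency in morphometry records."""


@dataclass
class ShapeMetrics:
    circularity: np.ndarray
    elongation: np.ndarray


def shape_metrics(area, perimeter, rtol: float = 1e-9) -> ShapeMetrics:
    """Circularity 4*pi*A/P^2 and elongation P^2/(4*pi*A).

    The isoperimetric inequality requires P^2 >= 4*pi*A; violations beyond
    ``rtol`` (relative) raise :class:`DataError`, smaller ones are clamped to
    a perfect circle.
    """
    a = np.atleast_1d(np.asarray(area, dtype=float))
    p = np.atleast_1d(np.asarray(perimeter, dtype=float))
    if np.any(a <= 0) or np.any(p <= 0):
        raise DataError("area and perimeter must be positive")
    iso = p**2 / (4.0 * math.pi * a)
    if np.any(iso < 1.0 - rtol):
        worst = float(iso.min())
        raise DataError(
            f"isoperimetric violation: P^2/(4*pi*A) = {worst:.6g} < 1; "
            "inconsistent area/perimeter measurement"
        )
    elong = np.maximum(iso, 1.0)
    return ShapeMetrics(circularity=1.0 / elong, elongation=elong)


def add_shape_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Append circularity and elongation columns for mito-bearing rows."""
    out = records.copy()
    out["circularity"] = np.nan
    out["elongation"] = np.nan
    mask = out["has_mito"].astype(bool) & out["area_um2"].notna() & out["perimeter_um"].notna()
    if mask.any():
        m = shape_metrics(out.loc[mask, "area_um2"], out.loc[mask, "perimeter_um"])
        out.loc[mask, "circularity"] = m.circularity
        out.loc[mask, "elongation"] = m.elongation
    return out


def proximity_filter(records: pd.DataFrame, max_distance: float = 500.0) -> pd.DataFrame:
    """Drop mitochondria farther than ``max_distance`` nm from the synapse.

    Rows beyond the threshold keep their synapse identity but lose the
    mitochondrion (has_mito becomes False, measurements cleared), so synapse
    denominators are unaffected.
    """
    out = records.copy()
    dist = out["distance_nm"]
    if (dist.dropna() < 0).any():
        raise DataError("negative mitochondrion-synapse distance")
    far = out["has_mito"].astype(bool) & dist.notna() & (dist > max_distance)
    out.loc[far, "has_mito"] = False
    out.loc[far, ["area_um2", "perimeter_um", "distance_nm", "compartment"]] = [
        np.nan, np.nan, np.nan, "",
    ]
    return out


def robust_outlier_mask(values, q: float = 0.01) -> np.ndarray:
    """ROUT-style outlier flags on a univariate sample.

    Residuals are taken from the median; the robust scale is the 68.27th
    percentile of |residuals| with the small-sample correction n/(n - delta)
    (delta = 1, the number of fitted location parameters).  Each point gets a
    two-sided p from t(n-1) on residual/scale, and a Benjamini-Hochberg-style
    step-down at FDR ``q`` flags outliers, largest residuals first.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 values for outlier detection")
    resid = x - np.median(x)
    scale = np.percentile(np.abs(resid), 68.27) * n / (n - _ROUT_DELTA)
    flags = np.zeros(n, dtype=bool)
    if scale <= 0:
        return flags
    p = 2.0 * stats.t.sf(np.abs(resid) / scale, df=n - 1)
    order = np.argsort(np.abs(resid))[::-1]  # largest residual first
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / n:
            flags[idx] = True
        else:
            break
    return flags


def robust_outliers(values, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Return (clean values, flagged values)."""
    x = np.asarray(values, dtype=float)
    flags = robust_outlier_mask(x, q=q)
    return x[~flags], x[flags]


def remove_outliers(
    records: pd.DataFrame,
    responses=("area_um2", "perimeter_um", "distance_nm"),
    q: float = 0.01,
) -> pd.DataFrame:
    """Drop mito rows flagged as outliers, per genotype x compartment x
    response (the default grouping; rows failing any response are dropped)."""
    out = records.copy()
    drop = np.zeros(len(out), dtype=bool)
    mito = out["has_mito"].astype(bool)
    for (_, _), idx in out[mito].groupby(["genotype", "compartment"]).groups.items():
        for resp in responses:
            vals = out.loc[idx, resp].to_numpy(float)
            ok = np.isfinite(vals)
            if ok.sum() < 5:
                continue
            flags = robust_outlier_mask(vals[ok], q=q)
            drop[out.index.get_indexer(np.asarray(idx)[ok])] |= flags
    return out[~drop].reset_index(drop=True)


@dataclass
class NestedTestResult:
    estimate: float  # genotype effect (non-reference minus reference)
    se: float
    p: float
    df: float
    n_animals: int
    n_obs: int
    method: str  # "lmm_reml" or "ols_fallback"


def nested_genotype_test(
    records: pd.DataFrame,
    response: str,
    compartment: str | None = None,
    reference: str = "WT",
) -> NestedTestResult:
    """Random-intercept mixed model y ~ genotype + (1 | animal), REML.

    ``response`` is one of area_um2, perimeter_um, elongation, distance_nm
    (elongation is derived if absent).  The Wald test on the genotype
    coefficient uses conservative between-animal degrees of freedom
    (n_animals - 2).  A singular fit (animal variance ~ 0) falls back to
    pooled OLS, flagged in ``method``.
    """
    if response == "elongation" and "elongation" not in records.columns:
        records = add_shape_metrics(records)
    if response not in records.columns:
        raise ValueError(f"unknown response {response!r}")
    sub = records[records["has_mito"].astype(bool)].copy()
    if compartment is not None:
        sub = sub[sub["compartment"] == compartment]
    sub = sub[np.isfinite(sub[response].to_numpy(float))]
    genotypes = sorted(sub["genotype"].unique(), key=lambda g: g != reference)
    if len(genotypes) != 2:
        raise ValueError("need exactly two genotypes with data")
    y = sub[response].to_numpy(float)
    x = (sub["genotype"] != reference).to_numpy(float)
    exog = np.column_stack([np.ones_like(x), x])
    groups = sub["animal_id"].to_numpy()
    n_animals = len(np.unique(groups))
    if n_animals < 4:
        raise ValueError("need at least two animals per genotype")
    dof = n_animals - 2
    method = "lmm_reml"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, exog, groups=groups).fit(reml=True)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        singular = float(np.asarray(fit.cov_re).ravel()[0]) < 1e-10
    except Exception:
        singular = True
        beta = se = np.nan
    if singular or not np.isfinite(se) or se == 0:
        ols = sm.OLS(y, exog).fit()
        beta, se = float(ols.params[1]), float(ols.bse[1])
        method = "ols_fallback"
    p = 2.0 * stats.t.sf(abs(beta / se), df=dof) if se > 0 else 1.0
    return NestedTestResult(
        estimate=beta, se=se, p=float(p), df=float(dof),
        n_animals=n_animals, n_obs=len(sub), method=method,
    )


@dataclass
class PresenceResult:
    per_animal: pd.DataFrame  # animal_id, genotype, n_synapses, fraction
    group_mean_pct: dict
    t_stat: float
    p: float
    zero_variance: bool = False


def mito_presence_test(records: pd.DataFrame) -> PresenceResult:
    """Fraction of synapses containing >=1 mitochondrion, per animal, with a
    two-sample Student t-test across animals."""
    per_syn = records.groupby(["animal_id", "genotype", "synapse_id"])["has_mito"].any()
    per_animal = (
        per_syn.groupby(["animal_id", "genotype"])
        .agg(n_synapses="size", fraction="mean")
        .reset_index()
    )
    per_animal = per_animal[per_animal["n_synapses"] > 0]
    genotypes = list(dict.fromkeys(records["genotype"]))
    if len(genotypes) != 2:
        raise ValueError("need exactly two genotypes")
    a = per_animal.loc[per_animal["genotype"] == genotypes[0], "fraction"].to_numpy()
    b = per_animal.loc[per_animal["genotype"] == genotypes[1], "fraction"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two animals per genotype")
    means = {g: 100.0 * v.mean() for g, v in zip(genotypes, (a, b))}
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return PresenceResult(per_animal, means, t_stat=0.0, p=1.0, zero_variance=True)
    t, p = stats.ttest_ind(a, b)
    return PresenceResult(per_animal, means, t_stat=float(t), p=float(p))


def analyze(
    records: pd.DataFrame,
    rout_q: float = 0.01,
    max_distance: float = 500.0,
    reference: str = "WT",
) -> dict:
    """Full morphometry analysis in the canonical order: outlier removal ->
    proximity filter -> shape metrics -> presence test + nested tests."""
    cleaned = remove_outliers(records, q=rout_q)
    filtered = proximity_filter(cleaned, max_distance=max_distance)
    withshape = add_shape_metrics(filtered)
    presence = mito_presence_test(withshape)
    nested = {}
    for comp in (None, "post", "pre"):
        for resp in ("area_um2", "perimeter_um", "elongation", "distance_nm"):
            key = f"{comp or 'all'}:{resp}"
            try:
                nested[key] = nested_genotype_test(
                    withshape, resp, compartment=comp, reference=reference
                )
            except ValueError:
                continue
    return {
        "records": withshape,
        "presence": presence,
        "nested": nested,
        "n_input": len(records),
        "n_after_outliers": len(cleaned),
    }
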