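"""Annotation-driven analysis of protein fold-change distributions.

Given a differential-expression table and gene-set annotations (e.g., the
"known mitochondrial" set, sub-organelle compartments or functional
categories), this module provides:

* :func:`subset_foldchanges` — split fold-changes into annotated targets and
  background.
* :func:`randomized_selection_test` — compare the target fold-change
  distribution against pooled size-matched random protein selections
  (two-sample Kolmogorov-Smirnov as the primary statistic, a dip-style
  unimodality statistic as an optional secondary readout of bimodality).
* :func:`category_summary` — per-category medians/IQRs of fold-changes with
  the +/-0.1 log2 reference convention.
* :func:`hypergeometric_ora` — simple over-representation analysis
  (hypergeometric upper tail + Benjamini-Hochberg), a declared stand-in for
  web-service GO enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._dip import dip_test


@dataclass
class AnnotationSet:
    """A named set of protein/gene identifiers (one GMT record)."""

    name: str
    members: set
    source: str = ""

    def __post_init__(self):
        self.members = {str(m) for m in self.members}
        if not self.name:
            raise ValueError("annotation set needs a name")

    def intersect(self, ids) -> set:
        return self.members & set(map(str, ids))


@dataclass
class DistTestResult:
    n_target: int
    n_iterations: int
    statistic: float  # two-sample KS D, target vs pooled random draws
    p_pooled: float
    per_iteration: np.ndarray  # KS D of target vs each single random draw
    dip: float | None = None
    dip_p: float | None = None
    method: str = "ks_vs_pooled_randomized_selection"


def subset_foldchanges(
    de: pd.DataFrame, ann: AnnotationSet
) -> tuple[np.ndarray, np.ndarray]:
    """Partition the DE table's log2 fold-changes by annotation membership.

    Returns (target_fc, background_fc).  IDs are compared case-insensitively
    after string normalization.
    """
    ids = de.index.astype(str)
    members = {m.lower() for m in ann.members}
    in_set = np.array([i.lower() in members for i in ids])
    if not in_set.any():
        raise ValueError(
            f"annotation {ann.name!r} has no overlap with the DE table; "
            "check the protein/gene ID namespace"
        )
    fc = de["log2fc"].to_numpy(float)
    return fc[in_set], fc[~in_set]


def randomized_selection_test(
    de: pd.DataFrame,
    ann: AnnotationSet,
    n_iter: int = 100,
    seed=None,
    compute_dip: bool = False,
    dip_mc: int = 200,
) -> DistTestResult:
    """Is the annotated fold-change distribution different from random
    protein selections?

    For each of ``n_iter`` iterations a protein set of the target's size is
    drawn without replacement from the quantified non-target proteins (so
    the random control shares no fold-change values with the target, which
    would otherwise create exact ties and a conservative reference); the
    primary statistic is the two-sample KS between the target fold-changes
    and the pooled random draws.  Because the pooled sample approximates the
    background distribution rather than adding independent observations, the
    p-value uses the background's effective size m*N/(m+N), not the pooled
    count.  Seed-reproducible.
    """
    target, background = subset_foldchanges(de, ann)
    if len(target) < 10:
        raise ValueError("need at least 10 annotated proteins in the DE table")
    if len(target) > len(background):
        raise ValueError("target set larger than the non-target background")
    rng = np.random.default_rng(seed)
    # sorting makes the draw sequence invariant to protein order in `de`
    target = np.sort(target)
    background = np.sort(background)
    m = len(target)
    pooled = np.empty(n_iter * m)
    per_iter = np.empty(n_iter)
    for i in range(n_iter):
        draw = background[rng.choice(len(background), size=m, replace=False)]
        pooled[i * m : (i + 1) * m] = draw
        per_iter[i] = stats.ks_2samp(target, draw).statistic
    d = float(stats.ks_2samp(target, pooled).statistic)
    en = m * len(background) / (m + len(background))
    p_pooled = float(
        np.clip(stats.distributions.kstwo.sf(d, int(round(en))), 0.0, 1.0)
    )
    dip = dip_p = None
    if compute_dip:
        dip, dip_p = dip_test(target, n_mc=dip_mc, seed=rng.integers(2**31))
    return DistTestResult(
        n_target=m,
        n_iterations=n_iter,
        statistic=d,
        p_pooled=p_pooled,
        per_iteration=per_iter,
        dip=dip,
        dip_p=dip_p,
    )


def category_summary(
    de: pd.DataFrame,
    categories: list[AnnotationSet],
    fc_reference: float = 0.1,
) -> pd.DataFrame:
    """Per-category fold-change summaries, sorted by median log2FC.

    ``frac_beyond_ref`` is the fraction of members with |log2FC| beyond the
    +/-``fc_reference`` reference lines; ``median_fold`` is the linear-scale
    2^median.
    """
    ids_lower = pd.Index(de.index.astype(str).str.lower())
    fc = de["log2fc"].to_numpy(float)
    rows = []
    for cat in categories:
        members = {m.lower() for m in cat.members}
        mask = ids_lower.isin(members)
        sub = fc[mask]
        if len(sub) == 0:
            rows.append((cat.name, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        med = float(np.median(sub))
        q1, q3 = np.percentile(sub, [25, 75])
        rows.append(
            (
                cat.name,
                int(len(sub)),
                med,
                float(2.0**med),
                float(q3 - q1),
                float(np.mean(np.abs(sub) > fc_reference)),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["category", "n", "median_log2fc", "median_fold", "iqr", "frac_beyond_ref"],
    )
    return out.sort_values(
        "median_log2fc", ascending=False, na_position="last"
    ).reset_index(drop=True)


def hypergeom_upper_tail(k: int, n_background: int, n_annotated: int, n_hits: int) -> float:
    """P(overlap >= k) when drawing n_hits from a background of size
    n_background containing n_annotated annotated items."""
    return float(stats.hypergeom.sf(k - 1, n_background, n_annotated, n_hits))


def hypergeometric_ora(
    hits: set,
    background: set,
    annotations: list[AnnotationSet],
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of each annotation among the hits.

    Hypergeometric upper-tail p per annotation (annotation restricted to the
    background), Benjamini-Hochberg q-values, sorted by q then p.
    """
    hits = set(map(str, hits))
    background = set(map(str, background))
    if not hits <= background:
        raise ValueError("hits must be a subset of the background")
    n_bg, n_hit = len(background), len(hits)
    rows = []
    for ann in annotations:
        members = ann.members & background
        k = len(members & hits)
        expected = n_hit * len(members) / n_bg if n_bg else np.nan
        p = hypergeom_upper_tail(k, n_bg, len(members), n_hit)
        rows.append((ann.name, len(members), k, expected, p))
    out = pd.DataFrame(
        rows, columns=["annotation", "n_in_background", "overlap", "expected", "p"]
    )
    if len(out):
        out["q"] = multipletests(out["p"].values, method="fdr_bh")[1]
        out["significant"] = out["q"] < fdr_q
    else:
        out["q"] = []
        out["significant"] = []
    return out.sort_values(["q", "p"]).reset_index(drop=True)
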