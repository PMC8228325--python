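"""Expression-weighted cell-type enrichment (EWCE-style bootstrap).

Cell-type *specificity* of a gene is the fraction of its total across-type
mean expression attributable to one cell type (rows of the specificity matrix
sum to 1).  A gene set's summed specificity in a cell type is compared with
the distribution of sums over size-matched random gene sets drawn from a
user-supplied background (here: all quantified mitochondrial proteins), which
yields a bootstrap z-score and upper-tail p per cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mitotest import AnnotationSet


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per cell (column).  Cells with zero total counts
    are dropped with a warning."""
    totals = counts.sum(axis=0)
    empty = totals == 0
    if empty.any():
        warnings.warn(f"dropping {int(empty.sum())} cells with zero counts", stacklevel=2)
        counts = counts.loc[:, ~empty]
        totals = totals[~empty]
    return counts * 1e6 / totals


def build_specificity(
    counts: pd.DataFrame,
    labels: pd.Series,
    exclude: set | tuple = (),
    depth_normalize: bool = True,
) -> pd.DataFrame:
    """Gene x cell-type specificity matrix.

    Expression is depth-normalized (CPM) per cell (unless
    ``depth_normalize=False``, for pre-normalized input), averaged per cell
    type (excluded / uninformative labels removed first), and each gene's
    row is divided by its across-type total, making specificity invariant to
    scaling a gene's expression by a positive constant.  Genes with zero
    total expression are excluded.
    """
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every cell in the count matrix")
    keep = ~labels.isin(set(exclude))
    if not keep.any():
        raise ValueError("all cell types excluded")
    counts = counts.loc[:, keep.values]
    labels = labels[keep]
    norm = cpm(counts) if depth_normalize else counts
    labels = labels.reindex(norm.columns)
    means = norm.T.groupby(labels.values).mean().T  # gene x type
    totals = means.sum(axis=1)
    nonzero = totals > 0
    if (~nonzero).any():
        means = means[nonzero]
        totals = totals[nonzero]
    return means.div(totals, axis=0)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # cell_type, observed, boot_mean, boot_sd, z, p, q
    n_boot: int
    n_target: int


def bootstrap_enrichment(
    spec: pd.DataFrame,
    target: set,
    background: set,
    n_boot: int = 10000,
    seed=None,
) -> EnrichmentResult:
    """Bootstrap cell-type enrichment of ``target`` against size-matched
    random subsets of ``background``.

    p is the upper-tail bootstrap probability with the +1/(n+1) correction
    (never exactly 0); q is Benjamini-Hochberg across cell types.
    """
    target = {str(g) for g in target}
    background = {str(g) for g in background}
    if not target <= background:
        raise ValueError("target must be a subset of the background")
    background = background & set(spec.index.astype(str))
    if not target <= background:
        missing = target - background
        raise ValueError(f"target genes missing from specificity matrix: {sorted(missing)[:5]}")
    if len(target) < 5:
        raise ValueError("need at least 5 target genes")
    bg_list = sorted(background)
    s = spec.loc[bg_list].to_numpy(float)  # n_bg x n_types
    t_mask = np.array([g in target for g in bg_list])
    observed = s[t_mask].sum(axis=0)

    rng = np.random.default_rng(seed)
    m = len(target)
    # size-matched subsets without replacement: top-m of random keys per row
    keys = rng.random((n_boot, len(bg_list)))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = s[idx].sum(axis=1)  # n_boot x n_types
    boot_mean = null.mean(axis=0)
    boot_sd = null.std(axis=0, ddof=1)
    # guard against degenerate nulls (e.g., target == background), where the
    # only variation left is float summation jitter
    tol = 1e-9 * np.maximum(np.abs(boot_mean), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(boot_sd > tol, (observed - boot_mean) / boot_sd, 0.0)
    p = (1.0 + (null >= observed[None, :]).sum(axis=0)) / (n_boot + 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "cell_type": spec.columns,
            "observed": observed,
            "boot_mean": boot_mean,
            "boot_sd": boot_sd,
            "z": z,
            "p": p,
            "q": q,
        }
    ).sort_values("p", kind="stable").reset_index(drop=True)
    return EnrichmentResult(table=table, n_boot=n_boot, n_target=m)


def top_n_by_foldchange(de: pd.DataFrame, ann: AnnotationSet, n: int = 50) -> list[str]:
    """The n annotated proteins with the largest log2 fold-change.

    Ties are broken by smaller p, then lexicographic ID.  If fewer than n
    annotated proteins are present, all are returned with a warning.
    """
    members = {m.lower() for m in ann.members}
    sub = de[[i.lower() in members for i in de.index.astype(str)]]
    if len(sub) == 0:
        raise ValueError("annotation has no overlap with the DE table")
    if len(sub) < n:
        warnings.warn(
            f"only {len(sub)} annotated proteins available (requested {n})",
            stacklevel=2,
        )
        n = len(sub)
    order = sub.assign(_id=sub.index.astype(str)).sort_values(
        by=["log2fc", "p", "_id"], ascending=[False, True, True], kind="stable"
    )
    return list(order.index[:n].astype(str))
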