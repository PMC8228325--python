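"""Genome-wide co-expression screen against a target gene (Grm5).

Cell-type expression profiles are built from single-cell counts: CPM per
cell, log10(x + 1), per-gene per-cell-type mean over *nonzero* values
(uninformative cell types excluded), and per-cell-type median normalization.
Each gene's profile is then Spearman-correlated with the target gene's
profile over pairwise-complete cell types, with Benjamini-Hochberg FDR
control across all tested genes (significant at q < 0.05).  Because Spearman
correlation is rank-based, the per-column median scaling cannot change rho;
it is applied for exactness of the intermediate profile output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .celltype import cpm
from .mitotest import AnnotationSet

DEFAULT_EXCLUDE = ("Low quality", "Batch grouping", "High intronic", "Doublet")


def build_profiles(
    counts: pd.DataFrame,
    labels: pd.Series,
    exclude: tuple | set = DEFAULT_EXCLUDE,
    pseudo_count: float = 1.0,
) -> pd.DataFrame:
    """Gene x cell-type processed expression profiles.

    Entries where a gene is unexpressed in every cell of a type (no nonzero
    values) are missing (NaN) and are excluded pairwise from correlations.
    """
    labels = labels.reindex(counts.columns)
    if labels.isna().any():
        raise ValueError("labels must cover every cell in the count matrix")
    keep = ~labels.isin(set(exclude))
    counts = counts.loc[:, keep.values]
    labels = labels[keep]
    log_expr = np.log10(cpm(counts) + pseudo_count)
    labels = labels.reindex(log_expr.columns)
    # mean over cells with value != 0 (zero counts give log10(0+1)=0)
    vals = log_expr.to_numpy(float)
    nonzero = vals != 0.0
    frame = pd.DataFrame(np.where(nonzero, vals, np.nan),
                         index=log_expr.index, columns=log_expr.columns)
    profiles = frame.T.groupby(labels.values).mean().T
    medians = profiles.median(axis=0, skipna=True)
    if (medians <= 0).any():
        raise ValueError("non-positive cell-type median; cannot median-normalize")
    return profiles / medians


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p (t approximation).

    Without ties the rank-difference formula is used, which is exact in
    floating point (monotone transforms give rho = +/-1 exactly, not
    1 - 1e-16); with ties it falls back to Pearson on ranks.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if len(np.unique(rx)) == n and len(np.unique(ry)) == n:
        d = rx - ry
        rho = 1.0 - 6.0 * float(d @ d) / (n * (n**2 - 1))
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if n <= 2:
        return rho, 1.0
    if abs(rho) == 1.0:
        p = np.finfo(float).tiny
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return rho, min(p, 1.0)


@dataclass
class ScreenResult:
    table: pd.DataFrame  # gene, rho, n, p, q, significant [, partition]
    target_gene: str
    partition_summary: pd.DataFrame | None = None


def spearman_screen(
    profiles: pd.DataFrame,
    target_gene: str,
    partition: AnnotationSet | None = None,
    min_shared: int = 3,
    fdr_q: float = 0.05,
) -> ScreenResult:
    """Spearman correlation of every gene's cell-type profile with the
    target's, over pairwise-complete cell types.

    Genes sharing fewer than ``min_shared`` non-missing cell types with the
    target are skipped.  BH FDR across all tested genes; optionally split by
    an annotation set (e.g., mitochondrial vs non-mitochondrial).
    """
    if target_gene not in profiles.index:
        raise ValueError(f"target gene {target_gene!r} not in profiles")
    target = profiles.loc[target_gene].to_numpy(float)
    t_ok = np.isfinite(target)
    if t_ok.sum() < min_shared:
        raise ValueError("target gene has too few non-missing cell types")
    if np.nanstd(target) == 0:
        raise ValueError("target profile is constant; rank correlation undefined")
    rows = []
    mat = profiles.to_numpy(float)
    genes = profiles.index.astype(str)
    for i, gene in enumerate(genes):
        if gene == target_gene:
            continue
        x = mat[i]
        ok = t_ok & np.isfinite(x)
        n = int(ok.sum())
        if n < min_shared:
            continue
        if np.std(x[ok]) == 0 or np.std(target[ok]) == 0:
            continue
        rho, p = _spearman(target[ok], x[ok])
        rows.append((gene, rho, n, p))
    table = pd.DataFrame(rows, columns=["gene", "rho", "n", "p"])
    if len(table):
        table["q"] = multipletests(table["p"].values, method="fdr_bh")[1]
        table["significant"] = table["q"] < fdr_q
    else:
        table["q"] = []
        table["significant"] = []
    summary = None
    if partition is not None:
        members = {m.lower() for m in partition.members}
        table["partition"] = [
            partition.name if g.lower() in members else f"non-{partition.name}"
            for g in table["gene"]
        ]
        summary = (
            table.groupby("partition")
            .agg(
                n=("gene", "size"),
                n_significant=("significant", "sum"),
                median_rho=("rho", "median"),
                median_abs_rho=("rho", lambda r: float(np.median(np.abs(r)))),
            )
            .reset_index()
        )
    return ScreenResult(table=table, target_gene=target_gene, partition_summary=summary)
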