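"""Peptide-level quality control and label-free protein quantification.

The quantification pipeline starts from a peptide table (intensity and
identification Q-value per peptide per sample, as produced by a DIA/SWATH
search engine) and produces a normalized protein x sample log2-abundance
matrix:

1. ``filter_peptides`` — keep a peptide only if it is confidently identified
   (Q <= 1e-3) in essentially all samples of at least half of the experimental
   groups, allowing one outlier sample per group; then keep only proteins with
   at least two surviving peptides.
2. ``rollup_proteins`` — protein abundance per sample is the log2 of the sum
   of its raw peptide intensities.
3. ``cyclic_loess_normalize`` — the "fast" cyclic loess scheme: each sample is
   loess-regressed against the mean of all samples in M-vs-A coordinates and
   the fitted trend subtracted, repeated for a fixed number of iterations.
4. ``replicate_cv`` — per-protein coefficient of variation on the raw
   (2^log2) scale within replicate groups, summarized as the median per group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

Q_THRESHOLD = 1e-3


class DesignError(ValueError):
    """Samples in the data do not match the sample-to-group design."""


@dataclass
class GroupDesign:
    """Sample-to-group assignment, with an optional block label per sample."""

    group: pd.Series  # sample_id -> group label
    block: pd.Series | None = None

    def __post_init__(self):
        self.group = pd.Series(self.group)
        if self.group.index.has_duplicates:
            raise DesignError("duplicate sample_id in design")

    @property
    def samples(self) -> list[str]:
        return list(self.group.index)

    @property
    def groups(self) -> list[str]:
        seen: dict = {}
        for g in self.group.values:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in(self, group_label) -> list[str]:
        return list(self.group.index[self.group.values == group_label])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroupDesign":
        frame = frame.set_index("sample_id")
        block = frame["block"] if "block" in frame.columns else None
        return cls(group=frame["group"], block=block)

    def to_frame(self) -> pd.DataFrame:
        out = self.group.rename("group").rename_axis("sample_id").reset_index()
        if self.block is not None:
            out["block"] = self.block.reindex(self.group.index).values
        return out


@dataclass
class PeptideTable:
    """Peptide x sample intensities and Q-values with a peptide->protein map.

    Intensities are raw MS intensities (positive where measured, NaN where
    missing); Q-values are the per-measurement identification confidence in
    [0, 1].  Every peptide maps to exactly one protein.
    """

    intensity: pd.DataFrame  # peptide_id x sample_id
    qvalue: pd.DataFrame
    protein: pd.Series  # peptide_id -> protein_id

    def __post_init__(self):
        if list(self.intensity.index) != list(self.qvalue.index):
            raise ValueError("intensity and qvalue peptide indexes differ")
        if list(self.intensity.columns) != list(self.qvalue.columns):
            raise ValueError("intensity and qvalue sample columns differ")
        self.protein = pd.Series(self.protein).reindex(self.intensity.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    @property
    def n_peptides(self) -> int:
        return len(self.intensity)

    def validate(self) -> None:
        inten = self.intensity.values
        if np.any(inten[np.isfinite(inten)] <= 0):
            raise ValueError("intensities must be positive where measured")
        q = self.qvalue.values
        finite_q = q[np.isfinite(q)]
        if np.any((finite_q < 0) | (finite_q > 1)):
            raise ValueError("Q-values must lie in [0, 1]")
        if self.protein.isna().any():
            raise ValueError("every peptide must map to a protein")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"peptide_id": self.intensity.index, "protein_id": self.protein.values}
        )
        for s in self.samples:
            out[s] = self.intensity[s].values
        for s in self.samples:
            out[f"{s}_qvalue"] = self.qvalue[s].values
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PeptideTable":
        frame = frame.set_index("peptide_id")
        qcols = [c for c in frame.columns if c.endswith("_qvalue")]
        samples = [c[: -len("_qvalue")] for c in qcols]
        return cls(
            intensity=frame[samples].astype(float),
            qvalue=frame[qcols].rename(
                columns=dict(zip(qcols, samples))
            ).astype(float),
            protein=frame["protein_id"],
        )


@dataclass
class ProteinMatrix:
    """Protein x sample log2 abundances, with peptide-count provenance."""

    log2: pd.DataFrame
    n_peptides: pd.Series
    normalized: bool = False

    @property
    def samples(self) -> list[str]:
        return list(self.log2.columns)


# ---------------------------------------------------------------------------
# peptide filtering


def peptide_keep_mask(
    qvalue: pd.DataFrame,
    design: GroupDesign,
    q_max: float = Q_THRESHOLD,
    allowed_outliers_per_group: int = 1,
) -> pd.Series:
    """Boolean mask over peptides implementing the group-wise Q-value rule.

    A group *qualifies* for a peptide when at least (group size - allowed
    outliers) of its samples have Q <= q_max; the peptide is kept when at
    least half of the groups (ceil(n_groups / 2)) qualify.  Missing Q-values
    count as failures.
    """
    unknown = set(qvalue.columns) - set(design.samples)
    if unknown:
        raise DesignError(f"samples not in design: {sorted(unknown)}")
    passes = qvalue.le(q_max).fillna(False)
    qualifying = pd.Series(0, index=qvalue.index)
    for g in design.groups:
        cols = [s for s in design.samples_in(g) if s in qvalue.columns]
        if not cols:
            continue
        need = max(len(cols) - allowed_outliers_per_group, 0)
        qualifying += (passes[cols].sum(axis=1) >= need).astype(int)
    required = math.ceil(len(design.groups) / 2)
    return qualifying >= required


def filter_peptides(
    pt: PeptideTable,
    design: GroupDesign,
    q_max: float = Q_THRESHOLD,
    min_peptides: int = 2,
    allowed_outliers_per_group: int = 1,
) -> PeptideTable:
    """Apply the Q-value filter, then drop proteins with < min_peptides
    surviving peptides (and the peptides of those failing proteins)."""
    keep = peptide_keep_mask(
        pt.qvalue, design, q_max=q_max,
        allowed_outliers_per_group=allowed_outliers_per_group,
    )
    surviving = pt.protein[keep.values]
    counts = surviving.value_counts()
    good_proteins = set(counts.index[counts >= min_peptides])
    final = keep & pt.protein.isin(good_proteins)
    if not final.any():
        warnings.warn("peptide filter removed every peptide", stacklevel=2)
    idx = pt.intensity.index[final.values]
    return PeptideTable(
        intensity=pt.intensity.loc[idx],
        qvalue=pt.qvalue.loc[idx],
        protein=pt.protein.loc[idx],
    )


# ---------------------------------------------------------------------------
# protein roll-up


def rollup_proteins(pt: PeptideTable, method: str = "sum") -> ProteinMatrix:
    """Roll peptides up to proteins.

    method="sum" (default): log2 of the summed raw peptide intensities per
    sample.  method="mean_log2": mean of the peptides' log2 intensities.
    Samples in which no peptide of a protein was measured become NaN.
    """
    if method == "sum":
        sums = pt.intensity.groupby(pt.protein).sum(min_count=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            log2 = np.log2(sums.where(sums > 0))
        if (sums <= 0).any().any():
            warnings.warn("zero total intensity rolled up as missing", stacklevel=2)
    elif method == "mean_log2":
        log2 = np.log2(pt.intensity).groupby(pt.protein).mean()
    else:
        raise ValueError(f"unknown roll-up method: {method!r}")
    n_pep = pt.protein.value_counts().reindex(log2.index)
    log2.index.name = "protein_id"
    return ProteinMatrix(log2=log2, n_peptides=n_pep, normalized=False)


# ---------------------------------------------------------------------------
# cyclic loess normalization ("fast" variant)


def cyclic_loess_normalize(
    m: ProteinMatrix,
    iterations: int = 10,
    span: float = 0.7,
    min_finite: int = 10,
) -> ProteinMatrix:
    """Fast cyclic loess: per iteration, each sample is corrected against the
    row-mean of all samples.

    For sample s with values x_s and per-protein mean across samples x_bar:
    M = x_s - x_bar is loess-regressed (locally linear, span ``span``) on
    A = (x_s + x_bar) / 2 and the fitted curve is subtracted from x_s.
    The row mean is recomputed between iterations, not between samples.
    Samples with fewer than ``min_finite`` finite values are left untouched.
    """
    x = m.log2.to_numpy(dtype=float, copy=True)
    n_samples = x.shape[1]
    if n_samples < 2:
        raise ValueError("normalization requires at least two samples")
    for _ in range(iterations):
        mean_all = np.nanmean(x, axis=1)
        for j in range(n_samples):
            col = x[:, j]
            ok = np.isfinite(col) & np.isfinite(mean_all)
            if ok.sum() < min_finite:
                warnings.warn(
                    f"sample {m.log2.columns[j]!r} has <{min_finite} finite "
                    "values; loess normalization skipped for it",
                    stacklevel=2,
                )
                continue
            a = (col[ok] + mean_all[ok]) / 2.0
            mm = col[ok] - mean_all[ok]
            delta = 0.01 * (a.max() - a.min())
            fit = lowess(mm, a, frac=span, it=3, delta=delta, return_sorted=False)
            x[ok, j] = col[ok] - fit
    out = pd.DataFrame(x, index=m.log2.index, columns=m.log2.columns)
    return ProteinMatrix(log2=out, n_peptides=m.n_peptides, normalized=True)


# ---------------------------------------------------------------------------
# replicate CV


def replicate_cv(
    pm: ProteinMatrix | pd.DataFrame, design: GroupDesign
) -> tuple[pd.DataFrame, pd.Series]:
    """Within-group coefficient of variation per protein, on the raw scale.

    Returns (per-protein-per-group CV table, median CV per group).  Groups
    with fewer than two samples are excluded (CV undefined).
    """
    log2 = pm.log2 if isinstance(pm, ProteinMatrix) else pm
    raw = np.power(2.0, log2)
    cols = {}
    for g in design.groups:
        samples = [s for s in design.samples_in(g) if s in raw.columns]
        if len(samples) < 2:
            continue
        sub = raw[samples]
        cols[g] = sub.std(axis=1, ddof=1) / sub.mean(axis=1)
    cv = pd.DataFrame(cols)
    return cv, cv.median(axis=0)
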