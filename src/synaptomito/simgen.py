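"""Synthetic data generators with planted ground truth.

Three generators emulate the statistical structure of the study's three data
modalities:

* :func:`simulate_peptides` — a two-group (6 vs 6) DIA/SWATH peptide table
  with a mitochondria-annotated protein stratum carrying a planted log2
  effect, per-sample systematic shifts, an optional smooth intensity-dependent
  bias (to exercise loess normalization) and Bernoulli Q-value failures.
* :func:`simulate_morphometry` — nested per-animal synapse/mitochondrion
  measurements (area, perimeter, distance, compartment) with genotype effects
  and between-animal random intercepts; the perimeter is derived from the
  planted area and elongation index via P = sqrt(4*pi*A*E) so the planted
  elongation is exactly recoverable.
* :func:`simulate_sc_counts` — a negative-binomial single-cell count matrix
  with cell-type marker genes and genes whose cell-type profiles are monotone
  transforms of a designated target gene's profile (for the co-expression
  screen).

Every generator is bit-reproducible given its seed and returns a truth table
recording what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .quantify import GroupDesign, PeptideTable, Q_THRESHOLD


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


# ---------------------------------------------------------------------------
# peptide-table generator


@dataclass
class PeptideSimConfig:
    """Two-group SWATH-style peptide simulation.

    Defaults follow the study design: 6 biological replicates per group,
    ~1766 proteins, an effect planted on the mitochondrial stratum.  Noise
    has two components: ``replicate_sd`` is protein-level biological
    variation shared by all peptides of a protein within a sample, and
    ``peptide_sd`` is independent per-measurement technical noise.  The
    defaults give a median protein CV near 9% at n = 6.
    """

    n_proteins: int = 1766
    peptides_per_protein: tuple[int, int] = (2, 12)
    n_per_group: int = 6
    groups: tuple[str, ...] = ("WT", "KO")
    frac_mito: float = 0.20
    effect_log2: float = 0.2
    effect_set: str = "mito"
    effect_frac: float = 1.0
    peptide_sd: float = 0.13
    replicate_sd: float = 0.12
    sample_offset_sd: float = 0.05
    intensity_bias_amplitude: float = 0.0
    q_fail_rate: float = 0.05
    baseline_mean: float = 17.0
    baseline_sd: float = 1.5
    peptide_offset_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_proteins >= 1, "n_proteins must be >= 1")
        _check(self.n_per_group >= 1, "n_per_group must be >= 1")
        _check(len(self.groups) >= 2, "need at least two groups")
        lo, hi = self.peptides_per_protein
        _check(1 <= lo <= hi, "peptides_per_protein must be a valid range")
        for name in ("frac_mito", "effect_frac", "q_fail_rate"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must lie in [0, 1]")
        _check(self.peptide_sd >= 0, "peptide_sd must be >= 0")
        _check(self.replicate_sd >= 0, "replicate_sd must be >= 0")
        _check(self.effect_set in ("mito", "other"), "effect_set must be 'mito' or 'other'")


def simulate_peptides(
    cfg: PeptideSimConfig,
) -> tuple[PeptideTable, GroupDesign, pd.DataFrame]:
    """Generate (PeptideTable, GroupDesign, TruthTable).

    Peptide intensity model (log2 scale): protein baseline + peptide offset
    + per-sample offset + group effect (on the effect stratum, applied to all
    non-reference groups) + smooth intensity-dependent bias (on every second
    sample within each group) + shared N(0, replicate_sd) protein-level
    replicate variation + independent N(0, peptide_sd) measurement noise.
    Q-values pass the 1e-3 threshold with probability 1 - q_fail_rate,
    independently per measurement.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(4, len(str(cfg.n_proteins)))
    proteins = np.array([f"P{i + 1:0{width}d}" for i in range(cfg.n_proteins)])
    n_mito = int(round(cfg.frac_mito * cfg.n_proteins))
    mito_idx = rng.choice(cfg.n_proteins, size=n_mito, replace=False)
    stratum = np.full(cfg.n_proteins, "other", dtype=object)
    stratum[mito_idx] = "mito"

    in_stratum = np.flatnonzero(stratum == cfg.effect_set)
    n_eff = int(round(cfg.effect_frac * len(in_stratum)))
    eff_idx = rng.choice(in_stratum, size=n_eff, replace=False) if n_eff else np.array([], int)
    effect = np.zeros(cfg.n_proteins)
    effect[eff_idx] = cfg.effect_log2

    lo, hi = cfg.peptides_per_protein
    pep_counts = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    pep_protein_idx = np.repeat(np.arange(cfg.n_proteins), pep_counts)
    n_pep = len(pep_protein_idx)
    peptide_ids = np.array(
        [
            f"{proteins[p]}_pep{k + 1:02d}"
            for p, k in zip(
                pep_protein_idx,
                np.concatenate([np.arange(c) for c in pep_counts]),
            )
        ]
    )

    samples = [f"{g}{i + 1}" for g in cfg.groups for i in range(cfg.n_per_group)]
    group_of = np.repeat(np.arange(len(cfg.groups)), cfg.n_per_group)
    design = GroupDesign(
        group=pd.Series(
            np.repeat(list(cfg.groups), cfg.n_per_group), index=samples
        )
    )

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)
    pep_offset = rng.normal(0.0, cfg.peptide_offset_sd, size=n_pep)
    sample_offset = rng.normal(0.0, cfg.sample_offset_sd, size=len(samples))
    # group effect applies to every non-reference group
    group_effect = np.where(group_of == 0, 0.0, 1.0)

    clean = (
        baseline[pep_protein_idx][:, None]
        + pep_offset[:, None]
        + sample_offset[None, :]
        + effect[pep_protein_idx][:, None] * group_effect[None, :]
    )
    # monotone intensity-dependent bias on every second sample within a group,
    # driven by the protein's clean rolled-up abundance so it appears as a
    # smooth trend against observed intensity (what cyclic loess removes)
    biased = np.array([i % 2 == 1 for i in range(cfg.n_per_group)] * len(cfg.groups))
    if cfg.intensity_bias_amplitude != 0.0:
        pep_clean = np.power(2.0, baseline[pep_protein_idx] + pep_offset)
        protein_clean = np.log2(np.bincount(pep_protein_idx, weights=pep_clean))
        centered = protein_clean[pep_protein_idx] - protein_clean.mean()
        bias = cfg.intensity_bias_amplitude * np.tanh(centered / 2.0)
        clean = clean + bias[:, None] * biased[None, :]

    replicate_noise = rng.normal(
        0.0, cfg.replicate_sd, size=(cfg.n_proteins, len(samples))
    )
    log2_int = (
        clean
        + replicate_noise[pep_protein_idx, :]
        + rng.normal(0.0, cfg.peptide_sd, size=(n_pep, len(samples)))
    )
    intensity = np.power(2.0, log2_int)

    fails = rng.random(size=(n_pep, len(samples))) < cfg.q_fail_rate
    u = rng.random(size=(n_pep, len(samples)))
    qvalue = np.where(
        fails,
        Q_THRESHOLD + u * (1.0 - Q_THRESHOLD),
        u * Q_THRESHOLD,
    )

    pt = PeptideTable(
        intensity=pd.DataFrame(intensity, index=peptide_ids, columns=samples),
        qvalue=pd.DataFrame(qvalue, index=peptide_ids, columns=samples),
        protein=pd.Series(proteins[pep_protein_idx], index=peptide_ids),
    )
    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "stratum": stratum,
            "true_log2fc": effect,
            "n_peptides": pep_counts,
        }
    )
    return pt, design, truth


# ---------------------------------------------------------------------------
# morphometry generator


def _per_geno_comp(value, genotypes=("WT", "KO"), compartments=("pre", "post")):
    """Broadcast a scalar (or per-genotype dict) to a (genotype, compartment)
    keyed dict."""
    if isinstance(value, Mapping):
        keys = list(value.keys())
        if keys and isinstance(keys[0], tuple):  # (genotype, compartment)-keyed
            return {
                (g, c): float(value[(g, c)]) for g in genotypes for c in compartments
            }
        out = {}
        for g in genotypes:
            v = value[g]  # genotype-keyed; scalar or nested per-compartment
            if isinstance(v, Mapping):
                for c in compartments:
                    out[(g, c)] = float(v[c])
            else:
                for c in compartments:
                    out[(g, c)] = float(v)
        return out
    return {(g, c): float(value) for g in genotypes for c in compartments}


def _per_geno(value, genotypes=("WT", "KO")):
    if isinstance(value, Mapping):
        return {g: float(value[g]) for g in genotypes}
    return {g: float(value) for g in genotypes}


def _default_area_mean_log():
    return {
        ("WT", "pre"): math.log(0.10),
        ("WT", "post"): math.log(0.10),
        ("KO", "pre"): math.log(0.10),
        ("KO", "post"): math.log(0.08),
    }


def _default_elongation_mean():
    return {
        ("WT", "pre"): 1.55,
        ("WT", "post"): 1.55,
        ("KO", "pre"): 1.55,
        ("KO", "post"): 1.40,
    }


@dataclass
class MorphoSimConfig:
    """Nested EM morphometry simulation: animals -> synapses -> mitochondria.

    Defaults mirror the study: 6 animals per genotype, ~35 synapses per
    animal (>=200 per genotype), mito-containing synapse probability 0.36 (WT)
    vs 0.42 (KO), a postsynaptic-only KO deficit in area (-20%) and
    elongation, and distances uniform on 0-600 nm so the 500 nm proximity
    rule removes about one sixth of profiles.
    """

    n_animals_per_genotype: int = 6
    synapses_per_animal: int = 35
    genotypes: tuple[str, str] = ("WT", "KO")
    p_mito: float | Mapping = field(default_factory=lambda: {"WT": 0.36, "KO": 0.42})
    p_post: float = 0.5
    area_mean_log: float | Mapping = field(default_factory=_default_area_mean_log)
    area_sd_log: float = 0.45
    elongation_mean: float | Mapping = field(default_factory=_default_elongation_mean)
    elongation_sd: float = 0.30
    animal_sd: float = 0.15
    distance_range: tuple[float, float] = (0.0, 600.0)
    synapse_length_mean: float = 320.0
    synapse_length_sd: float = 60.0
    outlier_rate: float = 0.0
    outlier_scale: float = 8.0
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_animals_per_genotype >= 1, "need >=1 animal per genotype")
        _check(self.synapses_per_animal >= 1, "need >=1 synapse per animal")
        for v in _per_geno(self.p_mito, self.genotypes).values():
            _check(0.0 <= v <= 1.0, "p_mito must lie in [0, 1]")
        _check(0.0 <= self.p_post <= 1.0, "p_post must lie in [0, 1]")
        for v in _per_geno_comp(self.elongation_mean, self.genotypes).values():
            _check(v >= 1.0, "elongation_mean must be >= 1")
        lo, hi = self.distance_range
        _check(0.0 <= lo < hi, "distance_range must be an increasing nm range")
        _check(0.0 <= self.outlier_rate <= 1.0, "outlier_rate must lie in [0, 1]")


def simulate_morphometry(
    cfg: MorphoSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (records, truth).

    Records follow the morphometry CSV schema (one row per synapse; mito
    measurements populated on mito-containing synapses).  Log-areas get a
    per-animal random intercept of sd ``animal_sd``; the elongation index is
    drawn as max(1, N(mean, sd)) and the perimeter derived exactly as
    P = sqrt(4*pi*A*E).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    p_mito = _per_geno(cfg.p_mito, cfg.genotypes)
    mu_area = _per_geno_comp(cfg.area_mean_log, cfg.genotypes)
    mu_elon = _per_geno_comp(cfg.elongation_mean, cfg.genotypes)

    rows = []
    for geno in cfg.genotypes:
        for a in range(cfg.n_animals_per_genotype):
            animal = f"{geno}_a{a + 1}"
            u = rng.normal(0.0, cfg.animal_sd)
            for s in range(cfg.synapses_per_animal):
                synapse = f"{animal}_s{s + 1:03d}"
                length = max(rng.normal(cfg.synapse_length_mean, cfg.synapse_length_sd), 1.0)
                has_mito = rng.random() < p_mito[geno]
                if not has_mito:
                    rows.append(
                        (animal, geno, synapse, "", False,
                         np.nan, np.nan, np.nan, length)
                    )
                    continue
                comp = "post" if rng.random() < cfg.p_post else "pre"
                area = math.exp(
                    rng.normal(mu_area[(geno, comp)] + u, cfg.area_sd_log)
                )
                if cfg.outlier_rate > 0 and rng.random() < cfg.outlier_rate:
                    area *= cfg.outlier_scale
                elong = max(1.0, rng.normal(mu_elon[(geno, comp)], cfg.elongation_sd))
                perimeter = math.sqrt(4.0 * math.pi * area * elong)
                distance = rng.uniform(*cfg.distance_range)
                rows.append(
                    (animal, geno, synapse, comp, True,
                     area, perimeter, distance, length)
                )
    records = pd.DataFrame(
        rows,
        columns=[
            "animal_id", "genotype", "synapse_id", "compartment", "has_mito",
            "area_um2", "perimeter_um", "distance_nm", "synapse_length_nm",
        ],
    )

    truth_rows = []
    for geno in cfg.genotypes:
        for comp in ("pre", "post"):
            mu = mu_area[(geno, comp)]
            truth_rows.append(
                {
                    "genotype": geno,
                    "compartment": comp,
                    "p_mito": p_mito[geno],
                    "area_mean_log": mu,
                    "area_mean_um2": math.exp(
                        mu + (cfg.area_sd_log ** 2 + cfg.animal_sd ** 2) / 2.0
                    ),
                    "elongation_mean": mu_elon[(geno, comp)],
                }
            )
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# single-cell count generator


_CORTICAL_TYPES = (
    "L2/3 IT", "L4", "L5 IT", "L5 PT", "L6 CT",
    "Pvalb", "Sst", "Vip", "Astro", "Oligo",
)


@dataclass
class ScSimConfig:
    """Negative-binomial scRNA-seq simulation with cell-type structure.

    Emulates a cortical reference dataset at desk scale: ~10 subclasses with
    marker genes, a target gene (default "Grm5") with a neuronal-leaning
    expression profile, and planted genes whose cell-type profiles are
    strictly monotone transforms of the target's (positive or reversed).
    Subclass averages in the emulated reference pool hundreds of cells, so
    ``cells_per_type`` defaults to 150; the simulated gene panel stands in
    for the *detected* genes a nonzero-mean screen actually tests, hence a
    moderate base expression (mean ~10 counts per cell).
    """

    n_cell_types: int = 10
    cells_per_type: int = 150
    n_genes: int = 1200
    n_marker_genes_per_type: int = 15
    marker_fold: float = 8.0
    nb_dispersion: float = 2.0
    target_gene: str = "Grm5"
    target_gene_profile: Sequence[float] | None = None
    n_pos_corr: int = 50
    n_neg_corr: int = 50
    uninformative_labels: tuple[str, ...] = ()
    gene_names: Sequence[str] | None = None
    marker_assignments: Mapping[str, Sequence[str]] | None = None
    base_mean_log: float = math.log(10.0)
    base_sd_log: float = 1.0
    depth_sd_log: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        _check(self.n_cell_types >= 2, "need at least two cell types")
        _check(self.cells_per_type >= 1, "cell types must not be empty")
        _check(self.n_genes >= 1, "need at least one gene")
        _check(self.nb_dispersion > 0, "nb_dispersion must be > 0")
        _check(self.marker_fold >= 1, "marker_fold must be >= 1")
        _check(self.n_pos_corr >= 0 and self.n_neg_corr >= 0, "corr counts must be >= 0")
        need = 1 + self.n_pos_corr + self.n_neg_corr
        _check(self.n_genes >= need, "n_genes too small for planted genes")
        if self.target_gene_profile is not None:
            _check(
                len(self.target_gene_profile) == self.n_cell_types,
                "target_gene_profile length must equal n_cell_types",
            )
            _check(
                all(v > 0 for v in self.target_gene_profile),
                "target profile values must be positive",
            )


def _default_target_profile(n: int) -> np.ndarray:
    # strictly decreasing, high in the (neuronal) leading types
    return 0.05 + 0.95 * np.exp(-0.45 * np.arange(n))


def simulate_sc_counts(
    cfg: ScSimConfig,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Generate (counts genes x cells, cell labels, truth).

    Truth records each gene's role: ``marker:<type>``, ``target``,
    ``pos_corr``, ``neg_corr`` or ``background``, plus each planted gene's
    per-type mean profile rank agreement with the target.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    if cfg.n_cell_types <= len(_CORTICAL_TYPES):
        types = list(_CORTICAL_TYPES[: cfg.n_cell_types])
    else:
        types = list(_CORTICAL_TYPES) + [
            f"Type{i + 1:02d}" for i in range(cfg.n_cell_types - len(_CORTICAL_TYPES))
        ]
    all_types = types + list(cfg.uninformative_labels)

    if cfg.gene_names is not None:
        _check(len(cfg.gene_names) == cfg.n_genes, "gene_names length mismatch")
        genes = list(cfg.gene_names)
        _check(cfg.target_gene in genes, "target_gene must be among gene_names")
    else:
        genes = [f"G{i + 1:05d}" for i in range(cfg.n_genes)]
        genes[0] = cfg.target_gene
    gene_pos = {g: i for i, g in enumerate(genes)}

    role = np.full(cfg.n_genes, "background", dtype=object)
    ti = gene_pos[cfg.target_gene]
    role[ti] = "target"

    profile = (
        np.asarray(cfg.target_gene_profile, float)
        if cfg.target_gene_profile is not None
        else _default_target_profile(cfg.n_cell_types)
    )

    free = [i for i in range(cfg.n_genes) if role[i] == "background"]
    rng.shuffle(free)
    pos_idx = [free.pop() for _ in range(cfg.n_pos_corr)]
    neg_idx = [free.pop() for _ in range(cfg.n_neg_corr)]
    for i in pos_idx:
        role[i] = "pos_corr"
    for i in neg_idx:
        role[i] = "neg_corr"

    # base expression and per-type mean matrix
    lam = rng.lognormal(cfg.base_mean_log, cfg.base_sd_log, size=cfg.n_genes)
    mu = np.tile(lam[:, None], (1, len(all_types)))

    # markers: explicitly assigned or random among remaining background genes
    if cfg.marker_assignments is not None:
        for t, names in cfg.marker_assignments.items():
            _check(t in all_types, f"marker type {t!r} not among cell types")
            for g in names:
                mu[gene_pos[g], all_types.index(t)] *= cfg.marker_fold
                if role[gene_pos[g]] == "background":
                    role[gene_pos[g]] = f"marker:{t}"
    else:
        for t_i, t in enumerate(types):
            take = min(cfg.n_marker_genes_per_type, len(free))
            chosen = [free.pop() for _ in range(take)]
            for i in chosen:
                mu[i, t_i] *= cfg.marker_fold
                role[i] = f"marker:{t}"

    # planted profile genes: strictly monotone transforms of the target profile
    scaled = profile / profile.max()
    rev = scaled.min() + scaled.max() - scaled  # order-reversing, positive
    informative = slice(0, cfg.n_cell_types)
    mu[ti, informative] = lam[ti] * cfg.n_cell_types * scaled / scaled.sum()
    for i in pos_idx:
        alpha = rng.uniform(0.5, 2.0)
        shape = scaled ** alpha
        mu[i, informative] = lam[i] * cfg.n_cell_types * shape / shape.sum()
    for i in neg_idx:
        alpha = rng.uniform(0.5, 2.0)
        shape = rev ** alpha
        mu[i, informative] = lam[i] * cfg.n_cell_types * shape / shape.sum()

    # cells
    cells, labels, mu_cols = [], [], []
    for t_i, t in enumerate(all_types):
        for c in range(cfg.cells_per_type):
            cells.append(f"{t.replace(' ', '_').replace('/', '')}_c{c + 1:03d}")
            labels.append(t)
            mu_cols.append(t_i)
    depth = rng.lognormal(0.0, cfg.depth_sd_log, size=len(cells))
    mean_mat = mu[:, mu_cols] * depth[None, :]
    theta = cfg.nb_dispersion
    p = theta / (theta + mean_mat)
    counts = rng.negative_binomial(theta, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=cells)
    labels_sr = pd.Series(labels, index=pd.Index(cells, name="cell_id"), name="cell_type")
    truth = pd.DataFrame({"gene": genes, "role": role})
    return counts_df, labels_sr, truth
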