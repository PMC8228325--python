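"""End-to-end orchestration of the synthetic analysis.

``run_all`` executes simulate -> quantify -> differential expression ->
mitochondrial distribution tests -> morphometry -> cell-type enrichment ->
co-expression screen on one shared seed, and writes a report bundle of plain
TSV/JSON files (tables plus volcano/ECDF/box plot data).  All randomness
derives from the config seed, and no output embeds a timestamp, so a fixed
seed reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .celltype import bootstrap_enrichment, build_specificity, top_n_by_foldchange
from .coexpr import build_profiles, spearman_screen
from .diffexpr import differential_expression, volcano_data
from .mitotest import (
    AnnotationSet,
    category_summary,
    hypergeometric_ora,
    randomized_selection_test,
)
from .morphometry import analyze as morpho_analyze
from .quantify import (
    cyclic_loess_normalize,
    filter_peptides,
    replicate_cv,
    rollup_proteins,
)
from .simgen import (
    MorphoSimConfig,
    PeptideSimConfig,
    ScSimConfig,
    simulate_morphometry,
    simulate_peptides,
    simulate_sc_counts,
)


@dataclass
class PipelineConfig:
    """Stage parameters for the full synthetic analysis.

    Analysis parameters default to the study's conventions: Q <= 1e-3 peptide
    filter, >=2 peptides per protein, 10 cyclic-loess iterations, eBayes
    p < 0.01 (uncorrected), 100 randomization iterations, 500 nm proximity
    rule, ROUT 1%, FDR 0.05, top-50 fold-change gene set.
    """

    seed: int = 0
    q_max: float = 1e-3
    min_peptides: int = 2
    loess_iterations: int = 10
    loess_span: float = 0.7
    p_threshold: float = 0.01
    n_iter: int = 100
    max_distance_nm: float = 500.0
    rout_q: float = 0.01
    fdr_q: float = 0.05
    top_n: int = 50
    n_boot: int = 2000
    peptides: dict = field(default_factory=dict)
    morpho: dict = field(default_factory=dict)
    sc: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_all(cfg: PipelineConfig, out_dir) -> dict:
    """Run every stage and write the report bundle into ``out_dir``.

    Returns the report summary dict (also written as report.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(cfg.seed, 6)
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": cfg.seed,
            "parameter_hash": cfg.param_hash(),
        }
    }

    # --- stage 1: peptide simulation --------------------------------------
    # effect on half the mito stratum: the fold-change distribution of mito
    # proteins then forms the two-mode structure the randomization test and
    # category summaries are built to expose
    pep_cfg = PeptideSimConfig(
        **{"seed": seeds[0], "effect_frac": 0.5, **cfg.peptides}
    )
    pt, design, truth = simulate_peptides(pep_cfg)
    io.write_peptide_table(pt, out / "peptides.tsv")
    io.write_design(design, out / "design.tsv")
    truth.to_csv(out / "peptide_truth.tsv", sep="\t", index=False)
    mito_ids = set(truth.loc[truth["stratum"] == "mito", "protein_id"])
    effect_ids = set(truth.loc[truth["true_log2fc"] != 0, "protein_id"])

    # --- stage 2: quantification ------------------------------------------
    filtered = filter_peptides(
        pt, design, q_max=cfg.q_max, min_peptides=cfg.min_peptides
    )
    pm = rollup_proteins(filtered)
    pm = cyclic_loess_normalize(
        pm, iterations=cfg.loess_iterations, span=cfg.loess_span
    )
    io.write_protein_matrix(pm, out / "protein_matrix.tsv")
    _, median_cv = replicate_cv(pm, design)
    report["quantify"] = {
        "n_peptides_input": pt.n_peptides,
        "n_peptides_kept": filtered.n_peptides,
        "n_proteins": len(pm.log2),
        "median_cv_pct": {g: round(100 * v, 3) for g, v in median_cv.items()},
    }

    # --- stage 3: differential expression ---------------------------------
    g1, g2 = design.groups[0], design.groups[1]
    de = differential_expression(pm, design, g1, g2, p_threshold=cfg.p_threshold)
    de.rename_axis("protein_id").reset_index().to_csv(
        out / "de_results.tsv", sep="\t", index=False, float_format="%.6g"
    )
    volcano_data(de).to_csv(
        out / "volcano_data.tsv", sep="\t", index=False, float_format="%.6g"
    )
    up = set(de.index[de["regulated"] == "up"].astype(str))
    down = set(de.index[de["regulated"] == "down"].astype(str))
    up_mito_frac = (
        100.0 * len(up & mito_ids) / len(up) if up else float("nan")
    )
    report["diffexpr"] = {
        "contrast": f"{g2} - {g1}",
        "n_tested": len(de),
        "n_up": len(up),
        "n_down": len(down),
        "pct_up_mitochondrial": round(up_mito_frac, 2),
    }

    # --- stage 4: mitochondrial distribution tests ------------------------
    mito_set = AnnotationSet("known_mito", mito_ids, source="simulated_truth")
    categories = [
        AnnotationSet("mito_effect", mito_ids & effect_ids, source="simulated_truth"),
        AnnotationSet("mito_null", mito_ids - effect_ids, source="simulated_truth"),
    ]
    io.write_gmt([mito_set, *categories], out / "annotations.gmt")
    rand = randomized_selection_test(
        de, mito_set, n_iter=cfg.n_iter, seed=seeds[1]
    )
    target_fc, _ = (
        de.loc[de.index.astype(str).isin(mito_ids), "log2fc"].to_numpy(),
        None,
    )
    ecdf = pd.DataFrame(
        {
            "log2fc": np.sort(target_fc),
            "ecdf": (np.arange(1, len(target_fc) + 1)) / len(target_fc),
        }
    )
    ecdf.to_csv(out / "mito_fc_ecdf.tsv", sep="\t", index=False, float_format="%.6g")
    cats = category_summary(de, categories)
    cats.to_csv(out / "category_summary.tsv", sep="\t", index=False, float_format="%.6g")
    ora = hypergeometric_ora(
        up | down, set(de.index.astype(str)), [mito_set, *categories], fdr_q=cfg.fdr_q
    )
    ora.to_csv(out / "ora.tsv", sep="\t", index=False, float_format="%.6g")
    report["mitotest"] = {
        "randomization": {
            "n_target": rand.n_target,
            "ks_statistic": round(rand.statistic, 6),
            "p_pooled": float(rand.p_pooled),
        },
        "category_median_fold": {
            r["category"]: round(r["median_fold"], 4)
            for _, r in cats.iterrows()
            if r["n"] > 0
        },
        "top_ora_annotation": ora.iloc[0]["annotation"] if len(ora) else None,
        "top_ora_q": float(ora.iloc[0]["q"]) if len(ora) else None,
    }

    # --- stage 5: morphometry ---------------------------------------------
    mcfg = MorphoSimConfig(**{"seed": seeds[2], **cfg.morpho})
    records, mtruth = simulate_morphometry(mcfg)
    io.write_morphometry(records, out / "morphometry.csv")
    mtruth.to_csv(out / "morphometry_truth.tsv", sep="\t", index=False)
    manalysis = morpho_analyze(
        records, rout_q=cfg.rout_q, max_distance=cfg.max_distance_nm
    )
    manalysis["presence"].per_animal.to_csv(
        out / "mito_presence_per_animal.tsv", sep="\t", index=False, float_format="%.6g"
    )
    nested_rows = [
        {
            "subset": key,
            "estimate": r.estimate,
            "se": r.se,
            "p": r.p,
            "method": r.method,
            "n_obs": r.n_obs,
        }
        for key, r in manalysis["nested"].items()
    ]
    pd.DataFrame(nested_rows).to_csv(
        out / "nested_tests.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pres = manalysis["presence"]
    report["morphometry"] = {
        "pct_synapses_with_mito": {g: round(v, 2) for g, v in pres.group_mean_pct.items()},
        "presence_t_p": float(pres.p),
        "nested_p": {row["subset"]: float(row["p"]) for row in nested_rows},
    }

    # --- stage 6: cell-type enrichment ------------------------------------
    # gene namespace shared with the proteomics simulation: mito protein IDs
    # become genes of the single-cell simulation, and the effect stratum is
    # made marker-like in the excitatory types.
    quantified_mito = sorted(mito_ids & set(de.index.astype(str)))
    sc_defaults = dict(cfg.sc)
    n_genes = sc_defaults.pop("n_genes", 1200)
    sc_probe = ScSimConfig(n_genes=n_genes, seed=seeds[3], **sc_defaults)
    filler = [f"G{i + 1:05d}" for i in range(n_genes)]
    gene_names = ["Grm5"] + quantified_mito
    gene_names += filler[: n_genes - len(gene_names)]
    effect_genes = sorted(set(quantified_mito) & effect_ids)
    exc_types = ["L2/3 IT", "L4", "L5 IT"]
    marker_assignments = {
        t: effect_genes[i :: len(exc_types)] for i, t in enumerate(exc_types)
    }
    sc_cfg = dataclasses.replace(
        sc_probe, gene_names=gene_names, marker_assignments=marker_assignments
    )
    counts, labels, sc_truth = simulate_sc_counts(sc_cfg)
    spec = build_specificity(counts, labels, exclude=set(sc_cfg.uninformative_labels))
    spec.rename_axis("gene").reset_index().to_csv(
        out / "specificity.tsv", sep="\t", index=False, float_format="%.6g"
    )
    background = set(spec.index.astype(str)) & set(quantified_mito)
    top = top_n_by_foldchange(
        de.loc[de.index.astype(str).isin(background)], mito_set, n=cfg.top_n
    )
    ewce = bootstrap_enrichment(
        spec, set(top), background, n_boot=cfg.n_boot, seed=seeds[4]
    )
    ewce.table.to_csv(out / "ewce.tsv", sep="\t", index=False, float_format="%.6g")
    top_row = ewce.table.iloc[0]
    report["celltype"] = {
        "n_target": ewce.n_target,
        "n_background": len(background),
        "top_cell_type": top_row["cell_type"],
        "top_z": round(float(top_row["z"]), 3),
        "top_p": float(top_row["p"]),
    }

    # --- stage 7: co-expression screen ------------------------------------
    profiles = build_profiles(counts, labels)
    screen = spearman_screen(
        profiles, "Grm5",
        partition=AnnotationSet("mito", set(quantified_mito)),
        fdr_q=cfg.fdr_q,
    )
    screen.table.to_csv(out / "grm5_correlations.tsv", sep="\t", index=False, float_format="%.6g")
    if screen.partition_summary is not None:
        screen.partition_summary.to_csv(
            out / "grm5_correlation_partition.tsv", sep="\t", index=False, float_format="%.6g"
        )
    report["coexpr"] = {
        "n_tested": len(screen.table),
        "n_significant": int(screen.table["significant"].sum()),
    }

    io.dump_json(report, out / "report.json")
    return report
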