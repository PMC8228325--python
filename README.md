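# synaptomito

Analysis toolkit for studying how reduced mGluR5 (metabotropic glutamate
receptor 5) activity regulates **synaptic mitochondria**, re-implementing a
multi-modal computational pipeline as a tested, reusable Python package:

1. **Label-free synaptosome proteomics** (DIA/SWATH): peptide Q-value
   filtering, protein roll-up, fast cyclic-loess normalization, replicate-CV
   summaries, and empirical-Bayes moderated t-statistics for two-group
   differential expression.
2. **Mitochondrial fold-change distribution analysis**: annotation-driven
   subsetting, a randomized-protein-selection distribution test, functional
   category summaries, and hypergeometric over-representation.
3. **Electron-microscopy morphometry**: circularity/elongation shape
   metrics, the 500 nm synapse-proximity rule, ROUT-style robust outlier
   removal, nested (animal-level) mixed-model inference, and
   mito-containing synapse fractions.
4. **Expression-weighted cell-type enrichment** (EWCE-style bootstrap)
   against a mitochondrial background.
5. **A genome-wide Grm5 co-expression screen** over single-cell cell-type
   expression profiles with FDR control.

Every stage can be exercised on synthetic data with planted ground truth
(`synaptomito.simgen`), so each statistical claim is testable by
simulation-recovery.

## The statistics at the core

**Moderated t.** For protein *g* with pooled two-group variance
s²_g on d_g degrees of freedom, the across-protein variance distribution is
modeled as scaled-F: s²_g | σ²_g ~ σ²_g·χ²(d_g)/d_g with prior
σ²_g ~ s₀²·d₀/χ²(d₀).  The prior (d₀, s₀²) is estimated by method of moments
on e_g = log s²_g − ψ(d_g/2) + log(d_g/2), and

    s²_post = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
    t_g = Δ_g / sqrt(s²_post·(1/n₁ + 1/n₂))  ~  t(d₀ + d_g)

with Δ_g the log2 fold-change.  At d₀ = 0 this is the ordinary pooled t; at
d₀ = ∞ all proteins share s₀².  Regulation is called at p < 0.01, two-sided,
uncorrected (the pipeline's convention, to keep more proteins available for
downstream pathway analysis).

**Randomized-selection distribution test.** The fold-change distribution of
an annotated protein set (e.g., "known mitochondrial") is compared against
100 size-matched random protein selections by a two-sample
Kolmogorov–Smirnov statistic on the pooled draws, with the p-value computed
at the background's effective sample size.  A dip-style unimodality
statistic is available as a secondary readout of bimodality.

**Shape metrics.** circularity = 4πA/P², elongation index = 1/circularity =
P²/(4πA); 1 for a circle, larger for elongated/complex mitochondrial
profiles.  Nested genotype effects are fitted as y = β₀ + β₁·genotype +
a_animal + ε by REML, with Wald tests on conservative between-animal
degrees of freedom (n_animals − 2) to avoid pseudoreplication.

**EWCE.** Specificity s_{g,c} is the fraction of gene g's across-cell-type
mean expression in cell type c (rows sum to 1).  A gene set's summed
specificity is compared with sums over size-matched random sets bootstrapped
from the mitochondrial background (10,000 draws, +1/(n+1)-corrected p).

**Co-expression screen.** CPM → log10(x+1) → per-gene per-cell-type mean of
nonzero values → per-type median normalization → Spearman correlation of
every gene against Grm5 over pairwise-complete cell types, Benjamini-
Hochberg FDR at q < 0.05.

## Worked example

```python
import synaptomito as sm

cfg = sm.PeptideSimConfig(n_proteins=400, seed=7)        # 6 vs 6 SWATH design
pt, design, truth = sm.simulate_peptides(cfg)
filtered = sm.filter_peptides(pt, design)                # Q<=1e-3 group rule
pm = sm.cyclic_loess_normalize(sm.rollup_proteins(filtered))
_, cv = sm.replicate_cv(pm, design)
de = sm.differential_expression(pm, design, "WT", "KO")  # moderated t

mito = set(truth.loc[truth.stratum == "mito", "protein_id"])
res = sm.randomized_selection_test(de, sm.AnnotationSet("mito", mito),
                                   n_iter=100, seed=7)
```

prints (via the summaries shown below):

```
peptides kept: 2779/2786
proteins quantified: 399
median CV: WT 8.5%, KO 8.6%
regulated at p<0.01: 30 up, 9 down
mito vs randomized selection: KS D=0.867, p=1.74e-56
```

The generator planted a +0.2 log2 effect on the mitochondrial stratum
(~20% of proteins): replicate CVs land near the 8–9% typical of SWATH
synaptosome data, the moderated t recovers the planted up-regulation, and
the mitochondrial fold-change distribution is decisively non-random.

The same stages are available from the shell:

```bash
synaptomito simulate peptides --out sim/ --seed 7
synaptomito quantify --peptides sim/peptides.tsv --design sim/design.tsv --out pm.tsv
synaptomito diffexpr --matrix pm.tsv --design sim/design.tsv --contrast KO-WT --out de.tsv
synaptomito run-all --seed 7 --out run/        # full pipeline + report bundle
```

## Layout

```
src/synaptomito/
  simgen.py       synthetic data generators with planted truth
  quantify.py     peptide filter, roll-up, cyclic loess, replicate CV
  diffexpr.py     empirical-Bayes moderated t
  mitotest.py     distribution tests, category summaries, ORA
  morphometry.py  shape metrics, proximity rule, ROUT, nested models
  celltype.py     specificity matrices and bootstrap enrichment
  coexpr.py       cell-type profiles and the Spearman screen
  pipeline.py     end-to-end orchestration (run-all)
  cli.py          click command-line interface
  io.py           TSV/CSV/GMT readers and writers
docs/methods.md   model assumptions, parameter choices, limitations
```
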