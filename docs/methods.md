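# Methods

This note documents the models, parameter choices and known limitations of
each stage, in the order the pipeline runs them.

## Synthetic data generators (`simgen`)

The generators define the conditions under which every downstream claim is
tested.  They are first-class, tested code, not fixtures.

### Peptide tables

Peptide intensity is modeled on the log2 scale as

    protein baseline + peptide offset + sample offset + group effect
    + intensity-dependent bias + replicate variation + measurement noise

with intensities 2^(·).  Defaults encode the study design: two groups
(WT/KO) of 6 biological replicates, ~1766 proteins with 2–12 peptides each,
a +0.2 log2 effect planted on the mitochondria-annotated stratum (20% of
proteins).

Noise has two components. `replicate_sd` (default 0.12 log2) is shared by
all peptides of a protein within a sample and models biological
replicate-to-replicate variation; `peptide_sd` (default 0.13 log2) is
independent per measurement.  The split matters: with ≥2 peptides per
protein, purely peptide-level noise would average out in the roll-up and
protein CVs would shrink with peptide count, which is not what replicate
CVs of real label-free data look like.  With these defaults the median
protein CV at n = 6 is ~9%, and the rolled-up protein values are exactly
lognormal, so the pooled variances follow the scaled-χ² sampling model the
moderated t assumes.

Q-values are Bernoulli per measurement: with probability 1 − `q_fail_rate`
(default pass rate 95%) the measurement draws Q ~ U(0, 10⁻³], otherwise
Q ~ U(10⁻³, 1).  Only the filter's combinatorics are modeled; real
search-engine Q-values are correlated across runs in ways we do not
emulate, and the true missingness structure of the deposited data is
unknown.

The optional intensity-dependent bias (amplitude × tanh of the centered
clean protein abundance, applied to every second sample within each group)
is a function of the protein's *rolled-up* abundance.  A peptide-specific
bias would be scrambled by the roll-up into scatter that no normalization
could remove; tying it to the quantity loess actually sees keeps it a
smooth, removable trend — which is what a detector-response bias is.

### Morphometry records

Animals → synapses → mitochondrial profiles.  Defaults: 6 animals per
genotype × 35 synapses (≥200 per genotype), mito-containing synapse
probability 0.36 (WT) vs 0.42 (KO), pre/post assignment at 0.5.  Log-areas
are normal with a per-animal random intercept (sd 0.15) and residual sd
0.45 around genotype×compartment means (0.10 µm², with a −20% postsynaptic
KO deficit).  The elongation index is drawn as max(1, N(mean, sd)) with a
postsynaptic KO reduction (1.55 → 1.40, sd 0.30), and the perimeter is
derived exactly as P = √(4πAE), so the planted elongation is recoverable to
machine precision when sd = 0.  Distances are uniform on 0–600 nm so the
500 nm proximity rule removes about a sixth of profiles.  One profile is
generated per mito-containing synapse; the analysis nests measurements in
animals, not synapses.

### Single-cell counts

Negative-binomial counts (dispersion θ = 2) over ~10 cortical subclasses
with per-type marker genes (8-fold), per-cell depth variation (lognormal,
sd 0.3), a target gene ("Grm5") with a strictly decreasing neuronal-leaning
profile, and planted genes whose per-type mean profiles are strictly
monotone power transforms of the target's profile (positive or
rank-reversed).  `cells_per_type` defaults to 150 and the base expression
to ~10 counts per cell: the emulated reference computes subclass averages
over hundreds of cells, and the nonzero-mean convention of the
co-expression screen only carries rate information for genes that are
actually detected — the stratum the simulated panel stands in for.  At
much lower expression or cell counts the planted monotone structure is not
recoverable by any rank-based screen; passing tests therefore speak to the
method on detected, moderately expressed genes, not to dropout-dominated
ones.

## Quantification (`quantify`)

*Filter.* A peptide is kept when, in at least ⌈n_groups/2⌉ groups, at least
(group size − 1) samples have Q ≤ 10⁻³ ("allowing one outlier within each
group"); then proteins need ≥2 surviving peptides.  The ≥half-the-groups
reading is the only one under which a protein present in one genotype only
(e.g., the knocked-out gene product) survives filtering.  Both the Q
threshold and the outlier allowance are parameters.

*Roll-up.* Protein abundance = log2 of the summed raw peptide intensities
(standard label-free practice; `mean_log2` is available as an option).
Zero/absent totals become missing values, no imputation anywhere.

*Normalization.* Fast cyclic loess: per iteration, each sample's
M = x_s − mean(all samples) is loess-regressed (locally linear, span 0.7,
via `statsmodels` lowess) on A = (x_s + mean)/2 and the fit subtracted; 10
iterations by default.  Only the iteration count and the "fast" scheme are
fixed by convention; span 0.7 and degree 1 are conventional defaults and
configurable.  Samples with <10 finite values are skipped with a warning.

*CV.* sd/mean on the raw (2^log2) scale within replicate groups, summarized
as the median over proteins.

## Differential expression (`diffexpr`)

Implemented from first principles (method-of-moments prior on
log-variances, trigamma inversion by Newton iteration); verified in the
test suite against Bioconductor limma's `eBayes` on a shared fixture
(agreement to ~1e-6 in t and p, ~1e-4 in d₀ and s₀²).  Conventions:

- p-values two-sided, **no multiple-testing correction** (the pipeline's
  stated choice); regulation called at p < 0.01;
- no intensity-dependent variance trend;
- block labels are recorded but not fitted (two-group contrast only);
- proteins quantified in one group only are reported separately with a
  fold-change versus the absent group's minimum observed abundance — an
  explicit floor convention, flagged, with no p-value;
- d₀ = ∞ (all excess variance ≤ 0) degrades gracefully to a common-variance
  z-like test; d₀ = 0 reproduces the ordinary pooled t exactly.

## Distribution tests (`mitotest`)

The randomized-selection test draws `n_iter` = 100 size-matched protein
sets without replacement from the quantified **non-target** proteins and
compares the target fold-changes with the pooled draws by two-sample KS.
Two deliberate choices keep the null calibrated (verified: p uniform over
hundreds of null replicates): draws exclude the target (overlap would
create exact ties and a conservative reference), and the p-value is
evaluated at the background's effective size m·N/(m+N) — the pooled sample
approximates the background distribution; it is not 100·m independent
observations.

The statistic behind the original "significantly different from a
randomized control" claim is not named in the source conventions, so the
method records `ks_vs_pooled_randomized_selection` in its result metadata,
and a dip-style unimodality statistic (sup-norm distance from the empirical
CDF to the nearest unimodal CDF, computed by convex-minorant /
concave-majorant decomposition over candidate modes, Monte-Carlo p against
the uniform reference) is exposed as an explicit secondary readout for
bimodality per se.

Category summaries report n, median log2FC (and 2^median), IQR and the
fraction beyond ±0.1 log2 (the reference-line convention).  ORA is a plain
hypergeometric upper tail with Benjamini-Hochberg adjustment — a declared
stand-in for web-service GO enrichment (g:SCS is service-specific and not
re-implemented).  Annotations travel as GMT files; no live database access.

## Morphometry (`morphometry`)

Pipeline order is fixed and logged: outlier removal → proximity filter →
shape metrics → nested tests.

*ROUT-style outliers.* Residuals from the median; robust scale = 68.27th
percentile of |residuals| with small-sample correction n/(n − δ), δ = 1
(the number of fitted location parameters — the exact correction used by
the original proprietary implementation is unpublished); per-point
two-sided p from t(n−1); BH-style step-down at Q = 1% flags outliers
starting from the largest residual.  Applied per genotype × compartment ×
response by default (the original's grouping is unstated; this is the
conservative reading and it is logged).  False-positive behavior is
calibrated in the tests (≤2 flags in ≥95% of clean N(0,1) samples of 100).

*Proximity rule.* Mitochondria farther than 500 nm from the active zone /
PSD lose their mitochondrion status but keep their synapse row, so synapse
denominators are unaffected.  The threshold is inclusive at exactly 500 nm.

*Nested inference.* Random-intercept LMM fitted by REML via
`statsmodels` MixedLM; Wald p on n_animals − 2 degrees of freedom.  The
reference mixed-model fitters provide no p-values, so the df convention is
necessarily ours; animal-level df is the conservative choice.  Singular
fits (animal variance → 0) fall back to pooled OLS, flagged in the result.
Calibration (200-replicate CI coverage ≥ 90%; type-I ≤ 0.07 under
animal-correlated nulls where the pooled t exceeds 0.5) is exercised in the
acceptance tests.

*Presence.* Fraction of synapses with ≥1 mitochondrion per animal, Student
t across animals.  Zero-variance degenerate cases return p = 1 with a flag.

## Cell-type enrichment (`celltype`)

Within-cell CPM before averaging (depth confounds removed; the published
EWCE procedure delegates this choice, so it is documented here).  Random
sets are size-matched only — no expression-level matching, following the
baseline procedure; GC/length matching is not meaningful for proteins.
Bootstrap count defaults to 10,000 (p stable to ~1e-4); p uses the
+1/(n+1) correction and is never exactly 0.  The multi-dataset sweep of the
original web service is replaced by looping over user-supplied specificity
matrices.  The top-N-by-fold-change selector breaks ties by smaller p, then
lexicographic ID, for reproducibility.

## Co-expression screen (`coexpr`)

CPM → log10(x+1) (pseudo-count on CPM, per the stated order) → per-gene
per-subclass mean over nonzero values → per-subclass median normalization →
Spearman vs the target over pairwise-complete subclasses (≥3 shared), BH
FDR at q < 0.05.  "Median normalized" is ambiguous (per type vs per gene);
we normalize per cell type on nonzero entries — Spearman is invariant to
any per-column monotone scaling, so the choice cannot change ρ and is
recorded only for exactness of intermediate outputs.  Spearman ρ is
computed by the exact rank-difference formula when ranks are tie-free
(monotone transforms give ρ = ±1 exactly, not 1 − ε), falling back to
Pearson-on-ranks with ties; p from the t approximation.

Known limitation: per-type depth composition induces a weak shared
component across genes' nonzero-mean profiles, which can push the realized
FDR of the screen somewhat above nominal when many true positives relax the
BH threshold.  The planted-null simulation (no correlated genes) yields ~0
discoveries, which is the calibration the screen's significance calls rely
on.

## Pipeline (`pipeline`, `cli`)

`run_all` executes all stages on one seed (child seeds via
`SeedSequence`), with analysis parameters defaulting to the study's
conventions: Q ≤ 10⁻³, ≥2 peptides, 10 loess iterations, p < 0.01, 100
randomization iterations, 500 nm, ROUT 1%, FDR 0.05, top-50 set.  The
pipeline plants the proteomic effect on *half* the mito stratum so the mito
fold-change distribution shows the two-mode structure the randomization
test is designed to expose.  The report bundle is plain TSV/JSON — plot
*data* (volcano coordinates, ECDFs, category summaries) rather than images
— and contains no timestamps, so a fixed seed reproduces it byte for byte.
The per-run provenance block records package version, seed and a hash of
all parameters.

Numerical conventions used throughout: p-values are clipped into (0, 1];
tie-breaks are deterministic (stable sorts, lexicographic IDs); all
randomness flows from explicit seeds; missing values are excluded pairwise,
never imputed.
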