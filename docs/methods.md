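# Methods

## Scope and model

`phylotai` analyses the evolutionary composition of a stress-induced
transcriptome sampled over a post-treatment time course (the motivating
design: a plant wounded and treated with herbivore oral secretions
under two temperature regimes, sampled at 0.5, 1, 5 and 11 h).  Two
per-gene evolutionary strata enter the analysis:

* **gene age** — the phylostratum PS ∈ {1..13}, the rank of the oldest
  clade on the focal species' lineage containing a detectable homolog
  (1 = cellular organisms, 13 = species-specific);
* **sequence divergence** — the Ka/Ks ratio against a close outgroup
  ortholog, a proxy for protein-level selective constraint.

The induced transcriptome age index and divergence index at timepoint
*t* are induction-weighted means over the responsive gene set:

    iTAI_t = Σ_i PS_i |FC_it| / Σ_i |FC_it|
    iTDI_t = Σ_i (Ka_i/Ks_i) |FC_it| / Σ_i |FC_it|

with |FC_it| the absolute log2 fold-change of gene *i* at *t*.  A
high-low-high trajectory (conserved mid stage) is an *hourglass*; the
inverse low-high-low shape is a *vase*.

## Phylostratigraphy

Homology hits are filtered at e-value ≤ 1e-05; viral and non-cellular
subjects are excluded; each remaining subject taxon is mapped to the
deepest lineage clade containing it, and the gene receives the minimum
(oldest) stratum over its hits — the standard min-stratum convention.
Genes with no surviving hit are species-specific (PS = n_strata).
Tightening the cutoff can only raise a gene's stratum, and adding a
hit can only lower it; both monotonicity properties are tested.  The
taxonomy is a plain child→parent mapping, so the test fixtures carry a
13-clade toy lineage instead of a full taxonomy dump; any richer
taxonomy that can be flattened to such a mapping plugs in unchanged.

## Divergence estimation

Ka and Ks are estimated with the Nei–Gojobori (1986) counting method
on gapless codon alignments: per-codon synonymous site fractions with
stop-codon targets excluded from the per-position denominators (so
S + N = 3 exactly per codon), difference counts averaged with equal
weight over all minimal mutational pathways avoiding stop
intermediates, and the Jukes–Cantor correction d = −(3/4)·ln(1−4p/3).
Proportions p ≥ 3/4 raise a saturation error rather than returning an
undefined number.  The estimator is deterministic and closed-form,
which lets the test suite verify it against exhaustive pathway
enumeration to 1e-12 on short alignments.  This is a deliberate
design choice over maximum-likelihood (GY94-style) estimation:
counting methods are desk-verifiable, and the downstream index only
consumes the ratio.  Precomputed tables from an ML tool can be
supplied via `read_divergence_table`.  Records are retained when
0.05 < Ks < 1 (both bounds strict): the lower bound removes pairs too
similar for a stable ratio, the upper bound removes saturated pairs.

## Responsive-gene selection and index computation

The expression universe is genes with TPM ≥ 1 in at least one sample
(inclusive).  A gene is responsive at *t* when |log2FC| ≥ 1
(inclusive) and adjusted p < 0.05 (strict); the Benjamini–Hochberg
step-up is provided for tables arriving with raw p-values and is
cross-checked against statsmodels.  By default the index at every
timepoint runs over the condition's **union** of responsive genes,
each weighted by its |FC| at that timepoint, so the gene set is
constant across the profile and a gene contributes little where it is
uninduced.  A per-timepoint mode (only genes differentially expressed
at *t* contribute at *t*) is available; on the synthetic scenarios
both modes agree on the qualitative profile shape.  Genes lacking a
Ka/Ks value after the Ks filter are dropped from iTDI and counted in
the log.

## Pattern tests

The permutation null shuffles the stratum values across the gene set
while the |FC| weight matrix stays fixed — gene age is exchangeable
given induction.  Statistics:

* flat-line: V = variance of the profile across timepoints;
* reductive hourglass: D = min(min_early − min_mid, min_late − min_mid)
  over the early/mid/late stage partition (default 0.5+1 h / 5 h / 11 h);
* reverse hourglass (vase): D′ = min(max_mid − max_early, max_mid − max_late),
  the exact sign-dual of D (rht(profile) = rvt(−profile), tested).

Stage statistics use within-stage minima/maxima by default; a
means-over-stages variant is behind `stage_stat="means"` because the
literature the tests descend from does not pin the reduction down.

p-values are upper-tail probabilities of the observed statistic under
a distribution fitted to the permuted statistics: a **moment-matched
gamma** for V (nonnegative and right-skewed — a Gaussian fit here
inflates the type-I error to ~0.07 at α = 0.05, while the gamma is
calibrated within binomial error) and a **Gaussian** for D and D′,
which are near-symmetric.  A rank-based empirical p is always reported
alongside.  The procedure repeats over independent runs (default
10,000 permutations × 100 runs, matching the motivating analysis) and
the aggregate p is the arithmetic mean of per-run p-values; per-run
values are retained.  Desk-scale defaults in the CLI and the
reproduction script are 1,000 permutations × 10 runs, which the
calibration and power checks show is ample at ~1,000-gene sets.

## Gene-set temporal analyses

Module assignments are consumed as input (network construction is out
of scope).  The module eigengene is the first right singular vector of
the per-gene standardized log2(TPM+1) matrix, sign-oriented to
positive mean member correlation and scaled to unit variance.  Module
membership is the Pearson correlation of a gene's log2(TPM+1) profile
with the eigengene, retained strictly above 0.75.  Module–trait
association is gene-level: per-gene Pearson correlation with the trait,
summarized per module as mean ± SE, with the top module contrasted
against each other module by the Wilcoxon–Mann–Whitney test
(gene-level rather than eigengene-level correlation is the variant
compatible with error bars and a rank test).  EC-annotated genes map
to primary vs specialized metabolism; a gene hitting both classes is
labeled specialized, the discriminative subset.  Temporal trajectories
z-score log2(median-over-replicates + 1) per gene across timepoints
(constant rows → all-zero, flagged); per-stage condition contrasts use
Welch's t-test on per-gene stage-mean z values with the conventional
*/**/***/**** tiers.

## Synthetic data

The generator is the package's test bed and defines its study
conditions: 2,000 genes split 50/50 into a young pool (strata 9–13,
Ka/Ks 0.4–1.2) and an ancient pool (strata 1–4, Ka/Ks 0.05–0.3) —
coupling age and divergence so one induction scenario drives both
indices; 15% of genes induced per timepoint with folded-normal
|log2FC| of mean 2 and padj < 0.01; under the hourglass pattern 90% of
the induced genes at early/late timepoints come from the young pool
and at the mid timepoint from the ancient pool (vase: swapped; flat:
pool-blind); non-induced genes carry N(0, 0.3) log2FC noise and
uniform padj.  Expression is TPM = 2^latent with per-module temporal
signals drawn orthogonal across (condition, timepoint) cells,
per-gene baselines, N(0, 0.5) noise and 3 replicates; the trait is an
affine function of one module's signal plus noise.  Homology hits and
mutated CDS pairs are generated consistent with each gene's true
stratum and target Ks.  Every output is a pure function of the
configuration and seed.

What the generator does **not** emulate: count-level sampling noise
and dispersion (fold-changes and adjusted p-values are drawn directly,
not fitted from counts), isoform structure, correlated induction
between neighboring timepoints, batch effects, and a realistic
taxonomy.  Passing tests therefore demonstrate that the pipeline's
inference is correct when its modeling assumptions hold, not that the
assumptions hold for any particular real dataset.

## Numerical choices and limitations

* Timepoints are decimal hours ordered numerically, never
  lexicographically; missing Ka/Ks is explicit missing, never 0.
* A degenerate permutation null (SD = 0) yields p = 1 when the
  observed statistic does not exceed the null mean, p = 0 with a
  warning otherwise.
* Sense-codon pairs always admit at least one stop-free mutational
  pathway (verified exhaustively over all 61×61 pairs); the fallback
  that counts stop-crossing steps as nonsynonymous is defensive only.
* Index profiles require a positive total |FC| weight at every
  timepoint; an all-zero column is an error naming the timepoint.
* Problem sizes in the test-suite and reproduction script (2,000-gene
  scenarios, 1,000 permutations × 10 runs, 500-replicate calibration)
  were chosen as the smallest sizes at which the calibration and power
  properties are stable across seeds.
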