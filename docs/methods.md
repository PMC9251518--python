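# Methods

`tipnet` analyses a staged bulk transcriptome — samples ordered along an
ordinal disease axis (here normal coronary angiography, NCA; intermediate
lesion, IML; acute myocardial infarction, AMI; 8 monocyte samples per
stage) — with two complementary machines: a weighted coexpression network
that summarises *persistent* covariation across all samples, and a
dynamic-network-biomarker (DNB) scan that looks for a *stage-local* burst of
variance and correlation, the statistical signature of a system approaching
a tipping point. This note records the models, the defaults and why they
are what they are, and what the synthetic studies do and do not establish.

## Expression quantification and filtering

Counts are converted to FPKM per sample,

    FPKM_gs = 1e9 * F_gs / (N_s * L_g),

with `F` the fragments assigned to gene `g` in sample `s`, `N_s` that
sample's total mapped fragments and `L_g` the gene length in bp. Each
sample is normalised by its own `N_s`; no between-sample rescaling is
applied. Genes enter the network analyses when FPKM > 0 in strictly more
than 8 of the 24 samples; the threshold is read literally (a gene detected
in exactly 8 samples is dropped) and is a parameter. Location tests run on
`log2(FPKM + 1)`; the pseudocount is configurable.

## Differential expression

Per stage pair (later over earlier), a gene is differentially expressed
when its FPKM mean ratio is >= 1.5 or <= 0.67 *and* its Benjamini–Hochberg
adjusted p is < 0.05. The location test is Welch's t on `log2(FPKM+1)` — a
deliberate, clearly-labelled stand-in for a count-model likelihood, which
is out of scope; consequences: no dispersion sharing across genes, and
fold changes are plain mean ratios (with a 1e-9 denominator guard). The
fold-change boundaries are inclusive, implemented with a 1e-9 relative
tolerance so decimal boundary cases (6.7/10) are not lost to binary
floating point.

## Coexpression network

Unsigned weighted network `a_ij = |cor(x_i, x_j)|^beta` on the expression
values as given. The soft threshold is the smallest power whose signed
scale-free fit R^2 (10 equal-width connectivity bins, log-log regression of
bin frequency on bin mean connectivity, R^2 signed by the negated slope)
reaches 0.85, else the best-fitting power. Equal-width bins are used
because quantile bins would put an identical frequency in every bin and
make the regression degenerate by construction. On desk-scale synthetic
data the 0.85 criterion is rarely attained — approximate scale-freeness is
an empirical property of genome-wide real networks — so the planted-module
experiments fix `beta = 8`, the value selected in the motivating study.

The adjacency is smoothed into the topological overlap measure

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),

`l_ij = sum_u a_iu a_uj` (u != i, j), and `1 - TOM` is clustered by
average linkage. The dynamic tree cut is implemented in its simplified
"tree" form: a static cut at 0.99 of the maximum merge height, after which
any cluster holding more than 40% of the genes is re-cut recursively at the
same relative height within its own subtree. The descent matters because
TOM dissimilarities saturate near 1 between unrelated groups: distinct
modules can merge just below a single global cut, while genuinely tight
clusters re-merge immediately at low heights and stop the recursion.
Clusters under `minModuleSize = 30` are pooled into grey (label 0).
Modules whose eigengene dissimilarity `1 - cor` falls below 0.25 are merged
iteratively, closest pair first. No post-hoc gene reassignment between
modules is performed (the reassignment threshold is in effect zero).

Module eigengenes are the first principal component of the module's
gene-standardised expression, scaled to unit sample variance and oriented
to correlate non-negatively with the module's mean profile. Module–trait
association is the Pearson correlation of each eigengene with each trait
(disease stage encoded 0/1/2), with the two-sided p from
`t = r sqrt((n-2)/(1-r^2))`. Gene significance (GS) is the absolute
gene–trait correlation (a signed variant is available); hub genes satisfy
|module membership| > 0.8 and GS > 0.2, both strict.

## DNB composite index and tipping-stage search

For a candidate gene group evaluated within one stage's samples:

    CI = SD_d * PCC_d / PCC_o

with `SD_d` the mean per-gene sample SD (n-1), `PCC_d` the mean absolute
Pearson correlation over within-group pairs and `PCC_o` the mean absolute
correlation between group and non-group genes. Pairs involving constant
genes contribute 0 with a warning; `PCC_o = 0` is flagged as an explicit
infinity rather than a silent large number. The stage with maximal CI is
the tipping stage; ties resolve to the earliest stage with a flag.

The published analyses never state how their DNB gene set was selected, so
the candidate search here is this package's own design, with every knob
exposed: within each stage genes are clustered on `1 - |PCC|` (average
linkage) and the tree is cut at a grid of heights (0.3, 0.4, 0.5, 0.6);
clusters of at least `min_size` (engine default 30, matching the
coexpression minimum module size) become candidates. Each candidate is
scored by the fold elevation of its peak-stage CI over the mean CI of the
other stages. The reported DNB group is the union of the candidates
scoring within 70% of the best whose CI peaks at the best candidate's
stage, and the per-stage CI, score and tipping call are recomputed on that
pooled membership. Two reasons: single-cut winners are typically fragments
of the underlying coordinated group, and pooling near-ties reassembles it;
and on data with no stage-specific group the near-ties are unrelated
chance clusters, so the pooled profile flattens and the reported fold
elevation honestly approaches 1 instead of inheriting the selection-biased
maximum over hundreds of candidates. The full audit trail (every candidate
with its per-stage CI and score) is retained in the result.

CI correlations default to FPKM as given; all recovery experiments pass the
`log2` switch (`log2(FPKM+1)`) because the synthetic generator plants
structure on the log scale and the lognormal raw scale attenuates
correlations in a magnitude-dependent way.

## Cohort statistics

Continuous baseline covariates reported as group mean +/- SD are compared
by one-way ANOVA reconstructed from the summaries (size-weighted grand
mean; pooled within-group variance). Categorical covariates get both the
Pearson chi-square (no continuity correction) and the Freeman–Halton exact
test: full enumeration of tables with the observed margins, p = total
probability of tables no more probable than the observed one, with a 1e-12
relative tolerance on the "no more probable" comparison so that exactly
tied tables (common in small balanced designs, where they make p = 1.000)
are not excluded by floating-point noise. Recomputing the published
baseline table from its printed summaries reproduces the BMI (p = 0.062)
and LVEF (p = 0.136) rows and the sex row (exact p = 1.000); the printed
age-row p (0.741) is not reproducible from its own printed summaries
(recomputation gives 0.64) and is treated as an in-table inconsistency, as
is the family-history row.

## Synthetic studies: what is planted and what passing tests show

`simulate_study` draws log2-scale expression
`x = mu_g + signal + noise_sd * eps` and exponentiates; counts are obtained
by inverting the FPKM formula against per-gene lengths (200–10,000 bp) and
a 20M-fragment library, and the FPKM actually analysed is recomputed from
those rounded counts, so quantisation is part of the test conditions.
Defaults mirror the motivating design: 3 stages x 8 samples, 2000 genes,
eight modules with the published module sizes (575…40) and mixed-sign
stage loadings (+0.64 to ±0.2), a 103-gene DNB group tipping at the middle
stage, and 10% of background genes essentially silent (mu ~ N(-12, 2)) so
the detection filter has real work.

Module `m` genes share `lambda_m * stage_z + sqrt(1-lambda_m^2) * (w*G +
sqrt(1-w^2)*eta_m)` where `stage_z` is the standardised ordinal stage, `G`
a global per-sample factor (weight `w = 0.5`) that couples modules — and
the DNB group, outside its planted stage (loading 0.4) — within stages,
and `eta_m` is module-private. At the planted stage the DNB group's
coupling to `G` is scaled by `1 - dnb_cross_corr_drop` (default: removed)
and replaced by a DNB-private factor scaled so the within-stage SD is
exactly `dnb_sd_inflation` (default 3) times its baseline and the expected
intra-group correlation is `dnb_intra_corr` (default 0.8). The private
factor is standardised over the stage's 8 samples so the planted spike
holds in each realisation: with one shared factor and 8 samples the
realised spike would otherwise vary by a factor ~2 across seeds, and
recovery experiments would be grading label noise rather than the
detector.

What the generator does *not* emulate: count overdispersion beyond
lognormal-plus-rounding, batch effects, outlier samples, gene-length or
GC bias, and any real regulatory topology — modules are single-factor
blocks. Passing recovery tests therefore show that the implementations
detect the structures they claim to detect at the study's sample sizes;
they do not certify performance on real monocyte data.

## Experiment sizes and evaluation choices

- Module recovery: 20 studies of 180 genes (three planted modules of
  60/50/40 at |loading| 0.7, other parameters at defaults), WGCNA on
  `log2(FPKM+1)` at beta = 8; success is adjusted Rand index >= 0.8
  against the planted partition, measured on the detection step
  (`cluster_modules`). The eigengene merge is assessed by its own
  threshold tests instead, because same-trait planted modules truly
  correlate ~0.55 and, at 24 samples, the merge rule occasionally and
  *correctly* merges them when the estimated eigengene correlation crosses
  0.75 — counting that against recovery would measure the sample size, not
  the detector.
- DNB recovery: 20 studies at full default scale; success is Jaccard >=
  0.5 against the planted 103 genes plus the correct tipping stage. Null
  false-alarm: 20 studies with no planted structure at all; the reported
  fold elevation of the selected group stays below 2.
- Null calibrations: 200-replicate uniformity checks (KS) for
  module–trait p-values and ANOVA-from-summary p-values; 1000 null genes
  for the DEG rejection rate.

These sizes keep the full suite and the acceptance script each within a
few minutes on a single core while leaving the statistical margins wide
(observed rates in repeated disjoint seed batches: module recovery
~58-60/60, DNB recovery ~57/60).

## Known limitations

- The Welch-t DEG caller is a stand-in; counts-based callers with
  dispersion shrinkage will differ, particularly at low counts.
- The soft-threshold scan's scale-free criterion is uninformative below a
  few thousand genes; the chosen-power fallback (best fit) then tends to
  the scan boundary.
- The DNB candidate search sees only clusters that form under
  within-stage correlation clustering; a coordinated group whose members
  never co-cluster at any cut height is invisible to it.
- The Freeman–Halton enumeration is exponential in table size; it guards
  itself (~2M partial tables) and larger tables must use chi-square.
- With 8 samples per stage, every correlation-based quantity carries
  large sampling noise; the per-stage CI of even a genuinely stationary
  coordinated group fluctuates by a factor ~2 across stages. Tipping
  calls on single small cohorts should be treated as hypotheses.
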