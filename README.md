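# tipnet

Staged-transcriptome network analysis: coexpression modules, dynamic
network biomarkers, and tipping-point detection.

## The problem

Diseases that progress through ordered stages — here coronary artery
disease, profiled in circulating monocytes across normal coronary
angiography (NCA), intermediate lesion (IML) and acute myocardial
infarction (AMI), 8 patients per stage — often deteriorate abruptly rather
than smoothly. Standard analyses (differential expression, weighted gene
coexpression network analysis) characterise how expression differs between
states, but they are blind to the *pre-disease* state: the stage just
before the abrupt transition, when intervention is most valuable.
Dynamic network biomarker (DNB) theory predicts that, approaching a
tipping point, a group of genes appears whose

1. expression variability rises sharply,
2. mutual correlation rises sharply, and
3. correlation with the rest of the transcriptome falls.

The three signatures combine into the composite index

    CI = SD_d · PCC_d / PCC_o

(mean within-group SD × mean within-group |Pearson r| ÷ mean group-to-rest
|Pearson r|), computed per stage; the stage where the selected group's CI
peaks is the inferred tipping point.

`tipnet` implements the full pipeline for anyone analysing staged
expression studies: FPKM quantification and filtering, pairwise
differential expression (fold change ≥ 1.5 or ≤ 0.67, BH-adjusted
p < 0.05), a from-scratch unsigned WGCNA (soft threshold by scale-free
fit, topological overlap, simplified dynamic tree cut, module eigengenes,
module–trait correlation, hub genes at |MM| > 0.8 & GS > 0.2), the DNB
composite-index engine with candidate search and audit trail, gene-list
intersection and hypergeometric over-representation, and the
baseline-characteristics statistics (ANOVA from summaries, chi-square and
exact Freeman–Halton r×c tests). A synthetic-study generator with planted
modules and a planted DNB group provides ground truth for every step.

## Worked example

The numbered scripts under `analysis/` run the full study on a simulated
cohort with planted truth (3 stages × 8 samples, 2000 genes, the published
module sizes, a 103-gene DNB group planted at IML):

```bash
python analysis/01_simulate_study.py
python analysis/02_cohort_statistics.py
python analysis/05_dnb_tipping_point.py
```

`02_cohort_statistics.py` re-derives the cohort table's group comparisons
from the published per-group summaries alone:

```
BMI ANOVA p = 0.062, LVEF ANOVA p = 0.136, sex exact p = 1.000
No baseline covariate separates the three stages at alpha = 0.05.
```

`05_dnb_tipping_point.py` runs the DNB engine and prints the per-stage
composite index of the selected group:

```
selected DNB group: 131 genes (fold elevation 6.8)
per-stage composite index:
  NCA: SD_d = 0.54, PCC_d = 0.37, PCC_o = 0.31, CI = 0.64
  IML: SD_d = 1.48, PCC_d = 0.80, PCC_o = 0.28, CI = 4.22
  AMI: SD_d = 0.57, PCC_d = 0.36, PCC_o = 0.34, CI = 0.60
tipping stage: IML
vs planted truth: Jaccard = 0.73, planted tipping stage = IML (recovered)
```

The CI of the selected group is flat at NCA and AMI and spikes at the
middle stage — all three DNB criteria fire there (SD up ~2.7×, internal
correlation up ~2.2×, external correlation down) — so the engine places
the tipping point at IML, matching the planted truth. Scripts 03, 04 and
06 add the differential-expression contrasts, the coexpression modules
with their stage correlations and hub genes, and the DEG/hub/DNB overlap
report whose pooled list is the final key-gene set.

The same machinery is scriptable via the `tipnet` CLI
(`simulate`, `fpkm`, `filter`, `deg`, `wgcna`, `dnb`, `integrate`, `ora`,
`cohort-stats`, `run`) or the library API (`tipnet.simulate_study`,
`tipnet.run_pipeline`, ...). See `docs/methods.md` for the models,
defaults and their rationale.

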