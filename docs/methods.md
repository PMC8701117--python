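# Methods

This note documents the models, parameter choices, and numerical decisions
behind `twindiff`, and what the synthetic-data tests do and do not establish
about real data.

## Paired differential methylation

β-values (methylated signal / total signal, in [0, 1]) are compared within
discordant MZ twin pairs: Δβ = β_affected − β_unaffected, so hypomethylation
in disease is negative. The per-probe test is the textbook one-sample t on
the per-pair deltas (df = n_pairs − 1), two-sided, with Benjamini–Hochberg
FDR across probes. DM calls require q < 0.05 **and** |mean Δβ| > 0.085, both
strict inequalities. Rationale for the effect threshold: it is the
AUC-selected whole-blood threshold from the DM-DE integration (below), so the
methylation screen and the expression link use one consistent cutoff.

Numerical decisions:

* **Zero-variance deltas.** With three pairs, identical deltas happen. Such
  probes are flagged degenerate (sd ≤ 1e-12 to absorb float rounding), given
  p = 1 when the mean is 0 and p = 0 otherwise, and excluded from the FDR
  correction (q = NaN) so a degenerate artifact can never be called DM via a
  zero p-value.
* **QC.** Probes with a detection p-value above 1e-5 in *any* sample are
  removed before analysis when a detection matrix is supplied.
* **Known limitation.** A paired t with 2 residual df cannot produce
  p-values below ~2/t²; published per-probe p-values far below that floor
  (whatever pooling produced them) are treated as input data in the bundled
  tables, not as something this test statistic reproduces.

## IFN-signature masking

To ask whether a dominant interferon signature hides independent signals, the
per-sample covariate c is the mean β over the most significant CpG of each
interferon-regulated gene in the DM set; every probe genome-wide is
residualized on c by OLS (with intercept) across samples, and the paired
pipeline reruns on residuals.

An identifiability caveat the implementation makes explicit: when the latent
IFN factor barely varies within affection groups (as in a 3-pair discovery
design), c is collinear with affection status and the regression removes
*every* within-pair group effect — factor-driven or not. Masking can separate
factor-driven from independent effects only when the factor varies within
groups; the test suite demonstrates both regimes (full masking at the
discovery design; an independent 25-probe block surviving 25/25 in a 20-pair
cohort with a dispersed factor).

## Genomic context

A CpG island is a run > 200 bp with GC > 55% and observed/expected CpG ratio
> 0.6, O/E = (#CpG · L)/(#C · #G). Detection is Takai–Jones-style: slide a
200-bp window (configurable step), flag qualifying windows, merge
overlapping/adjacent flags, then trim each merged region one terminal base at
a time (removing the base whose loss leaves the better GC + O/E; ties trim
right) until the whole extent qualifies; regions that cannot be trimmed to a
qualifying extent longer than 200 bp are dropped. Every reported island
therefore re-measures as valid.

Context labels: shores are the (0, 2 kb] flanks, shelves (2 kb, 4 kb],
with N = lower-coordinate side irrespective of strand (450k manifest
convention); equidistant ties go to the lower-coordinate island; everything
else is open sea. Island enrichment of a DM set is an exact two-sided
binomial test of the island count against the array background fraction
(1/3 of array CpGs in islands).

## Replication concordance

At the discovery DM probes, the replication cohort's paired deltas are
recomputed per cell type; a probe is concordant when the replication mean Δβ
has the discovery sign (an exactly zero replication delta counts as
discordant — conservative), and significantly concordant when additionally
the replication paired-t p < 0.05 with the replication cohort's own df.
Global concordance is an exact binomial sign test against 0.5.

## Differential expression

Features in the lower half of the *range* of mean log2 intensities — the
midpoint of (min, max) of feature means, read literally, not the median — and
features without gene annotation are dropped. The two-group moderated t
shrinks per-feature pooled variances toward a scaled-inverse-χ² prior whose
hyperparameters (d0, s0²) come from moment-matching the log-variances
(digamma/trigamma inversion, Newton). When the observed log-variance spread
is no larger than sampling noise (or too few features are available), the
estimator falls back to full pooling: d0 = ∞, s0² = mean variance, and the
total df is capped at the pooled residual df across features. Zero sample
variances are offset to 1e-5 × median before taking logs. The implementation
reproduces the reference R implementation (limma's eBayes) to ~1e-4 relative
on t; that cross-check runs in the test suite via Rscript.

Activity stratification: active disease is SLEDAI ≥ 6 (the table convention;
a strict "> 6" mode exists since both conventions appear in the literature);
samples without SLEDAI are excluded from stratified runs. Native and custom
annotation runs of a study are merged at q < 0.2 keeping the smallest-p
record per gene (ties: larger |logFC|, then feature id).

## DM-DE integration

The Δβ threshold per expression cell type maximizes the AUC of the binary
classifier X = 1[Δβ < t] for Y = 1[logFC > 0]; for a binary predictor the
AUC equals (sensitivity + specificity)/2. The grid spans [−0.15, 0] in 0.005
steps — the published thresholds (−0.085 whole blood, −0.055 monocytes,
−0.08 B cells, −0.055 T cells, shipped in `datasets`) are all grid points —
and ties break toward 0, the least stringent (gene-retaining) choice. A
logistic-regression reading of the same selection is deliberately not the
default: the grid scan over the binary rule is the reproducible procedure,
and the two coincide for a binary predictor.

DM-DE genes: ≥ 1 CpG with mean Δβ < t* and methylation p < 0.01, joined to
expression records on gene symbol, keeping the smallest-p CpG per gene; genes
with non-positive or missing logFC stay in the table flagged
`upregulated=False`, because the published reports include such rows.

LFC profiles are clustered with complete linkage on Euclidean distance;
non-significant entries are imputed as 0 for clustering (matching how the
published heatmaps render NS) and *dropped* for correlations. Cross-condition
correlations default to Spearman rank correlation on complete pairs — that is
the method under which the published within-experiment (0.95, 0.99) and
cross-tissue (0.66) coefficients reproduce from the bundled tables; Pearson
is available via `method="pearson"` (it gives 0.96, 0.99, 0.76 on the same
data).

## Network clustering

MCODE operates on the unweighted topology; STRING-style confidence scores
only gate edges (default minimum 0.4; 0–1000 exports are auto-normalized) and
annotate output. Determinism: seeds and expansions break ties by node id;
clusters are vertex-disjoint by visited-marking, must contain a 2-core, and
the haircut iteratively strips singly-connected members. The packaged edge
list over the DM-DE genes is synthetic (see `string_edges_synthetic.tsv`): a
stand-in constructed to mirror the described two-cluster topology (an
IFN-inducible clique; a nucleic-acid-sensing clique centred on DDX58/RIG-I)
for regression testing, carrying no real interaction evidence.

## Drug annotation

Drug tokens parse as `Name^<colts> <flags>^`: integer superscripts are CoLTS
repositioning scores (validated to [−16, +11]), letters are status flags
(F approved, D trial, G GRAS, T lupus therapy, FW withdrawn). Names are
canonicalized by whitespace-trim and case-fold; slash variants
("Rapamycin/Sirolimus") and collective entries ("Imidazoles") are single
entities. Summaries count canonical drugs once regardless of how many genes
or sources reach them. CoLTS ranking is descending, missing scores last,
ties alphabetical.

## Synthetic data: what it emulates and what it does not

β-values are generated on the logit scale — baseline + loading × latent
activity + Gaussian noise, inverse-logit back — so additive noise can never
leave [0, 1]; clamping is monitored and warns if > 0.1% of values touch the
boundary. One scalar latent IFN activity per sample (affected twins centred
at 1, unaffected at 0) drives all signal probes, mirroring the analysis
assumption that a single covariate can remove the whole signature. Loadings
are calibrated per probe so an affected twin at mean activity shifts by
exactly `effect_delta` on the β scale (default −0.2).

Default noise (`beta_noise_sd=0.008` logit ≈ 2e-3 β-scale;
`latent_ifn_sd=0.01`) represents technical-scale within-pair variation. This
is a deliberate design-stage choice: with 2 residual df, BH correction across
2000 probes requires within-pair delta sds below ~0.005 for a −0.2 effect to
be detectable at q < 0.05 at all — the same arithmetic implied by discovery
data in which every reported site cleared p < 1.06e-7 with three pairs.

Expression: signal genes are placed in the bright half of the intensity range
(so the intensity filter, which removes the dim half of the range, never
removes planted signal by construction), upregulated in cases by
`planted_logfc` (default 2); SLEDAI is uniform over 0–20 integers so both
activity strata are populated. The synthetic genome plants three
verified-by-construction CpG islands in AT-rich flanks wide enough that
shore/shelf windows never overlap, and probes are placed at known offsets
(island centre, ±500 bp, ±3 kb, ±8 kb) from *detected* islands so manifest
labels are consistent with the detector.

What passing synthetic tests does **not** show: robustness to cell-type
composition differences, batch effects, probe cross-reactivity, or
non-Gaussian β noise — none of which the generator emulates (deconvolution
and normalization are out of scope; normalized matrices are inputs). Results
on real cohorts depend on those factors.

## Problem sizes

Tests and the acceptance script run at 2000 probes × 3 pairs (discovery),
4 pairs (replication), 20/20 expression samples, 300-gene threshold scans ×
100 replicates, and ≤ 8-node graphs for exhaustive MCODE oracles — sizes at
which every brute-force oracle is exact and the whole suite completes in
well under a minute.
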