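# Methods

This note documents the models, estimators and numerical choices behind
`screenbias`, and what the synthetic-data experiments do and do not
demonstrate about real screens.

## Data model and conventions

All matrices are genes (or guides) × models. Gene identity is the bare
HGNC-style symbol; DepMap-style `"SYMBOL (ENTREZ)"` headers are stripped on
load, since every downstream join is symbol-keyed. Coordinates are 1-based;
a gene belongs to the p arm when its start position lies before the
chromosome's centromere, q otherwise (the start position alone decides —
using the midpoint changes the assignment only for genes straddling the
centromere, which are rare and ambiguous anyway). A packaged table of
approximate GRCh38 centromere midpoints is used by default and can be
overridden with a two-column CSV when the annotation follows another build.
Cohort construction intersects models and genes across the CRISPR,
copy-number and expression inputs; a gene missing CN or TPM after that
intersection is excluded from CN-dependent metrics only.

## Preprocessing

Guides carrying any disqualifying library QC flag (ambiguous alignment to
one or several genes, no alignment, intergenic-only alignment, or being the
sole passing guide of a gene) are removed. Replicates are removed when mean
reads/guide < 185, when their best Pearson correlation with a sibling
replicate over high-variance genes is < 0.41, or when their NNMD exceeds
−1.25; thresholds are configurable with these values as defaults. Two
under-specified points are resolved as follows and recorded in the QC
report: replicate correlations are computed on **gene-level** profiles, and
"high-variance genes" defaults to the top 100 genes by variance of the
preliminary gene-level LFC (both configurable).

LFCs use a pseudocount of 1 and reads-per-total normalization:
`LFC = log2((c_s + 1)/T_s) − log2((c_p + 1)/T_p)`; with several plasmid
samples the log-normalized plasmid abundances are averaged into one
reference. Replicate LFCs are averaged per model; gene-level LFC is the
median over a gene's surviving guides (even counts: midpoint of the central
pair, the standard convention used for every median in the package).
Profile scaling is the per-model affine map sending the non-essential
median to 0 and the essential median to −1; it is idempotent and
rank-preserving.

## Corrections

Both corrections are pure per-(screen, arm) shifts, hence idempotent and
rank-preserving within each (screen, arm); genes without an arm assignment
are never shifted, because both estimators are arm-scoped.

*Arm-median alignment.* `e_g − (m_s − med(m_s))` on arms with > 5 genes,
counted on the shared gene axis (the alternative — counting per screen —
cannot differ here because the gene axis is dense after intersection). With
a single screen `med(m_s) = m_s` and the correction is the identity. Note
the formula aligns each screen to the arm's cross-screen median level; it
deliberately does not force the arm median to zero, so arm-level biology
shared by all screens survives.

*Unexpressed-gene centering.* Per (model, arm), the mean LFC of the model's
unexpressed genes (TPM strictly < 1) on the arm is subtracted, so the
corrected unexpressed mean is exactly zero. When an arm has no unexpressed
gene in a model, that (model, arm) is left unchanged and counted in the
returned summary — subtracting any global fallback would couple arms.

## Proximity-bias quantification

Per-gene profiles (rows across models) are compared by **uncentered**
cosine similarity; a centering flag turns this into Pearson correlation for
sensitivity analysis but is off by default. All off-diagonal similarities
are quantile-normalized jointly to a normal shape with mean 0 and sd 0.2 by
mapping the midrank `r` to `0.2·Φ⁻¹((r − 0.5)/n)`. Because the map is
strictly rank-preserving, it cannot change any Brunner-Munzel probability;
it is retained as the canonical intermediate (and for heatmap displays).

Per arm, the Brunner-Munzel probability that an intra-arm similarity
exceeds an inter-arm one is estimated from combined-sample midranks in
O((n+m) log(n+m)); ties contribute 1/2, and the estimator is exactly equal
to the brute-force pair count (property-tested). The dataset summary is the
unweighted mean of per-arm BMPs; arms with fewer than 2 mapped genes are
excluded. At genome scale the inter-arm pair set is quadratic, so it is
subsampled to a per-arm budget (default 10⁶) with a seeded generator; at
the scales where the exact value is computable, the subsampled BMP agrees
within 0.01. TP53 stratification reruns the entire pipeline (cosine →
normalization → BMP) within the wild-type and mutant blocks and reports the
mean per-arm mutant/wild-type BMP ratio.

## CN-bias quantification

Amplified unexpressed positives are the unexpressed genes (TPM < 1) at or
above the per-model (1 − 0.01) CN quantile taken over **all** genes;
remaining unexpressed genes are the outgroup. The AURC integrates the
recall-vs-rank curve by the trapezoidal rule over the rank index and
normalizes by K − 1, so a random ranking scores ≈ 0.5; LFC ties are broken
by gene id for determinism.

The ARD is the mean over integer-CN bins of |bin median / bin sd|. Bins
with fewer than 5 members or zero sd are excluded by default, because empty
or singleton integer bins are inevitable at high CN and would make the
statistic undefined or wildly unstable; the raw form (sum over all defined
bins divided by the maximum CN value) is available behind a flag. The
dataset-level ARD pools unexpressed (gene, model) observations across
models before binning.

## Quality and biomarker metrics

Screens are rank-based classifiers with LFC ascending. AUROC uses the
rank (Mann-Whitney) identity; AUPRC integrates the precision-recall curve
by trapezoids. The per-screen classification uses raw LFCs; per-model
scaling is rank-preserving so scaled profiles give identical values. NNMD
uses the **unscaled** median absolute deviation by default (the 1.4826
normal-consistency factor is behind a flag); only the ratio convention
changes between the two, not any comparison between methods.

For recall at 5% FDR, PPV_k is computed over the ranked union of essential
and non-essential controls, and k* is the **deepest** rank with
PPV_k ≥ 0.95 — PPV is not monotone in k, and the deepest admissible rank is
what "the lowest LFC threshold still satisfying the precision constraint"
means operationally. Recall of a gene set is the fraction of its screened
members at or below the LFC at rank k*. When no rank satisfies the
constraint, recalls are 0 and the result is flagged.

The oncogene-addiction ROC pools (oncogene, model) instances across screens
— mutated oncogenes as positives, wild-type-and-unexpressed as negatives,
oncogenes lacking either dropped — ranked by scaled LFC. The biomarker scan
performs, for every (tissue, CFE, SSD gene) with ≥ 3 models in both strata,
a two-sided pooled-variance t-test (Welch behind a flag), and applies
Benjamini-Hochberg jointly across **all** tests of the scan, not per
tissue. Mutation calls are consumed as a binary matrix; deriving them from
variant files is out of scope.

## Synthetic screen generator

The generator emulates the statistical structure of dependency-map data at
desk scale; defaults describe a typically biased dataset of 20 models and
1000 genes on 5 chromosomes (10 arms of 100 genes):

| parameter | default | meaning |
|---|---|---|
| `essential_fraction` / `essential_effect` | 0.1 / −1 | common-essential genes and their LFC |
| `noise_sd` | 0.2 | gene-level residual spread after guide collapse |
| `cn_bias_slope` β | 0.1 | depletion per copy above diploid, b = −β·max(0, CN−2) |
| `arm_offset_sd_wt` / `arm_offset_sd_mut` | 0.1 / 0.3 | per-(model, arm) offset spread by TP53 status |
| `fraction_unexpressed` | 0.3 | genes in the constitutively low-expression class (roughly the fraction of genes with TPM < 1 in a typical cell line) |
| `fraction_tp53_mutant` | 0.5 | TP53-mutant models |

Copy number is integer 0–8 with mode 2, with occasional contiguous
amplified runs per (model, chromosome) plus sparse single-gene deviations,
so the top-1% CN threshold is meaningful. TPM is lognormal with three gene
classes (unexpressed, variably expressed — the pool oncogenes are drawn
from, so that wild-type-unexpressed negatives exist — and expressed).
Unexpressed genes carry true effect 0: that targeting them is
fitness-neutral is the premise of both the AURC metric and the
unexpressed-gene centering. The observed LFC decomposes exactly as
`effect + cn_bias + arm_offset + noise` and all components are stored, so
`truth_reconstruction_check` verifies the bundle to 10⁻¹⁰.

Two generator design points deserve emphasis. First, arm offsets are drawn
per (model, arm) with TP53-status-dependent spread and are then centered to
zero median across models within each arm: the offsets model
*screen-specific deviations* from the arm's consensus level, because a
component shared by every screen is observationally equivalent to true
arm-level biology and no cross-screen method could (or should) remove it.
Second, every output component draws from its own RNG stream spawned from
the master seed, so enabling count emission or adding biomarkers never
perturbs the other components.

Optional count emission inverts the gene LFCs into negative-binomial read
counts (dispersion 10) around a plasmid baseline of 500 mean reads/guide,
with 2 replicates per model and guide-level jitter (sd 0.1), to exercise
the preprocessing chain end to end.

**What the simulations do not show.** The generator plants additive,
arm-constant offsets and a piecewise-linear CN bias; real screens show
nonlinear, segment-heterogeneous CN effects, partial-arm truncations,
guide-efficiency variation and off-target structure. Passing the planted-
bias recovery tests therefore demonstrates that the estimators measure and
the corrections remove *arm-scoped additive* bias under realistic noise —
not that they handle every bias mechanism of real data.

## Experiment scales and numerical choices

The calibration and recovery experiments run on 1000-gene × 20-model
bundles (10 arms × 100 genes): large enough that per-arm BMPs and per-model
AURCs are stable, small enough that the whole suite runs in well under a
minute per experiment. Null calibration uses 10 seeds; bias-recovery and
CN-monotonicity experiments use 3–5 seeds per condition; the pure-null
biomarker FDR experiment uses several hundred small scans because the
false-discovery proportion of a single null scan is almost binary. The
CN-monotonicity and ARD experiments switch arm offsets off to isolate the
CN axis; the quality-preservation experiments use the fully biased default
so the corrections have something to remove. Degenerate inputs fail loudly:
zero-total count samples, screens where the control medians coincide, arms
with no unexpressed genes (skipped and counted), empty Brunner-Munzel
samples, and all-degenerate CN bins all raise or warn as documented in the
API.

## Known limitations

* The benchmark evaluates external correction methods only through their
  output matrices; it never executes them.
* SSD gene lists and CFE catalogs are inputs; the package does not derive
  them.
* The packaged centromere table is approximate and build-specific; supply
  matching coordinates for real annotations.
* The paired t-test contrasting corrected vs uncorrected per-arm BMPs
  treats arms as exchangeable units; arms share genes' model axis, so the
  pairing removes arm-level variance but p-values should be read as
  descriptive.
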