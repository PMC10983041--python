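# Methods

This note documents the models, conventions and design choices behind
`svimpact`: what each stage computes, the defaults and why, what the
synthetic cohort does and does not emulate, and the numerical edge cases.

## Coordinates and SV representation

All intervals are 0-based half-open; breakpoints are single 0-based base
offsets. An SV record is a breakpoint pair with a class (DEL, DUP, INV,
TRA) and an origin (germline/somatic); intrachromosomal records are
canonicalized to `pos_a <= pos_b`, and a record is a TRA exactly when its
breakpoints sit on different chromosomes. All slop comparisons are
inclusive (a 200 bp slop accepts a 200 bp offset and rejects 201 bp).

## Call-set harmonization and recurrence

Two germline caller replicates are consensus-merged per patient: a record
from caller A is kept iff caller B has a record with the same chromosome
pair and both breakpoints within 200 bp. Matching is one-to-one, greedy
by ascending total breakpoint distance with ties broken by input order,
and the emitted coordinates are caller A's. One-to-one matching was
chosen over many-to-many because duplicated emissions would inflate
downstream recurrence counts. Class agreement is *not* required by
default (matching is purely positional), but a `require_class_match` flag
is available.

Cross-patient recurrence flags each record whose corresponding
breakpoints (A to A and B to B after canonical ordering — never
cross-matched, to preserve SV geometry) lie within 10 bp of another
patient's SV; `either_shared` requires one matching breakpoint,
`both_shared` both. A patient's own other SVs never count. Catalog
overlap (e.g. against a known-variant database) uses the same both-
breakpoint rule; reciprocal-overlap matching is not implemented.

## Breakpoint matrices

For a window `w` of gene `g`, the unweighted matrix entry is 1 iff any
breakpoint of any SV of the sample falls in the window; both breakpoints
of every SV contribute independently, and each mate of a translocation
counts on its own chromosome. Upstream/downstream windows are
strand-aware (upstream = 5′ of the gene on the gene's strand) and exclude
the gene body, so a breakpoint inside the gene is coded only by the
gene-body (or 3′UTR) window — this prevents the same geometry from being
double-coded across windows and is configurable in principle via the
window intervals. Genes without a 3′UTR are skipped by the 3′UTR window;
genes on chromosomes absent from the cohort keep all-zero rows.

The 1 Mb flank matrix is anchored at the gene start and weighted by
relative distance: `entry = 1 − d/extent` for the nearest breakpoint with
`d <= extent` (default 1 Mb), else 0. The linear decay is a deliberate,
transparent choice — the weighting idea is that nearer breakpoints count
more, and any monotone decay would serve; linear is trivially testable
(`d = extent/2` gives exactly 0.5) and the formula is isolated in one
function should a different kernel be wanted.

## Association model

The response is `log2(x + 1)` of the linear-scale expression value; the
pseudocount-1 base-2 log is fixed throughout (robust at zero, effect
sizes read as log2 fold changes). The predictor of interest is the gene's
breakpoint value. Three covariate tiers: `none` (intercept only),
`tissue` (tissue-of-origin indicator contrasts, reference = most frequent
tissue, which keeps the design full-rank and leaves the breakpoint
coefficient invariant to label order), `full` (tissue + per-gene copy
number + ploidy + purity; copy number entered as raw copies with ploidy
as a separate term, matching the covariate list as stated). Fits use
ordinary least squares (statsmodels); the reported p is the two-sided p
of the breakpoint coefficient, which with no covariates and a binary
breakpoint is algebraically the pooled two-sample t-test p (asserted to
1e-10 in the tests).

Degenerate designs never crash: constant expression, constant breakpoint,
or true rank deficiency flag the gene untestable (p absent); constant
*covariate* columns (e.g. a flat copy-number profile for a gene) are
simply dropped, since they carry no information; a single-tissue cohort
drops the tissue term with a warning; samples with missing covariates are
dropped listwise and logged.

Genes with fewer than 3 carriers are excluded before FDR.
Benjamini–Hochberg q-values are computed within the tested gene set of
one (window, model) run — per-window FDR, no cross-window pooling.
Direction is the sign of the breakpoint coefficient. The germline/somatic
overlap takes genes significant in both origins (p < 0.01 each, full
model) for the same window with the same direction.

## Mechanism layers

*Enhancer duplication*: an SV is an enhancer-duplication candidate for a
gene iff it is a DUP, both breakpoints lie in the gene's 100 kb flank
(either side) without entering the gene, the SV does not span the gene,
and the SV interval contains at least one whole enhancer (partial overlap
available behind a flag, off by default — "spanning" is read as whole
containment). Enrichment of this class among significant up-associations
is a Pearson chi-squared on the 2×2 table, no continuity correction, with
a warning when any expected cell is below 5 and an absent p on a zero
margin.

*SV class by direction*: each significant gene is attributed to every SV
class with a breakpoint in its window; per class, a 2×2 of (class vs
other) × (increased vs decreased expression).

*Cytobands*: per patient and band, the breakpoint count inside vs outside
the band is tested by a 1-df chi-squared goodness of fit against the
expectation proportional to the band's share of total genome length; this
yields one p per band per patient, and the cohort summary lists bands
enriched below 1e-4 in at least 20 patients (both thresholds
configurable). A joint goodness-of-fit across all bands was rejected
because it gives one p per patient, not per band.

*Copy categories*: ploidy-corrected copies = copies × 2/ploidy (diploid
equivalent; the correction formula is ours). Bins are exact at the
printed cutoffs: >5 amplification, [3, 5] copy gain, [0, 1] copy loss,
(1, 3) neutral. Gene-spanning DUP/DEL events are cross-tabulated against
the categories with DUP-gain and DEL-loss enrichment tests.

*Essentiality*: genes up-associated with breakpoints are intersected with
genes whose gene-effect score is below −0.75 in more than 5% of cell
lines; genes absent from the essentiality matrix are excluded with a
warning.

## Survival and signature

Cox proportional-hazards fits are stratified on cancer type and use
Breslow tie handling (the lifelines default, stated here so external
comparisons match). Follow-up capping truncates time at the cap and
clears the event flag. One-sided p for a positive coefficient is
`p_two/2` if the coefficient is positive, else `1 − p_two/2`. Constant
features, fewer than two events, or a failed fit are flagged untestable.

The signed signature contains genes with (i) a positive breakpoint–
survival association (one-sided p < 0.05) in any of the four windows
(gene body, 100 kb up, 100 kb down, weighted 1 Mb flank — configurable)
and (ii) a breakpoint–expression association (two-sided p < 0.05) in any
window; the direction is the sign of the most significant qualifying
expression association, ties broken by larger |beta|. Expression–survival
Cox fits use unstandardized `log2(x + 1)` expression as the covariate.

The t-score of a sample is the pooled-variance two-sample t statistic of
the sample's values over signature-high genes vs signature-low genes,
computed on cohort-mean-centered log2 profiles (a helper performs the
centering; "differential profile" = deviation from the cohort per-gene
mean). Genes missing from a profile are dropped; fewer than two genes on
a side is an error; zero pooled variance yields 0 when the means agree
and NaN with a warning otherwise. Score tertiles are the empirical 1/3
and 2/3 quantiles; tied scores that collapse a boundary are an error
naming the collision. The tertile test is a stratified k-sample log-rank
(observed−expected and covariance accumulated per stratum and summed;
chi-squared with k−1 df) implemented in-package because lifelines does
not expose a stratified multivariate log-rank — it is verified against
lifelines' unstratified test on single-stratum data.

## Synthetic cohort generator

The generator is first-class, tested code and defines the study
conditions for all validation.

*Genome*: `n_chroms` chromosomes (default length 30–60 Mb in the shipped
configurations), genes packed without overlap with Dirichlet-distributed
gaps, random strands, ~half of genes given a 200–2000 bp 3′UTR at the
strand-appropriate end; uniform random enhancers; cytobands tiling each
chromosome with jittered boundaries. Packing infeasibility is an explicit
error.

*SV cohort*: germline SVs come from a population panel (default 250 SVs)
with per-SV carrier frequency uniform on [0.05, 0.5] and Bernoulli draws
per patient — the simplest generative mechanism that reproduces the
observed cross-patient breakpoint sharing. Default germline class mix is
DEL 0.78 / INV 0.125 / DUP 0.093 / TRA 0.002 with log-normal sizes of
median 2.1 kb (σ = 1); the size distribution beyond the median is a
modeling choice, not an observation. Somatic SVs are patient-private
(Poisson, mean 30/patient), class mix DEL 0.30 / DUP 0.25 / INV 0.21 /
TRA 0.24, log-normal sizes of median 175 kb (σ = 1.5). The second
germline caller replicate equals the first with uniform ±50 bp jitter per
breakpoint (well inside the 200 bp merge slop) and 5% per-call dropout.
Panel SVs may carry per-tissue frequency multipliers, used to construct
tissue-confounded cohorts.

*Expression*: log2 expression = per-gene baseline (uniform [3, 8]) +
per-(gene, tissue) offset (Normal(0, 0.5) by default) + planted effect ×
carrier indicator + 0.3 × (copies − 2) + Normal(0, noise) with noise SD
0.5 by default; the matrix is emitted on the linear scale as `2**log2`,
so a +1 log2 effect doubles a carrier's value exactly in the noiseless
limit. Copy number starts diploid and is perturbed only by somatic
gene-spanning DUP/DEL events — germline SVs leave the tumor copy profile
flat, reproducing the germline/somatic copy-category contrast. Planted
effects each ride on one dedicated panel SV whose breakpoints are placed
inside the stated window of the effect gene; enhancer-duplication effects
are DUPs in the upstream flank with a fresh enhancer placed inside the
duplicated span. Ploidy ~ Uniform[1.5, 4.5] and purity ~ Uniform[0.3, 1]
by default.

*Survival*: exponential event times with hazard = baseline ×
exp(Σ log-HR × feature) (baseline 0.01/month by default, optional
per-stratum log-hazard offsets), independent exponential censoring with
rate `baseline × c/(1−c)` so that roughly a fraction `c` of
baseline-hazard patients are censored before their event, and follow-up
capped at 240 months with the event flag cleared at the cap.

What the generator does *not* emulate: read-level data and sequence
content, SV calling itself, mobile-element insertions, linkage between
panel SVs, somatic copy-number structure beyond single-event
perturbations, and non-exponential hazards. Passing tests therefore
demonstrate the correctness and calibration of the analysis under these
generative assumptions, not performance on real cohorts, where caller
artifacts, population structure and expression covariance would add
noise the generator does not model.

## Validation design and problem sizes

The combinatorial kernels (matrices, merge, recurrence, geometric
classification) are checked for exact equality against independent
brute-force re-implementations on randomized instances (up to 100 genes ×
100 samples × 1,000 SVs for matrices; 1,000 records for merge and
recurrence). Statistical identities are checked in closed form (t-test
equivalence at 1e-10; hand-computed BH and t-score values; the Pearson
chi-squared formula). Recovery experiments use 400 samples, 4 tissues and
1,000 genes with 30 planted +1.0 log2 effects (10 seeds), null
calibration pools p-values over 5 seeds, enhancer-duplication and
survival power use 20 seeds at 200–600 samples, and the end-to-end run
uses the default 300-patient, 800-gene configuration; these sizes keep
the full validation suite to a few minutes while leaving the empirical
checks well-powered.

## Known limitations

- The linear-decay distance weight is a stand-in for "nearer breakpoints
  weigh more"; results near the 1 Mb boundary depend on the kernel.
- BH is applied per (window, model); no cross-window multiplicity
  control, by design.
- The Cox stage fits one feature at a time (plus stratification); no
  multivariable clinical adjustment and no proportional-hazards
  diagnostics.
- The 2 kb upstream window is available but not part of the default
  pipeline windows, mirroring its marginal role in the analysis design.
- Lift-over, caller-native VCF dialects, and TAD-aware windows are out of
  scope.
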