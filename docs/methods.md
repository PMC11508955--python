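# Methods

## Scope and model

`hlatag` models HLA carrier screening as a deterministic Boolean decision
layer on top of noisy per-assay observations, validated as a binary
diagnostic test.  There is deliberately no probabilistic carrier inference:
clinical screening panels of this kind act on hard calls, and the
uncertainty lives in the validation statistics, not in the verdict.

A panel (`hlatag.panel`) is a set of assays plus one rule per target
allele.  Assays are either tag SNVs (`snv_tag`: positive when the sample
carries ≥1 copy of the configured tag allele) or allele-specific
amplifications (`allele_specific`: positive when the target channel
amplifies alongside a ß-Globin reference channel).  Rules combine *groups*
of assays; within a group assays are ANY-combined (a SNV covered by two
TaqMan designs is one group), and across groups the combinator is SINGLE,
ANY or ALL.  Three-valued logic handles indeterminates: ANY short-circuits
on any positive, ALL on any determinate negative, so a composite verdict is
indeterminate only when the data genuinely cannot decide it.  This
maximises determinate output; the alternative (propagating indeterminate
through ALL whenever any member is indeterminate) discards samples whose
verdict is already falsified.

HLA nomenclature is handled at two-field resolution: every clinically
actionable target here is a two-field allele, and reference typings at
higher resolution are truncated for matching.  Expression-suffixed null
alleles (e.g. `*N`) are conservatively treated as non-matching a carrier
target; this is configurable (`allele_match(..., null_mismatches=False)`)
because usage varies between labs.

### Tag-allele orientation is configuration

Which nucleotide of each tag SNV counts as "positive" is recorded as
explicit data in the shipped panel config (`data/default_panel.yaml`),
sourced from the published assay descriptions and dbSNP orientation (e.g.
rs2395029-G for B\*57:01).  The inference engine reads it from the panel and
never hard-codes it; labs using differently-oriented assay exports edit the
config, not the code.

## Validation statistics

Determinate verdicts versus reference carrier status give a 2×2 table;
indeterminates never enter any denominator and are carried as a separate
count (so a cohort of 125 with two failed wells is reported as n = 123 plus
2 indeterminate, not silently shrunk).

Point metrics are the four standard ratios.  A metric with an empty
denominator is *undefined*, never 0.

Confidence intervals (95% default):

* **Sensitivity/specificity**: exact Clopper–Pearson from beta quantiles
  (`scipy.stats.beta.ppf`), `lo = 0` at x = 0 and `hi = 1` at x = n; at
  x = n the lower bound equals the closed form (α/2)^(1/n).  The
  implementation is cross-checked in the test suite against an independent
  bisection on the binomial CDF over every (x, n) with n ≤ 250 at 1e-9.
* **PPV/NPV**: adjusted logit — normal interval on
  log((x+0.5)/(n−x+0.5)) with SE √(1/(x+0.5)+1/(n−x+0.5)), back-transformed
  — which stays defined near the boundary; at a degenerate estimate
  (x ∈ {0, n}) the code falls back to Clopper–Pearson.  The standard
  (unadjusted) logit interval is also provided.  No single textbook formula
  reproduces all published predictive-value bounds in this literature, so
  the method actually used is recorded on every interval and is selectable
  per fit; it is never silent.

Percentages render with half-up rounding (1 dp for metrics, 2 dp for
concordance).  Concordance between two call sets is the agreement
proportion over pairs determinate on both sides, with discordant sample ids
listed and indeterminate pairs counted separately.

Zygosity concordance cross-tabulates marker zygosity (het/hom) against
reference allele copies (1/2) over true-positive carriers.  Copy-number
predictions (`predicted_copies`) are always emitted with a non-clinical
flag: linkage between marker dose and allele dose is imperfect, and the
package treats markers as presence detectors only.

No multiple-testing adjustment is applied across units: each marker/rule
table is reported on its own, as is conventional for assay-validation
reports.

## Cluster calling

Endpoint allelic discrimination is re-implemented as a small deterministic
algorithm (instrument software is a black box; reproducibility requires an
open one):

1. **Signal**: one (FAM, VIC) pair per well, baseline-subtracted upstream
   if start-cycle reads exist.
2. **Normalisation**: both channels divided by one shared zero-anchored
   scale (the maximum signal over both channels of non-NTC wells).  This is
   invariant under common rescaling and — unlike per-channel min-max — does
   not stretch pure noise across the unit square when a genotype class is
   absent, which is what makes the "no positives in this cohort" case come
   out all-negative instead of hallucinating a positive cluster.  The
   trade-off is an assumption that genuine amplification reaches a
   substantial fraction of the plate's dynamic range, which holds for
   endpoint TaqMan reads.
3. **Seeded k-means**: centroids start at canonical positions (allele-1
   axis / diagonal / allele-2 axis for SNV assays; reference-only axis and
   both-channels quadrant for allele-specific assays) and are refined by
   plain k-means.  A class left empty keeps its prior, anchoring degenerate
   cohorts.  The loop is fully deterministic and order-independent; the
   `seed` option exists for API stability but no step is stochastic.
4. **Rejection**: a well inside the NTC envelope (max NTC signal × 1.2, or
   8% of scale when no NTCs are given) is indeterminate; for
   allele-specific assays a failed reference channel is indeterminate
   regardless of target signal (failed reaction ≠ negative).  Boundary
   rejection uses the relative margin (d₂−d₁)/(d₂+d₁) between the two
   nearest centroids, below threshold 0.33 by default — scale-free, and
   monotone: raising the threshold can only add indeterminates.

Consequence, verified in the tests: with cluster separation ≈ 6σ all
*determinate* calls match the generating labels and a few percent of wells
are boundary-rejected; with σ ≪ separation (12σ) every well is recovered
exactly.  Accuracy degrades monotonically as separation shrinks.  The
separation score reported by `fit_cluster_model` is the silhouette
coefficient.

## Synthetic cohorts

The generator (`hlatag.simulate`) emulates the statistical phenomena the
validation layer must survive, not the biology that produces them:

* **Carrier structure**: target-allele copies drawn from Hardy–Weinberg
  proportions for allele frequency *p* (or from a carrier prevalence π via
  p = 1−√(1−π); supplying both inconsistently is an error).  Non-carrier
  haplotypes get filler alleles from a small fixed list that includes
  near-miss names (B\*58:06) to exercise two-field matching.
* **Marker noise**: each marker fires with its own tagging sensitivity
  σ_m on carriers and 1−τ_m on non-carriers — a phenomenological stand-in
  for incomplete LD; no haplotype or recombination structure is simulated.
  Markers are independent by default or *comonotone* (one shared latent
  uniform per sample), bracketing the correlation regimes an ALL rule can
  face: independent errors are suppressed by conjunction, fully linked ones
  are not.
* **Zygosity discordance**: marker zygosity mirrors copy number except
  with a configurable flip probability, reproducing the observed
  hom-marker/one-copy mismatches.
* **Indeterminates**: injected per well at a flat rate.
* **Fluorescence**: isotropic Gaussian clouds at per-class centroids,
  clipped at zero, plus NTC wells near the origin.  Default test geometry
  places classes at instrument-realistic positions (signal ≈ 3 arbitrary
  units, bleed-through ≈ 0.3).

One seeded `numpy` generator drives all draws; equal seeds give
byte-identical cohorts.  `fixture_from_confusion` deterministically
reconstructs a minimal cohort realising any printed 2×2 table (TP/FP/FN/TN
plus indeterminate extras), which is how the published validation tables
are pinned as exact test fixtures; `crossed_two_marker_fixture` builds the
two-marker cohort whose single-marker false positives are disjoint, the
configuration under which a conjunction rule converts all of them to true
negatives while preserving every true positive.

What passing these tests does **not** show about real data: the generator
has no plate effects, no DNA-quality gradients, no correlated well
failures, no population structure in allele frequencies, and its
fluorescence clouds are isotropic Gaussians.  Results on synthetic cohorts
validate the *pipeline logic and statistics*, not assay chemistry.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a laptop-class run: printed
tables at their published sizes (125–233 samples), cluster recovery at
n = 132 wells, parameter recovery at n = 10⁴ samples, exact-interval
oracle over all (x, n) with n ≤ 250, and interval coverage over 2000
replicate cohorts of n = 125.  Tolerances: interval agreement with the
independent oracle at 1e-9; published percentages compared at their printed
1-dp precision, accepting either half-up rounding or truncation because the
source tables mix both conventions (e.g. an exact lower bound of 82.35%
printed as 82.3%, and 99.99% printed as 99.9%).

Degenerate inputs are handled explicitly rather than numerically: empty
denominators give undefined metrics, n = 0 intervals raise, all-identical
fluorescence raises a degenerate-data error naming the assay, and ties in
centroid assignment break toward the lower class index.

## Known limitations

* No composite clinical verdict is defined for B\*15:02: both SNVs are
  validated separately (plus a screening ANY combination and a discrepancy
  report), because discordance between them is a review trigger, not a
  resolvable state.
* Predictive values are prevalence-bound: PPV/NPV here describe the
  validation cohort and are not projected to other populations.
* The cluster caller is a reproducible stand-in for instrument software
  and assumes one assay per fit, two or three classes, and endpoint (not
  per-cycle) chemistry; no Ct estimation or melting analysis.
* VCF input is consumed at the GT level only; structural or phased
  haplotype information is ignored by design (carrier logic is
  zygosity-level).
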