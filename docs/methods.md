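# Methods

This note records the models behind each stage, the defaults that matter,
what the synthetic-data generators do and do not emulate, and the numerical
choices made where the design was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Ka/Ks estimation and the sliding-window scan

**Estimator.** Pairwise Ka/Ks uses Nei–Gojobori (1986) counting: each sense
codon contributes synonymous/nonsynonymous *site* fractions by classifying
its nine single-nucleotide mutants (stop-creating mutants count
nonsynonymous; sites always sum to 3 per codon), and *differences* between
two codons are averaged over all minimal mutational pathways (≤ 6), with
pathways through stop codons excluded whenever a stop-free pathway exists;
if every pathway passes through a stop, all pathways are used and the steps
into or out of a stop count as nonsynonymous. Proportions pS = Sd/S and
pN = Nd/N get the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3). A
proportion ≥ 3/4 cannot be corrected; the estimate is flagged saturated and
its ratio is undefined. Ks = 0 likewise leaves the ratio undefined rather
than infinite, and such windows break runs during region calling. NG86 was
chosen as the simplest defensible pairwise estimator; the correction is a
single internal function, so a different distance correction can be swapped
in without touching the counting.

NG86 assumes no transition/transversion bias when counting sites. Under the
simulator's default kappa = 2 the estimator therefore underestimates a
neutral gene's Ka/Ks (measured mean ≈ 0.88 in the test suite); under
kappa = 1, where the estimator's assumptions hold, the neutral mean is
≈ 0.97. Both sit inside the 0.8–1.2 neutrality band the tests assert. This
is the estimator's well-known conservative direction: it deflates, not
inflates, evidence for positive selection.

**Windows.** Default window 50 codons, step 1 codon (maximal positional
resolution). Per-codon site and difference counts are additive, so profiles
are assembled from cumulative sums; a window's estimate uses only the codons
inside it. Genes shorter than one window yield no profile and are reported
as too short.

**Region calling.** Maximal runs of consecutive windows with defined
Ka/Ks > 1 become candidate regions; each region's p-value is a one-sided
one-sample t-test of the per-window (Ka − Ks) against 0 (alternative:
mean > 0). (Ka − Ks) rather than the ratio keeps the statistic defined when
a window's Ks is tiny. A zero-variance run gets p = 0 when its constant
difference is positive (flagged `degenerate_variance`), p = 1 otherwise.

The minimum run length defaults to **half a window (25 windows)**. With a
1-codon step, adjacent windows share 49 of 50 codons, so every window in a
short run can be looking at the same handful of substitutions — and since
run membership already requires Ka > Ks, the t-test over such a run is
self-confirming. Calibration on simulated neutral-background genes
(dN/dS = 0.2, 300 codons, divergence 0.3 substitutions/codon) shows runs
caused by single localized fluctuations stay under ~20 windows, while a
genuine 50-codon selected segment sustains runs of ~50–90 windows; the
half-window minimum separates the two regimes, giving a measured
false-positive rate of ~0.5–3% of genes at alpha = 0.05 with ~96% recovery
of planted segments (recomputed by `scripts/acceptance.py`). `min_run` is
an exposed flag; a non-overlapping mode (`step = window`) is available for
fully independent windows.

**Gene sets.** A gene lands in comparison set 1a when every evaluated
species pair carries a significant region, in set 1b when every C3 pair does
and no C4 pair does; a gene missing any comparison is unclassifiable. A
relaxed mode (`require_significant=False`) classifies on the presence of
Ka/Ks > 1 runs without the t-test, since published usage of "ratio greater
than one" is ambiguous about test significance.

Coordinates are 0-based half-open codon units everywhere in the library;
region reports add 1-based inclusive columns for protein numbering.

## Codon-pair simulator

A random ancestor (codons uniform over the 61 sense codons) evolves along
two independent branches of length `branch_length/2`, so the pair's expected
divergence is `branch_length`. Each codon follows a continuous-time process
(Gillespie simulation): single-nucleotide proposals with HKY-style
transition/transversion weighting (kappa, default 2), accepted at relative
rate 1 if synonymous, omega if nonsynonymous, 0 if they would create a stop
— so stop handling never reaches the analysis stages. Rates are normalized
so `branch_length` is the expected number of substitutions per codon for a
neutral (omega = 1) gene; under purifying omega the realized divergence is
correspondingly lower. Omega varies along the gene via a piecewise-constant
map that must tile the gene exactly.

Not emulated on purpose: realistic codon frequencies (F3x4 and kin),
among-site rate heterogeneity beyond the omega map, indels (analysis input
is assumed gap-stripped), and CpG or context effects. Passing calibration
therefore shows the scan recovers regions under its own model class, not
that it is robust to alignment error or compositional bias in real data.

## Diel phase-shift detection

**Grids.** The CAM species is sampled at 0,3,…,21 h after lights-on, the C3
reference at 0,4,…,24 h, both under a 12:12 photoperiod; the 24 h sample is
identified with 0 h. Both series are interpolated to the union grid
{0,3,4,6,8,9,12,15,16,18,20,21} h.

**Interpolation.** Monotone (shape-preserving) piecewise-cubic Hermite
interpolation on the periodically extended series (period 24 h). Shape
preservation means no overshoot beyond neighbouring samples, so interpolated
points can never fabricate a spurious peak — important because the peak is
read off the grid. The cost of the periodic extension is that polynomial
reproduction is lost in the interval adjacent to the wrap (the slope limiter
zeroes the derivative at a wrap-side extremum); the tests check linear
reproduction away from the wrap and cosine accuracy (max error ≈ 0.011 on
the union grid for a 3 h sampling interval, bound 0.05).

**Normalization and peaks.** Z-scoring (population denominator) happens
after interpolation, on the common grid, making profiles comparable on an
identical support. The peak is the grid time of the maximum value (earliest
wins ties); phases quantize into morning [0,6), afternoon [6,12), early
night [12,18), late night [18,24) — the 12:12 photoperiod halves the day and
the night is split to distinguish "late night" patterns. Constant series
cannot be Z-scored and propagate an unclassifiable `none` call with a
reason.

**Classification.** Rule-based on peak bins: morning-to-night iff the C3
peak bin is morning and the CAM peak bin is either night bin;
afternoon-to-night iff the C3 bin is afternoon and the CAM bin is late
night. Hierarchical clustering (average linkage, Euclidean distance on the
concatenated Z-profiles) is provided as descriptive output, not as the
decision rule: the published clusters are defined by their peak-shift
semantics, and a rule makes the ground truth of a simulated pair
well-defined. Ortholog pairs are formed by intersecting reciprocal best
hits with ortholog-group co-membership; genes appearing in conflicting
retained pairs are rejected with a report rather than resolved by guesswork,
and multi-member groups are handled pairwise per RBH pair without
family-level aggregation.

**Generator and its known resolution limit.** Simulated courses are
`amplitude·cos(2π(t − peak)/24) + N(0, noise_sd)` i.i.d. per sample
(defaults amplitude 1, noise 0.3), matching the Z-score/clustering
assumptions — no autocorrelated noise, no asymmetric waveforms. The
calibration study uses 200 pairs: 100 unshifted (one shared uniform random
peak) and 100 carrying an exact 12 h shift, alternating the two observed
patterns — C3 peak 3 h → CAM 15 h (morning-to-night) and C3 peak 8 h → CAM
20 h (afternoon-to-night), the C3 afternoon peak placed on a sampled
timepoint. The two shift patterns are not equally detectable: the C3
species' 4 h grid has a single sample inside the afternoon bin (8 h), whose
flanking samples at 4 h and 12 h sit at cosine value 0.5 versus the peak's
1.0; with noise 0.3 a flank exceeds the peak sample often enough that
afternoon peaks are misbinned in roughly a fifth of pairs, a limit of the
sampling design rather than of the classifier (grid-time argmax peak
calling cannot average it away). Morning-to-night pairs, with two morning
samples near their peak on each grid, classify with ~98% accuracy. The
study reports overall accuracy (~0.90–0.94 depending on seed) and the full
confusion table; confusions are between adjacent bins only.

**Expression pre-filter.** Genes enter the analysis when detected (> 0) in
at least 4 samples with mean expression ≥ 5 (RPKM-scale), the standard
expressed-transcript filter for this data type.

## Ortholog clades and the CAM-specific screen

A photosynthesis type (NVP, C3, CAM, C4) is present in a group as soon as
one gene from one species of that type is a member — clade labels describe
sharing, not completeness — and the label is the canonical NVP:C3:CAM:C4
ordering of present types, with single-type groups rendered `<type>-only`.
Species labels are canonicalized case-insensitively with whitespace
stripped; the OrthoMCL `species|gene` dialect is parsed with the species
taken from before the first `|`. The partition is exact (every group in one
clade; per-species clade fractions sum to 1) and is property-tested against
direct set arithmetic.

The conserved-CAM screen consumes a boolean gene × panel-species presence
matrix (optionally thresholded from BLASTp E-values at 1e-5 — homology
search itself is out of scope) and keeps candidates present in ≥ 1 species
of *each* independent CAM lineage and in *no* non-CAM panel species. The
same E-value cutoff is applied to the presence and absence sides, since no
separate absence threshold is published. Tribe membership is an input
column; the candidate pool is the stated intersection of CAM-only ortholog
groups and CAM-only tribes.

## Enrichment

Expected overlap e = |set|·|category|/N (the standard independence null);
over-representation p = P(X ≥ o) and under-representation p = P(X ≤ o) for
X ~ Poisson(e), evaluated through the regularized-gamma survival function
(accurate for counts ≥ 10^4 without term summation; verified against an
arbitrary-precision oracle to 1e-12 over o ≤ 100, λ ≤ 50). Poisson is the
statistic of record here; a hypergeometric option exists for sensitivity
analyses. Unassigned genes form a "Non-module" category so categories always
partition the universe. BH adjustment runs within each gene set across
categories (matching column-wise flagging of a set × module table); the
family choice is a flag. Flags are `q<0.05` / `q<0.01` by default.

A discrete tail test only attains its nominal size where the null tail
probability lands just below the threshold: at integer expected counts
(e = 1) the achievable size of the level-0.05 Poisson test is ~0.019, at
e = 0.8 it is 0.0475. The null-calibration study therefore uses e = 0.8 per
cell (20000 genes, sixteen 200-gene modules, an 80-gene set drawn
uniformly), where nominal and achievable size coincide; measured rate
≈ 0.046. The power study uses the planted design (2000 genes, sixteen
100-gene modules, 20-gene set at 8-fold in M11). `fold_enrichment` is
defined as the target observed/expected ratio: the overlap count is drawn
from Fisher's noncentral hypergeometric distribution (biased-urn model)
with odds solved so the mean overlap equals fold·e, reducing exactly to a
uniform draw at fold 1. At fold 8 the planted mean overlap is 8 with
spread ≈ 2, while the q < 0.05 flag requires an overlap of 6; the measured
flag rate is therefore ~0.88–0.94 depending on seed, the irreducible
Monte-Carlo variability of a count that close to its detection threshold.

## Pipeline and reproducibility

All randomness flows from the config seed; per-stage and per-replicate
seeds are derived arithmetically, so identical configs give byte-identical
outputs (checked by manifest sha256 digests in the acceptance script and
tests). Outputs are TSV with headers naming units and coordinate
conventions, plus a JSON manifest of parameters, version and digests. The
calibration studies use 50 genes (recovery), 200 genes (null), 200 diel
pairs, 500 null and 100 power enrichment replicates — sizes at which each
study completes in seconds while the binomial error on its rate estimate is
small against the bound it is compared to.

## Known limitations

- NG86 ignores transition bias and codon frequencies; its neutral ratio is
  deflated under biased mutation (conservative for positive selection).
- The region t-test treats overlapping windows as exchangeable within a
  run; the half-window minimum run length is a calibration-backed heuristic,
  not an exact correction for window correlation.
- The diel classifier's afternoon sensitivity is capped by the C3 sampling
  grid (one afternoon sample), as quantified above.
- The enrichment statistic is Poisson by design even though the exact
  finite-universe null is hypergeometric; for small categories the Poisson
  tail is mildly conservative.
- The simulators are calibration instruments: they share the analysis
  stages' model assumptions, so passing studies demonstrate correctness of
  the implementation and internal consistency, not robustness to real-data
  artifacts (alignment error, waveform asymmetry, count noise).
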