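# Methods

## Binned-Poisson enrichment calling

Aligned reads are stored as 5′ start + strand (BED6); extension to the mean
fragment length is a separate, explicit step so the generator/caller
contracts stay orthogonal. A plus-strand read starting at *s* extends to
[*s*, *s*+L); a minus-strand read ending at *e* extends to [*e*−L, *e*),
clipped to chromosome bounds. Each extended fragment contributes exactly one
count, to the bin containing its midpoint — this keeps the track total equal
to the fragment count on every input, which the suite asserts as a
conservation property.

The background rate for a bin with IP count *k* is

    λ = max(local input count, genome-wide input mean per bin) · N_IP / N_input

a conservative local/global maximum: sparse input bins fall back to the
genome-wide mean instead of producing spuriously small λ. The bin is
enriched iff the exact upper-tail Poisson probability P(X ≥ k; λ) falls
below the threshold (default 10⁻⁹) **and** the pseudocounted fold
(k + 1)/(λ + 1) reaches the minimum fold over input (default 5). The
pseudocount of one fragment stabilizes sparse bins without changing calls at
depth. The fold denominator defaults to the same λ as the p-value; a
`local_lambda` switch exposes the pure genome-mean alternative. No
multiple-testing correction is applied — the fixed 10⁻⁹ threshold *is* the
genome-wide control (at 10⁶ bins the expected null count is 10⁻³), and the
suite checks that the realized per-bin rate on i.i.d. Poisson nulls stays
below 1.5× the threshold.

Strictly adjacent enriched bins merge into regions; a single non-enriched
bin splits them (`merge_gap` widens this if wanted). Region p is the minimum
bin p, region fold the maximum bin fold.

At λ = 1 the smallest enriched count is 12: P(X ≥ 12; 1) ≈ 8.3 × 10⁻¹⁰ <
10⁻⁹ ≤ P(X ≥ 11; 1) ≈ 1.0 × 10⁻⁸. The test suite re-derives this from an
independent factorial tail sum.

## Promoter classification

Coordinates are 0-based half-open throughout; TSS windows are
[TSS − w, TSS + w) with w = 2000 bp. A mark flags a TSS iff **either
boundary** of an enriched region lies inside the window — a region spanning
the whole window without a boundary inside does not flag it, which mirrors
boundary-based peak-to-TSS assignment. Classes: bivalent = H3K4me3 ∧
H3K27me3; active = H3K4me3 ∧ ¬H3K27me3; unmarked otherwise.

## TSS-relative display statistics

`metagene_profile` flips minus-strand genes so positive offsets point
downstream. Two statistics are offered. *Coverage* accumulates per-bp
fragment coverage; note that 200-bp fragments low-pass the signal — two
Gaussian components at ±100 bp (σ = 50) produce near-flat coverage across
the TSS, so coverage is the right statistic for occupancy but not for
visualizing flanking bimodality. *Midpoint* counts fragment midpoints in
bins (default 25 bp), the same allocation the enrichment tracks use, and
preserves the two flanking modes. The discrete reflection convention maps
base-pair offset o to −o−1, so a fragment covering offsets [50, 250) on a
plus-strand gene covers [−250, −50) on its minus-strand mirror; the profile
of a strand-mirrored dataset equals the reversed profile exactly.

`ordered_density_matrix` ranks genes by the summed density of a chosen mark
(default H3K27me3) over ±4 kb, descending, ties broken lexicographically by
gene id.

## Expression integration

Isoform RPKMs are summed per TSS as the transcriptional-output metric. Fold
changes are log₂((B + c)/(A + c)) with c = 1 RPKM by default: silent genes
get a bounded, zero fold change rather than 0/0. The differential filter is
strict (|FC| > 1.5 on the linear scale, i.e. |log₂FC| > log₂1.5); the filter
is defined on the pseudocounted ratios. The hypergeometric overlap test is
upper-tailed, P(X ≥ observed), with the universe defaulting to all genes
carrying an annotated TSS and expression data. KS tests use the asymptotic
two-sample two-sided formula; the suite validates the D statistic against a
direct CDF-scan oracle at n ≤ 25 and the hypergeometric p against full
enumeration for universes ≤ 12. The group t-test is the classic
equal-variance unpaired test, with medians reported alongside. Clustering is
agglomerative with Euclidean distance; the linkage method is a flag
(default: average). Rows are pre-sorted by gene id so the tree is invariant
to input row order.

## NanoString normalization and Monte Carlo FDR

Values are log₂(count + 1) minus the per-sample mean of the log₂
housekeeping values — algebraically, division by the housekeeping geometric
mean — so housekeeping rows average exactly zero in every sample, and the
transform is exactly invariant to per-sample scaling when the pseudocount is
zero (within 0.01 log₂ units for counts ≥ 100 at pseudocount 1). Gene rows
may then be centered across samples (idempotent). Up/down calls are
inclusive at ±log₂(fold).

The Monte Carlo FDR's null is **label permutation**: the observed statistic
is the unpaired t-test p on per-sample median expression between the two
groups; each of n_iter (default 10,000) iterations permutes the sample
labels and the FDR is the fraction of iterations whose null p falls at or
below the chosen threshold. This is the minimal exchangeability null
consistent with a "random iterations" simulation and is an interpretation,
not a uniquely determined procedure; the statistic is pluggable for
gene-level alternatives. For a single dataset the permutation FDR is a
discrete random quantity, so the convergence check averages 10 independent
exchangeable datasets (12 vs 12 samples, 40 genes) and compares the mean to
the threshold within three empirical standard errors.

## FRAP

Curves are normalized to the maximum pre-bleach intensity. The endpoint
estimator uses I_dip = the first post-bleach frame and I_sat = the mean of
the last `tail_window` frames (default 1, matching "intensity at the end of
the recovery"), and reports

    MF = (I_sat − I_dip) / (1 − I_dip).

The operand order in the numerator is the standard orientation: recovery
(I_sat > I_dip) yields a positive mobile fraction. For a noiseless
single-exponential truth the finite window biases the endpoint estimator by
exactly MF_true·e^(−kT); the suite asserts this closed form, and at the
default acquisition geometry (30 s intervals, 29 post-bleach frames ≈ 14
min, k = 0.01 s⁻¹ ⇒ kT = 8.4) the bias is negligible (< 10⁻⁴). The
single-exponential fit (I_dip, amplitude, k via least squares) is provided
as an alternative estimator and for rate constants; a near-zero amplitude
leaves k unidentifiable and is flagged rather than reported as converged.
No photobleaching-decay correction is applied by default. Averaged curves
align at the bleach frame; pre-bleach frame counts may differ, the common
grid spanning the minimum pre/post extent. Group comparisons use the
equal-variance unpaired t-test on per-cell mobile fractions.

## Synthetic data: what it emulates

The generators define the study conditions the suite runs under.

* **Genome**: genes placed with ≥ 5 kb spacing (promoter windows disjoint),
  classes i.i.d. from a (bivalent, active, unmarked) probability triple.
  Per-gene random sub-streams derive from (seed, gene index), so enlarging a
  gene set never reshuffles existing genes.
* **ChIP reads**: the IP library is a mixture of a uniform background and,
  per enriched TSS, two Gaussian fragment-center components at ±100 bp
  (σ = 50 bp), strand-oriented, the downstream (+1-nucleosome) component
  scaled by (1 − depletion). Component masses are solved jointly with the
  background share in closed form so the expected IP/input density ratio
  over TSS ± 200 bp equals the requested class fold exactly at zero
  depletion (at positive depletion the realized window fold is accordingly
  lower). H3K4me3/H2A.Z enrich bivalent + active promoters, H3K27me3 only
  bivalent ones. Exactly the requested read total is emitted (multinomial
  allocation); fragments are 200 bp, sequenced from a random end at 36 bp.
  Peak breadth is a free parameter, not a calibrated one. No sequencing
  error, mappability structure, duplicates or GC bias are simulated, so
  recovery rates measured here bound the idealized method, not real-library
  behaviour.
* **Expression**: condition B = condition A × 2^shift(class) ×
  lognormal noise (σ = 0.1 log₂ units by default) — the simplest positive
  multiplicative noise compatible with RPKM data; the default bivalent shift
  of +1 log₂ unit represents a strong class-wide regulatory response.
* **NanoString**: counts = round(sample scale × gene base × 2^effect ×
  lognormal noise), housekeeping effects pinned to zero. Rounding to integer
  counts makes per-sample scale invariance exact only up to rounding error.
* **FRAP**: pre-bleach frames at 1, post-bleach
  I(t) = I_dip + MF(1 − I_dip)(1 − e^(−kt)) + Gaussian noise; defaults
  mirror the acquisition geometry above (31 frames at 30 s, 2 pre-bleach,
  noise σ = 0.01, I_dip = 0.5), with an optional between-cell spread of the
  true mobile fraction (σ = 0.03) for group-power studies with 14 cells per
  group.

## Problem sizes

The validation suite and `scripts/acceptance.py` use: 600-gene genomes on a
6 Mb chromosome with 10⁶-read libraries and fold 20 for recovery statistics
(~200 genes per class, matching the class-stratified statistics at desk
scale); ten 10⁶-bin Poisson(2) track pairs for null calibration; 14 cells ×
31 frames per FRAP group with 200 replicate simulations for power; 10
datasets × 10,000 permutations for FDR convergence. These sizes give
sampling errors well inside every asserted tolerance while a full run of
suite plus acceptance script completes in well under a minute of compute.

## Known limitations

* λ estimation uses a single local bin; schemes with multi-scale local
  windows (1 kb/10 kb) are not implemented.
* The caller reports no FDR/q-values — by design, matching the fixed
  threshold convention it implements.
* The Monte Carlo FDR null is one defensible choice among several; with few
  samples per group the permutation distribution is coarse.
* FRAP modelling is empirical single-exponential; no reaction–diffusion
  model, and no image processing (inputs are intensity traces).
* The CLI's `chip call` reconstructs chromosome extents from the gene table
  rather than a chrom.sizes file; supply genes covering each chromosome's
  span or use the library API for exact control.
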