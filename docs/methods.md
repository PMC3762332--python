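# Methods

This note records the models each module implements, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical and
design choices made where the procedure was genuinely open.

## Microarray hit calling

Each spot contributes a raw intensity `R = F/B` (foreground over
background median; `B > 0` enforced for unflagged spots). Spatial trends
are removed by dividing each `R` by the median over the window centered on
the spot (default 9×9). Two open points are resolved as follows: the
window **includes the center spot** — a single spot cannot shift a
9×9 median, and the inclusive window is the simplest consistent rule — and
windows are **truncated at grid borders** rather than padded, so no
fabricated values enter a median. Both choices are oracle-tested against a
brute-force windowed median for grids up to 12×12 and windows {3, 5, 9}.

Because most spots are non-binders, the sub-unity part of the `R'`
distribution is noise. The noise model reflects the shadow set
`N₁ = {R' < 1}` around 1 (`N₂ = 2 − N₁`) and uses `N = N₁ ∪ N₂`: its mean
is exactly 1 by construction and its **population** SD (divide by |N|)
calibrates `Z = (R' − N̄)/std(N)`. Values exactly 1 are excluded from N₁
(they contribute no deviation; 1 is a fixed point of the mirror). Fewer
than 10 shadow values is treated as an uninterpretable array, not a
silent estimate. The mirror assumes the noise is symmetric around 1 on
the linear scale; for mildly skewed (e.g. log-normal) noise the estimate
is a few percent conservative-low, which only moves the effective Z
cutoff slightly.

A protein is a hit for a motif only when all four of its spots — two
printed duplicates on each of two replicate arrays — reach `Z ≥ 3`
(inclusive). A protein with any flagged or missing spot can never be a
hit; this is the conservative completion of the all-four rule. Replicates
are paired by identical (row, column) layout; mismatched layouts are an
error, never auto-aligned.

## PDI integration and screen statistics

Every (protein, motif) pair with at least one hit is classified
methylated-only / unmethylated-only / both; identifier universes must
reconcile exactly. Percentages are reported rounded to the nearest
integer percent, matching how screen summaries are printed (the rounded
categories can sum to 100 ± 1). Annotation enrichment is the strictly
upper hypergeometric tail `P(X ≥ k)` — enrichment claims are one-sided —
with the universe defaulting to every protein printed on the array
(1321 TFs + 210 cofactors = 1531), configurable. The saturation curve is
Monte-Carlo over random motif subsets with a fixed seed and reported
standard error; tests check it against the closed form
`E[unique] = Σ_p (1 − C(M−m_p, n)/C(M, n))`.

## Consensus derivation

Bound motifs are aligned on the methylated CpG and reduced to k-mers
(default k = 6) with the CpG at the two central positions; motifs whose
CpG sits too close to an end are skipped with a warning, and motifs with
several CpGs contribute one k-mer per CpG. Distance between k-mers is the
fraction of mismatching **flank** positions — the central CG is constant
by construction and carries no discriminative information. Clustering is
greedy average-linkage agglomeration, stopping when the best remaining
merge falls below the similarity cutoff (default 0.75, i.e. ≥3 of 4
flanks for k = 6; the cutoff is a parameter since only "a selected
cutoff" is specified by the procedure this follows). Flank distances are
quantized to multiples of 1/(k−2), so ties are the norm rather than the
exception; merges are tie-broken by the lexicographically smallest merged
member tuple, which makes the partition deterministic and input-order
invariant — the main reason the agglomeration is written out directly
rather than delegated to a generic linkage routine with opaque tie
handling. Each group is summarized as a per-position base-frequency PWM
and an IUPAC string: a position's letter is the smallest degenerate code
covering every base at ≥25% frequency (standard logo-style degeneracy;
configurable). A TF bound to a single motif keeps that motif as its
consensus. Reverse complements are not collapsed for array motifs, which
are probed double-stranded with a stated written strand.

## In vivo k-mer enrichment

Coordinates are 0-based half-open throughout; methylome positions refer
to the plus-strand C of each CpG. Peaks are filtered to those strictly
shorter than a cutoff, given either in bp or as a length quantile
(default 0.95, emulating "95% of peaks shorter than 371 bp"). Summit
methylation `M` pools read counts over all covered CpGs in summit ±60 bp
(coverage-weighted; the unweighted per-CpG mean is available) — pooling
is robust to low-coverage CpGs. Strata: high `M ≥ 0.8` (boundary counted
high), low `M < 0.2`.

Foreground sequences are summit ±60 bp (121 bp); background is each peak
extended by 50 bp per side, so the foreground is contained in the
background (an exclusive-background mode exists). Every window whose
central two bases are CG is counted; a k-mer and its reverse complement
are pooled under the lexicographically smaller key. Counting scans the
forward strand once: because CG is its own reverse complement, every
central-CpG window on the reverse strand is the reverse complement of the
forward-strand window at the same locus, so a forward scan with canonical
pooling already captures both strands. Scanning both strands explicitly
would count every physical window twice, which roughly squares the
hypergeometric p-values and destroys null calibration (measured: 3/10
null genomes produced a spurious Bonferroni-significant 6-mer with
double counting, 0/10 without).

Per k-mer, `p_raw` is the upper hypergeometric tail of drawing the
foreground windows from the background windows; Bonferroni multiplies by
the a-priori family size — all `4^(k−2)` possible central-CpG k-mers
(256 for k = 6), not just observed ones — and significance is
`p_adj < 0.01`. With reverse-complement pooling only 136 canonical
classes exist, so m = 256 over-corrects slightly; the a-priori family
definition is kept and `n_tests` is exposed for callers who want the
canonical count. Significant k-mers feed the consensus machinery; the
largest group's consensus is reported with deterministic tie-breaks.

## Kinetics

The 1:1 Langmuir model is assumed (the label-free readout follows
standard surface-binding analysis; no more complex transport or
bivalency model is identifiable from single-trace data):
association `S(t) = S_eq (1 − e^{−k_obs t})` with `k_obs = k_on C + k_off`
and `S_eq = S_max k_on C / k_obs`; dissociation `S_0 e^{−k_off t}`.
Fitting is two-stage for identifiability: `k_off` from the wash phase
alone (initialized by log-linear regression of the positive tail), then
`k_on` and `S_max` from the association phase with `k_off` fixed
(initialized from the plateau median and the time to half-plateau). All
starts are deterministic and seed-free; a joint three-parameter
refinement is available behind `joint=True`. A flat trace returns a
non-converged fit with the reason "no observed binding signal" rather
than a number. `K_D = k_off/k_on` per concentration; the average over
concentrations is the arithmetic mean, flagged when only one fit
converged or when the estimates disagree by more than 3×.

At the 10 s sampling interval, traces with `k_obs ≳ 0.1 s⁻¹` leave only a
few points on the rise, so noisy-recovery accuracy degrades for the
fastest rate combinations (a Cramér–Rao analysis of the sampling design
shows even an ideal estimator reaches only ~11% median K_D error at
`k_off ≈ 0.05 s⁻¹` with 5% multiplicative noise); recovery experiments
therefore report the median over the full rate grid.

## ChIP-bisulfite comparison

Per-read calls are an integer matrix (methylated / unmethylated /
missing); a site's level is methylated over informative calls, and reads
missing a call are dropped from that site only. The region mean pools all
informative calls. The input-vs-ChIP test at each shared CpG is the exact
binomial tail `P(X ≥ chip_k | chip_n, p₀)` with `p₀` the input sample's
observed level (plug-in null — the comparison is explicitly against the
genomic input); "binomial probability density" is interpreted as this
cumulative tail, since a point mass cannot serve as a significance value.
The test is one-sided (increase) by default, matching the directional
claim that a methyl-preferring TF enriches the methylated fraction;
`less` and `two-sided` are available, and degenerate nulls (`p₀ ∈ {0,1}`)
are computed from the forced binomial and flagged. Consensus and
neighboring sites are both reported so the contrast (consensus up,
neighbors flat) is computable. Exact binomial tests are conservative at
low read depth (discrete p-value atoms: achieved size ≈ 0.026 at depth
20, α = 0.05), so the null-calibration experiment uses depth 2000, where
the achieved size approaches nominal.

## Synthetic generators

All generators are deterministic under a fixed seed and return truth
objects. What they emulate — and do not:

- **Arrays** (`gen_microarray`): 1,536 proteins × 2 spots across two
  replicate arrays; multiplicative log-normal background noise
  (log-SD 0.1), a smooth spatial trend for local normalization to remove,
  10 planted binders elevated by 6 noise-SD on all four spots, `B` drawn
  log-normally around 500 units. Not emulated: spot-morphology artifacts,
  saturation, inter-array intensity drift, spatially correlated defects —
  so recovery results show the statistical chain works, not that it
  survives every scanner pathology.
- **Peaks/methylome** (`gen_peaks_methylome`): 400 non-overlapping peaks
  of 200–350 bp on a uniform-random genome; summit methylation drawn from
  high/low/mid strata at 48%/38%/14% (U(0.85,0.99)/U(0.01,0.15)/
  U(0.3,0.7) — kept clear of the 0.8/0.2 boundaries so sampling noise in
  pooled M rarely crosses a stratum); the planted k-mer inserted into
  high-M foreground windows at Poisson rate `(fold−1)×` the uniform
  background expectation; CpG coverage Poisson(30)+1 with binomial
  methylated counts. Not emulated: genomic base composition, CpG islands,
  repeat structure — real backgrounds are handled by the
  foreground-vs-background design, not by the generator.
- **Sensorgrams** (`gen_sensorgram`): 10 s sampling; phase durations
  default to ~5 characteristic times, bounded to [100 s, 5000 s];
  multiplicative Gaussian noise. Not emulated: bulk-shift artifacts,
  baseline drift, mass-transport limitation.
- **Bisulfite** (`gen_bisulfite`): i.i.d. Bernoulli calls per read and
  site at stated levels with optional per-call missingness. Not emulated:
  conversion failure, clonal PCR duplicates, read-level haplotype
  structure.

## Degenerate inputs and numerical conventions

Missing values propagate as NaN through the array chain and block hits;
all-missing windows and empty peak lists warn rather than raise;
correlation needs ≥3 joint cells; the noise model needs ≥10 shadow
values; empty significant-k-mer sets yield a no-consensus result, not an
error. Exact tail probabilities come from scipy's hypergeometric survival
function and exact binomial test; the test suite pins both to
exact-fraction enumerations (relative agreement ~1e-15). Quantile
cutoffs use linear interpolation (NumPy default). Percentages are
rounded to the nearest integer only at the reporting boundary, never
inside computations.

## Problem sizes used in recovery experiments

Planted-binder recovery runs 20 seeds at full array scale (1,536
proteins); k-mer recovery and null calibration run 10 seeds at 400
summits (~240 kb genome per seed); kinetic recovery runs the 3×3 rate
grid noiseless plus 20 noisy seeds per cell; the bisulfite null runs
10,000 sites at depth 2000. These sizes give Monte-Carlo error well below
each check's tolerance while keeping the whole suite fast.
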