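# Methods

## The switching model

Cells carry a binary heritable state: responder (R, TLR2-licensed) or
non-responder (NR). Lineages expand by binary division; at each division
both daughters inherit the mother's state and then flip independently with
per-generation probabilities `p_on` (NR→R) and `p_off` (R→NR) — one
Bernoulli draw per daughter per division. This is the simplest generative
reading of "switching per generation"; the alternative (one flip decision
per mother, copied to both daughters) would induce extra daughter–daughter
correlation and is not implemented.

The per-generation transition matrix over (NR, R) is
`[[1−p_on, p_on], [p_off, 1−p_off]]`. Its fixed point, the stationary
responder fraction, is `f_ss = p_on/(p_on+p_off)`; at the default rates
(0.01, 0.055) this is 0.1538, matching the observed ~15% cap on the
responding subpopulation. A population starting at fraction `f0` relaxes as
`f(g) = f_ss + (f0 − f_ss)·λ^g` with `λ = 1 − p_on − p_off`; for
`p_on + p_off > 1` the approach is oscillatory (a warning is emitted, the
closed form still holds). The prediction band is the pointwise envelope of
trajectories over a grid (default 21×21) of rate pairs inside the fitted
95% CIs — a conservative envelope, not a joint confidence region.

### Likelihood

State is observed only on terminal cells still in the field of view at the
end of the experiment; cells that died or left are censored. The likelihood
of a lineage's observed leaf states marginalizes all hidden states exactly
by post-order pruning over the two states: censored leaves contribute a
partial likelihood of 1 in both states (they constrain nothing but preserve
the tree topology); observed leaves contribute an indicator. Partial
likelihoods are rescaled per node, so deep forests cannot underflow.
Impossible data (e.g. discordant leaves under zero rates) yield −∞.

### Fitting

`fit_switching_rates` maximizes the summed pruning log-likelihood over
`(p_on, p_off)` on the logit scale (probabilities bounded to
[1e−8, 1−1e−8] during optimization only) with multi-start Nelder–Mead.
Starts include a method-of-moments point derived from direction-resolved
Fitch-parsimony switch counts. The root-state distribution is, per the
`root_dist_mode` option, a free parameter (default), tied to the stationary
fraction, or fixed. Estimates pinned at the boundary are reported with
boundary flags, never silently clipped.

Confidence intervals default to profile likelihood: for each rate the
profiled log-likelihood (nuisance parameters re-optimized, warm-started;
Brent's method when one nuisance remains) is intersected with
Δlogℓ = χ²₁(0.95)/2 = 1.92 by bracketed root finding on the logit scale.
When the profile never crosses the threshold toward a boundary, the CI
endpoint is 0 or 1. Percentile bootstrap over lineages (default 1000
resamples) is available as an alternative.

### Parsimony and concordance

`fitch_parsimony` is the standard two-state small parsimony: censored
leaves carry the full state set (uninformative), the minimum switch count
equals the number of union events, and root ties are reported explicitly
(assignment resolves ties NR-first, deterministically).
`relatedness_concordance` classifies observed leaf pairs by the focal
cell's division distance to the most recent common ancestor (1 = sister,
2 = cousin, ≥3 = extended) and reports P(relative is R | cell is R) per
class.

### Study scale

The lineage-tracing experiment tracked 58 lineages for up to five
generations, totaling ~273 divisions. `study_scale_design()` reproduces
this with a per-generation censoring probability of 0.39, chosen so the
expected division count `58·s·((2s)^5−1)/(2s−1)` at survival `s = 0.61`
is ≈273. At this scale the leaf-state likelihood of ~273 divisions carries
limited information about the rare NR→R transition (≈4–5 expected events):
the median 95% profile-CI half-width for `p_on` computes to ≈0.012–0.014,
above the reported ±0.005 — even fully observed transmissions would bound
the 95% half-width near ±0.009 (binomial information, ~465 NR
transmissions), so a ±0.005 interval at this sample size must draw on
information beyond the leaf states alone (for example an external
constraint on the stationary fraction from large-population staining, which
ties `p_on = f_ss·p_off/(1−f_ss)` and shrinks the `p_on` interval by
roughly that factor). The package reports the leaf-state-likelihood answer.
Profile intervals are near-nominal at the 500-lineage recovery scale
(coverage checked in [0.90, 0.99] over 100 replicates) and mildly
anticonservative (~0.87) at the 58-lineage scale.

## Trace featurization and responder calling

Traces are nuclear/cytoplasmic p65 median-intensity ratios plus a
destabilized fluorescent reporter, at 5-minute frames. QC rejects cells
whose mean pre-stimulus total p65 falls outside the population's [25th,
99th] percentile range (inclusive; lower-value percentile convention, which
on an n-point ladder removes exactly the cells below the 25% rank and above
the 99% rank). The baseline is the median pre-stimulus ratio; peaks are
post-stimulus local maxima with prominence ≥ 10% of baseline (the detector
is `scipy.signal.find_peaks`; the prominence default is a package choice —
at baseline noise above ~3% of baseline, noise-level "peaks" near the
threshold are possible). "AUC steady" integrates the baseline-subtracted
ratio, clipped at zero, from the first trough after the first peak to trace
end: ≈0 for a single transient pulse, large for sustained or oscillatory
activity.

Responder calling thresholds each cell's maximum post-stimulus ratio
(optionally within a fixed window, e.g. 30 min for fixed-cell designs)
against the *maximum* of the media-control scores — strict exceedance, so a
cell exactly at the control maximum is a non-responder; a quantile rule is
available when controls are contaminated. Responder fractions carry Wilson
score intervals. Bimodality is Sarle's coefficient
BC = (skew²+1)/kurtosis on log scores with population moments and
non-excess kurtosis (uniform = 5/9, the conventional bimodality threshold).
Count distributions are compared by a 2×k χ² on 10 equal-width pooled bins,
merging bins rightward while any expected cell count is below 5; with all
10 bins surviving this is the 9-degree-of-freedom comparison. Strongly
separated distributions (e.g. Poisson(2) vs Poisson(20)) empty the middle
bins and necessarily merge below 10 — the df convention is therefore
data-dependent by design.

## Spatial clustering

The statistic is the median over responders of each responder's median
Euclidean distance to its k = 5 nearest responders (self excluded; ties at
the k-th distance all enter the median, making the statistic
deterministic). The null permutes responder labels over the fixed cell
positions (count preserved), matching "randomized responder positions"
while keeping the monolayer geometry; uniform position redraw is provided
as an option. The one-sided p-value toward clustering uses the add-one
convention `p = (1+#{null ≤ obs})/(1+n_perm)`. Duplicate coordinates are
jittered by <0.01 µm with a seeded RNG and logged.

## Methylation bimodality

Nanopore-style call tables are filtered at |LLR| > 1.5 (between the
thresholds a call is discarded as ambiguous). Rows with `num_motifs > 1`
are motif groups — CpGs within 10 bp receive one call for the whole group —
and are expanded to per-CpG columns using the CG offsets in the sequence
context. Genomic positions (0-based) are converted to strand-aware
TSS-relative coordinates (0 = TSS, upstream negative); the promoter window
−110…−60 is inclusive at both ends. Per-read unmethylated-CpG counts
exclude reads covering fewer than 80% of the in-window CpGs (truncated-read
guard; every exclusion is logged). The two-component binomial mixture is
fitted by EM (tolerance 1e−8, ≤500 iterations, 10 seeded restarts, best
kept; non-convergence flagged); components are ordered by U-probability and
the fit is flagged bimodal when both weights are ≥0.05 and the component
probabilities differ by ≥0.5. Bisulfite-derived matrices enter through the
same matrix type; parsing raw bisulfite alignments is out of scope.

## Synthetic data

The generators define the test conditions:

- **Lineages**: rates (0.01, 0.055), stationary initialization, 58 lineages
  × 5 generations with censoring 0.39 (study scale) or 500 complete
  lineages (recovery scale).
- **Traces**: 400 cells, responder fraction 0.1538, 5-min frames over 480
  min, stimulus at 45 min; responders emit one alpha-function pulse
  (amplitude ~N(2, 0.4), peak 15 min after onset) or, in oscillatory mode,
  a damped 75-min-period oscillation; baseline ratio ~N(1, 0.05), frame
  noise SD 0.03. The reporter integrates supra-threshold activity with
  first-order production and a 90-min half-life, mimicking a destabilized
  (PEST) fluorophore — constants are free configuration, as no reporter
  kinetics are prescribed by the data. Total p65 is lognormal, giving the
  QC filter something real to reject.
- **Monolayers**: lineage expansion with daughters displaced ~N(0, 15 µm)
  from mothers in a 500-µm field (40 lineages × 3 generations by default;
  12 h per generation is the implied growth scale).
- **Methylation reads**: 12 CpGs (8 inside the window), hidden per-read
  block state with weight 0.6 unmethylated, per-site error 0.05, missing
  rate 0.05; optional emulation of the 10-bp grouping limit.
- **Dose response**: capped Hill curve `f_max·c^h/(c^h+EC50^h)` with
  `f_max` defaulting to the stationary fraction.

What the generators deliberately do **not** emulate: cell-cycle-length
heterogeneity, spatially varying density, reporter maturation delays and
bleaching, segmentation/tracking errors, read-level quality variation, or
any coupling between methylation state and lineage identity. Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical structure, not robustness to those real-data artifacts.

## Problem sizes used in the checks

Recovery and calibration run at: 100 replicates × 500 complete lineages
(rate recovery and CI coverage), 100 replicates at the 58-lineage study
scale (CI width), 500 label-shuffled + 150 grown fields at 499 permutations
(spatial calibration/power), 100 × 500-read matrices (EM recovery), and
100 × 300-cell trace sets with equal-size media controls (end-to-end
responder fraction; 300 cells sits on a favorable point of the Wilson
coverage oscillation, exact coverage 0.957 at p = 0.15). Oracle equivalence
uses 200 random censored trees (likelihood, ≤4 generations, vs hidden-state
enumeration) and 200 trees with ≤10 divisions (parsimony, vs exhaustive
minimum).

## Known limitations

- No continuous-time switching; generations are the clock, so unequal
  division times map onto effective per-generation rates.
- The spatial test is the k-NN median statistic only (no Ripley-K family).
- The methylation EM assumes conditionally independent sites given the
  block state; with 10-bp grouping enabled the effective number of
  independent sites is smaller, and the binomial `n_sites` should then be
  interpreted per group.
- Fitting assumes the division tree is known without error; tracking
  mistakes are not modeled.
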