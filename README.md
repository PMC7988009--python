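# episwitch

Quantitative analysis of **digital (all-or-nothing) TLR2/NF-κB signaling in
epithelial monolayers**. When epithelial cells sense bacterial lipopeptides
through TLR2, only a subset — capped near 15% — responds with NF-κB nuclear
translocation. That cap is set by a heritable, bistable epigenetic switch on
the TLR2 promoter: cells are *responders* (R) or *non-responders* (NR), the
state is inherited through division, and it flips stochastically at a small
per-generation rate. `episwitch` implements the full quantitative toolkit
for this biology:

- **`episwitch.lineage`** — the core two-state Markov switching model on
  binary lineage trees: simulation, exact pruning (marginal) likelihood of
  observed terminal states, maximum-likelihood fitting of the switching
  probabilities `p_on` (NR→R) and `p_off` (R→NR) with profile-likelihood or
  bootstrap CIs, Fitch small-parsimony reconstruction, the stationary
  responder fraction `p_on/(p_on+p_off)`, and the closed-form relaxation
  `f(g) = f_ss + (f0 − f_ss)·λ^g`, `λ = 1 − p_on − p_off`.
- **`episwitch.traces`** — single-cell NF-κB trace featurization (first-peak
  amplitude, post-peak "AUC steady", expression percentiles), QC filtering,
  responder calling against media controls, Wilson-interval responder
  fractions, Sarle's bimodality coefficient, dose–response χ² comparisons.
- **`episwitch.spatial`** — the responder clustering statistic (median
  distance from each responder to its 5 nearest responders) with a
  label-permutation randomization test.
- **`episwitch.methylation`** — per-read promoter CpG analysis from
  nanopore-style call tables (LLR ±1.5 filter, 10-bp motif grouping),
  unmethylated-CpG counts over the −110…−60 promoter window, en-bloc read
  classification, and a two-component binomial mixture fitted by EM.
- **`episwitch.synth`** — seeded generators reproducing the statistical
  structure every stage assumes, so the whole pipeline runs and is tested
  without any external data.
- **`episwitch.experiments`** — study-scale recovery and calibration
  experiments built from the above.

A thin `episwitch` command-line interface wraps the common stage chains
(`simulate`, `fit`, `predict-decay`, `call-responders`, `features`,
`correlate`, `spatial-test`, `methyl-bimodal`, `compare-counts`,
`simulate-all`); the primary interface is the Python API, demonstrated by
the scripts in `examples/`.

## Worked example

Fitting the switching rates from a simulated lineage-tracing experiment at
the study's scale (58 lineages, up to five generations, ~273 divisions,
censoring for cells that die or leave the field of view):

```python
from episwitch.lineage import (SwitchingRates, simulate_lineages,
                               fit_switching_rates, stationary_fraction,
                               study_scale_design)

rates = SwitchingRates(p_on=0.01, p_off=0.055)
print(f"{100 * stationary_fraction(rates):.1f}%")   # 15.4% responder cap

trees = simulate_lineages(rates, stationary_fraction(rates), seed=11,
                          **study_scale_design())
fit = fit_switching_rates(trees, root_dist_mode="stationary")
print(fit.p_on, fit.ci_on)   # e.g. 0.0060 (0.0003, 0.0296)
print(fit.p_off, fit.ci_off) # e.g. 0.0139 (0.0008, 0.0666)
```

The stationary fraction `0.01/(0.01+0.055) = 15.4%` is the model's
explanation of the observed ~15% responder cap, and the fitted intervals
cover the generating rates. `examples/01_lineage_switching.py` through
`examples/05_methylation_bimodality.py` walk through each capability
(decay prediction after a demethylating perturbation, trace featurization
and responder calling, spatial clustering, methylation bimodality) and
print the numbers with one-line interpretations.

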