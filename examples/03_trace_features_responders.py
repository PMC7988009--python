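"""Featurize single-cell NF-kB traces and call responders.

Generates a synthetic stimulated population (15% responders emitting one
nuclear-translocation pulse) plus a media-control population, applies the
initial-expression QC filter, scores each cell by its maximum post-stimulus
nuclear/cytoplasmic ratio, calls responders by strict exceedance of the
control maximum, and summarizes bimodality.
"""

from dataclasses import replace

from episwitch.synth import GeneratorConfig, TraceParams, gen_trace_set
from episwitch.traces import (
    bimodality_coefficient,
    classify_responders,
    features_table,
    qc_filter,
    responder_fraction,
    responder_scores,
)

cfg = GeneratorConfig(seed=42, trace=TraceParams(n_cells=400,
                                                 responder_fraction=0.15))
cells, truth = gen_trace_set(cfg)
controls, _ = gen_trace_set(
    replace(cfg, trace=replace(cfg.trace, responder_fraction=0.0)), seed=43
)

cells = qc_filter(cells)          # reject 25-99% initial-expression outliers
controls = qc_filter(controls)
print(f"{len(cells)} stimulated cells and {len(controls)} controls pass QC")

scores = responder_scores(cells)
calls = classify_responders(scores, responder_scores(controls), rule="max")
frac, (lo, hi) = responder_fraction(calls)
print(f"called responder fraction: {frac:.3f} (95% Wilson CI {lo:.3f}-{hi:.3f})")
print(f"generating fraction was 0.150 -> the CI should cover it")

bc = bimodality_coefficient(scores)
print(f"bimodality coefficient of log scores: {bc:.3f} "
      f"({'bimodal' if bc > 5 / 9 else 'unimodal'}; threshold 5/9 = 0.556)")

feats = features_table(cells[:200])
print("\nper-cell features (first rows):")
print(feats[["peak_amplitude", "time_to_peak_min", "auc_steady",
             "expr_p95"]].head().round(3))
print("\nA pulsatile response has near-zero AUC after the first peak "
      "(auc_steady), unlike sustained oscillatory signaling.")
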