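"""Single-cell NF-κB trace featurization and responder calling.

Traces are per-cell time series of the nuclear/cytoplasmic p65 median
intensity ratio (translocation readout) and a destabilized fluorescent
reporter of NF-κB-driven gene expression.  This module extracts the scalar
features used to characterize a response (first-peak amplitude, sustained
post-peak activity, expression percentiles), calls responders against media
controls, and quantifies bimodality and dose response at the population
level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "CellTrace",
    "TraceFeatures",
    "ResponderCall",
    "BIMODALITY_THRESHOLD",
    "qc_filter",
    "extract_features",
    "features_table",
    "responder_scores",
    "classify_responders",
    "responder_fraction",
    "bimodality_coefficient",
    "feature_correlations",
    "compare_count_distributions",
]

#: A bimodality coefficient above this value (the uniform distribution's
#: 5/9) is conventionally flagged as bimodal.
BIMODALITY_THRESHOLD = 5.0 / 9.0


@dataclass
class CellTrace:
    """One cell's time course.

    ``nc_ratio`` is nuclear/cytoplasmic median p65 intensity; ``reporter`` is
    the summed nuclear+cytoplasmic median reporter intensity.  ``nuc_p65`` and
    ``cyt_p65`` are kept when available so the initial-expression QC filter
    can operate on total p65.
    """

    cell_id: str
    time_min: np.ndarray
    nc_ratio: np.ndarray
    reporter: np.ndarray
    stimulus: str = ""
    concentration: float = np.nan
    t_stim_min: float = 0.0
    nuc_p65: np.ndarray | None = None
    cyt_p65: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.nc_ratio = np.asarray(self.nc_ratio, dtype=float)
        self.reporter = np.asarray(self.reporter, dtype=float)
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError(f"{self.cell_id}: time_min must be strictly increasing")
        if not (len(self.time_min) == len(self.nc_ratio) == len(self.reporter)):
            raise ValueError(f"{self.cell_id}: series lengths differ")
        if np.any(self.nc_ratio <= 0):
            raise ValueError(f"{self.cell_id}: nc_ratio must be positive")
        for arr in (self.nuc_p65, self.cyt_p65):
            if arr is not None and len(arr) != len(self.time_min):
                raise ValueError(f"{self.cell_id}: p65 series length differs")

    @property
    def total_p65(self) -> np.ndarray | None:
        if self.nuc_p65 is None or self.cyt_p65 is None:
            return None
        return np.asarray(self.nuc_p65) + np.asarray(self.cyt_p65)


@dataclass
class TraceFeatures:
    """Scalar features of one trace; peak fields are None when no peak."""

    cell_id: str
    peak_amplitude: float | None
    time_to_peak_min: float | None
    auc_steady: float | None
    n_peaks: int
    expr_p95: float
    expr_max: float
    stimulus: str = ""
    concentration: float = np.nan


@dataclass
class ResponderCall:
    cell_id: str
    score: float
    status: str  # "responder" | "non_responder"
    threshold_used: float


def qc_filter(
    traces: Sequence[CellTrace], low_pct: float = 25.0, high_pct: float = 99.0
) -> list[CellTrace]:
    """Reject cells whose initial total p65 expression is an outlier.

    The initial expression of each cell is its mean total p65 before the
    stimulus; cells outside the population's [low_pct, high_pct] percentile
    range (inclusive boundaries, lower-value percentile convention) are
    removed.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("empty trace set")
    initial = []
    for tr in traces:
        tot = tr.total_p65
        if tot is None:
            raise ValueError(f"{tr.cell_id}: nuc/cyt p65 required for QC")
        pre = tr.time_min < tr.t_stim_min
        if not pre.any():
            raise ValueError(f"{tr.cell_id}: no pre-stimulus frame")
        initial.append(float(np.mean(tot[pre])))
    initial = np.asarray(initial)
    if len(traces) == 1:
        warnings.warn("single trace: percentile QC is degenerate, keeping it",
                      stacklevel=2)
        return traces
    lo = np.percentile(initial, low_pct, method="lower")
    hi = np.percentile(initial, high_pct, method="lower")
    keep = (initial >= lo) & (initial <= hi)
    return [tr for tr, k in zip(traces, keep) if k]


def extract_features(
    trace: CellTrace,
    min_prominence: float | None = None,
    baseline_window: float | None = None,
) -> TraceFeatures:
    """Extract translocation and expression features from one trace.

    The baseline is the median pre-stimulus ratio (restricted to the last
    ``baseline_window`` minutes before the stimulus if given).  Peaks are
    post-stimulus local maxima with prominence at least ``min_prominence``
    (default 10% of baseline).  ``auc_steady`` integrates the
    baseline-subtracted ratio, clipped at zero, from the first trough after
    the first peak to the end of the trace (trapezoid rule) — a pulse that
    returns to baseline scores ~0, sustained or oscillatory activity scores
    high.
    """
    t, y = trace.time_min, trace.nc_ratio
    pre = t < trace.t_stim_min
    post = t >= trace.t_stim_min
    if not post.any():
        raise ValueError(f"{trace.cell_id}: no post-stimulus frames")
    if not pre.any():
        raise ValueError(f"{trace.cell_id}: no pre-stimulus frames")
    pre_mask = pre
    if baseline_window is not None:
        pre_mask = pre & (t >= trace.t_stim_min - baseline_window)
    baseline = float(np.median(y[pre_mask]))
    if min_prominence is None:
        min_prominence = 0.1 * baseline

    y_post = y[post]
    t_post = t[post]
    peaks, _ = signal.find_peaks(y_post, prominence=min_prominence)
    n_peaks = int(len(peaks))

    expr_p95 = float(np.percentile(trace.reporter, 95))
    expr_max = float(np.max(trace.reporter))

    if n_peaks == 0:
        return TraceFeatures(
            trace.cell_id, None, None, None, 0, expr_p95, expr_max,
            trace.stimulus, trace.concentration,
        )

    first = peaks[0]
    peak_amplitude = float(np.max(y_post) - baseline)
    time_to_peak = float(t_post[first] - trace.t_stim_min)

    # first trough after the first peak: first local minimum, else global
    # minimum of the remaining trace
    tail = y_post[first:]
    troughs, _ = signal.find_peaks(-tail)
    trough = first + (int(troughs[0]) if len(troughs) else int(np.argmin(tail)))
    seg_t = t_post[trough:]
    seg_y = np.maximum(y_post[trough:] - baseline, 0.0)
    auc = float(np.trapezoid(seg_y, seg_t)) if len(seg_t) > 1 else 0.0

    return TraceFeatures(
        trace.cell_id, peak_amplitude, time_to_peak, auc, n_peaks,
        expr_p95, expr_max, trace.stimulus, trace.concentration,
    )


def features_table(
    traces: Sequence[CellTrace],
    min_prominence: float | None = None,
    baseline_window: float | None = None,
) -> pd.DataFrame:
    """Feature extraction over a trace set, as a DataFrame indexed by cell."""
    rows = [
        vars(extract_features(tr, min_prominence, baseline_window))
        for tr in traces
    ]
    return pd.DataFrame(rows).set_index("cell_id")


def responder_scores(
    traces: Sequence[CellTrace], window_min: float | None = None
) -> pd.Series:
    """Per-cell responder score: max nc_ratio within a post-stimulus window.

    ``window_min=None`` uses the full post-stimulus trace; fixed-cell style
    scoring uses e.g. ``window_min=30``.
    """
    out = {}
    for tr in traces:
        mask = tr.time_min >= tr.t_stim_min
        if window_min is not None:
            mask &= tr.time_min <= tr.t_stim_min + window_min
        if not mask.any():
            raise ValueError(f"{tr.cell_id}: empty scoring window")
        out[tr.cell_id] = float(np.max(tr.nc_ratio[mask]))
    return pd.Series(out, name="score")


def classify_responders(
    scores: Mapping[str, float] | pd.Series,
    control_scores: Sequence[float],
    rule: str = "max",
) -> list[ResponderCall]:
    """Call responders by strict exceedance of a media-control threshold.

    ``rule="max"`` thresholds at the maximum control score;
    ``rule="quantile:q"`` at the q-quantile of the controls (default
    ``quantile`` alone uses q = 0.99).  A cell exactly at the threshold is a
    non-responder ("greater than" is strict).
    """
    control_scores = np.asarray(list(control_scores), dtype=float)
    if control_scores.size == 0:
        raise ValueError("empty control set")
    if control_scores.size < 10:
        warnings.warn(
            f"only {control_scores.size} control cells; >=10 recommended",
            stacklevel=2,
        )
    if rule == "max":
        threshold = float(np.max(control_scores))
    elif rule == "quantile" or rule.startswith("quantile:"):
        q = float(rule.split(":", 1)[1]) if ":" in rule else 0.99
        threshold = float(np.quantile(control_scores, q))
    else:
        raise ValueError(f"unknown rule {rule!r}")
    scores = pd.Series(scores)
    return [
        ResponderCall(
            str(cid),
            float(s),
            "responder" if s > threshold else "non_responder",
            threshold,
        )
        for cid, s in scores.items()
    ]


def responder_fraction(
    calls: Sequence[ResponderCall], ci_level: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Responder fraction with a Wilson score confidence interval."""
    calls = list(calls)
    if not calls:
        raise ValueError("no calls")
    k = sum(c.status == "responder" for c in calls)
    n = len(calls)
    lo, hi = proportion_confint(k, n, alpha=1 - ci_level, method="wilson")
    return k / n, (float(lo), float(hi))


def bimodality_coefficient(
    scores: Sequence[float], log_transform: bool = True
) -> float:
    """Sarle's bimodality coefficient BC = (skewness² + 1) / kurtosis.

    Population (biased) moments and non-excess kurtosis, so a Gaussian gives
    ~1/3 and the uniform distribution exactly 5/9; values above 5/9
    (``BIMODALITY_THRESHOLD``) indicate bimodality.  Computed on log scores
    by default, matching how translocation ratios are summarized.
    """
    x = np.asarray(list(scores), dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 scores")
    if log_transform:
        if np.any(x <= 0):
            raise ValueError("log transform requires positive scores")
        x = np.log(x)
    if np.var(x) == 0:
        raise ValueError("zero variance")
    skew = stats.skew(x, bias=True)
    kurt = stats.kurtosis(x, fisher=False, bias=True)
    return float((skew**2 + 1.0) / kurt)


def feature_correlations(
    features: pd.DataFrame,
    feature_cols: Sequence[str] | None = None,
    concentration_col: str = "concentration",
    stimulus_col: str = "stimulus",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson R between features, and per-stimulus dose R².

    Returns ``(corr, r2)``: ``corr`` is the Pearson correlation matrix over
    feature columns (pairs involving a constant feature are NaN, i.e.
    undefined rather than 0); ``r2`` holds, per stimulus and feature, the R²
    of an ordinary linear regression of the feature on log10(concentration).
    """
    if feature_cols is None:
        feature_cols = [
            c
            for c in features.columns
            if c not in (concentration_col, stimulus_col)
            and pd.api.types.is_numeric_dtype(features[c])
        ]
    if len(features) < 3:
        raise ValueError("need at least 3 cells")
    corr = features[list(feature_cols)].corr(method="pearson", min_periods=2)

    rows = {}
    for stim, sub in features.groupby(stimulus_col) if stimulus_col in features else [("", features)]:
        conc = sub[concentration_col].astype(float)
        if conc.nunique() < 2:
            raise ValueError(f"stimulus {stim!r}: need >=2 distinct concentrations")
        x = np.log10(conc.to_numpy())
        r2 = {}
        for col in feature_cols:
            y = sub[col].astype(float).to_numpy()
            ok = np.isfinite(y) & np.isfinite(x)
            if ok.sum() < 3 or np.var(y[ok]) == 0:
                r2[col] = np.nan
                continue
            res = stats.linregress(x[ok], y[ok])
            r2[col] = res.rvalue**2
        rows[stim] = r2
    return corr, pd.DataFrame(rows).T


def compare_count_distributions(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    n_bins: int = 10,
) -> tuple[float, int, float]:
    """χ² comparison of two count distributions on shared equal-width bins.

    Counts are pooled to define ``n_bins`` equal-width bins (rightmost bin
    closed); bins whose expected count under homogeneity falls below 5 in
    either group are merged rightward (the last bin merges leftward).  The
    resulting 2×k contingency table gives χ² with k−1 degrees of freedom.
    """
    a = np.asarray(list(counts_a), dtype=float)
    b = np.asarray(list(counts_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    if edges[0] == edges[-1]:
        raise ValueError("pooled counts are constant; cannot bin")
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)

    # merge rightward while any expected cell < 5
    ha, hb = list(ha.astype(float)), list(hb.astype(float))
    n_a, n_b, n_tot = a.size, b.size, a.size + b.size

    def expected_ok(xa, xb):
        col = xa + xb
        return min(n_a * col / n_tot, n_b * col / n_tot) >= 5

    i = 0
    while i < len(ha):
        if expected_ok(ha[i], hb[i]):
            i += 1
            continue
        if i + 1 < len(ha):  # merge into the right neighbour
            ha[i + 1] += ha[i]
            hb[i + 1] += hb[i]
            del ha[i], hb[i]
        elif i > 0:  # last bin merges leftward
            ha[i - 1] += ha[i]
            hb[i - 1] += hb[i]
            del ha[i], hb[i]
            i -= 1
            if expected_ok(ha[i], hb[i]):
                i += 1
        else:
            break
    if len(ha) < 2:
        raise ValueError("fewer than 2 bins survive expected-count merging")
    table = np.array([ha, hb])
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
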