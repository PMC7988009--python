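"""Unit tests for NF-κB trace featurization and population statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from episwitch.traces import (
    CellTrace,
    bimodality_coefficient,
    classify_responders,
    compare_count_distributions,
    extract_features,
    feature_correlations,
    qc_filter,
    responder_fraction,
    responder_scores,
)

import pandas as pd


def flat_trace(cell_id="c", value=1.0, total=None, n=50, t_stim=60.0):
    t = np.arange(n) * 5.0
    nc = np.full(n, value)
    total = value * 100 if total is None else total
    cyt = np.full(n, total / (1 + value))
    return CellTrace(cell_id, t, nc, np.zeros(n), t_stim_min=t_stim,
                     nuc_p65=total - cyt, cyt_p65=cyt)


class TestQCFilter:
    def test_percentile_ladder(self):
        """1..100 initial values: the 25-99% rule drops 1-24 and 100."""
        traces = [flat_trace(f"c{v}", total=float(v)) for v in range(1, 101)]
        kept = qc_filter(traces)
        kept_vals = sorted(tr.total_p65[0] for tr in kept)
        assert kept_vals == [float(v) for v in range(25, 100)]
        assert len(kept) == 75

    def test_identical_values_all_kept(self):
        traces = [flat_trace(f"c{i}", total=50.0) for i in range(20)]
        assert len(qc_filter(traces)) == 20

    def test_single_trace_kept_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            kept = qc_filter([flat_trace()])
        assert len(kept) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qc_filter([])


class TestExtractFeatures:
    def test_flat_trace_has_no_peak(self):
        f = extract_features(flat_trace())
        assert f.n_peaks == 0
        assert f.peak_amplitude is None and f.auc_steady is None
        assert f.expr_p95 == 0.0

    def test_triangular_pulse_returns_to_baseline(self):
        """Peak to 3 at 15 min post-stim, back to 1 by 45 min: AUC steady 0."""
        t = np.arange(0, 250, 5.0)
        t_stim = 60.0
        y = np.interp(t, [t_stim, t_stim + 15, t_stim + 45], [1, 3, 1])
        y[t < t_stim] = 1.0
        y[t > t_stim + 45] = 1.0
        f = extract_features(CellTrace("c", t, y, np.zeros_like(t),
                                       t_stim_min=t_stim))
        assert f.peak_amplitude == pytest.approx(2.0)
        assert f.time_to_peak_min == pytest.approx(15.0)
        assert f.auc_steady == pytest.approx(0.0, abs=1e-12)

    def test_pulse_plus_plateau_integrates_plateau(self):
        """A 0.5-high 100-min plateau after the pulse: hand trapezoid 52.5."""
        t = np.arange(0, 300, 5.0)
        t_stim = 60.0
        y = np.interp(t, [t_stim, t_stim + 15, t_stim + 45], [1, 3, 1])
        y[t < t_stim] = 1.0
        y[t > t_stim + 45] = 1.0
        plateau = (t >= t_stim + 50) & (t <= t_stim + 150)
        y = np.where(plateau, 1.5, y)
        f = extract_features(CellTrace("c", t, y, np.zeros_like(t),
                                       t_stim_min=t_stim))
        # plateau 100 min x 0.5 plus the two 5-min ramp trapezoids (2 x 1.25)
        assert f.auc_steady == pytest.approx(52.5, abs=1e-9)

    def test_no_post_stimulus_frames_rejected(self):
        tr = flat_trace(t_stim=1e6)
        with pytest.raises(ValueError, match="post-stimulus"):
            extract_features(tr)

    @given(shift=st.floats(-0.5, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_auc_invariant_to_additive_offset(self, shift):
        """Baseline subtraction makes AUC invariant to a constant offset."""
        t = np.arange(0, 300, 5.0)
        t_stim = 60.0
        rng = np.random.default_rng(0)
        y = 1.0 + np.interp(t, [t_stim, t_stim + 15, t_stim + 200], [0, 2, 0.6])
        y[t < t_stim] = 1.0
        y = y + rng.normal(0, 0.01, y.shape)
        base = extract_features(CellTrace("c", t, y, np.zeros_like(t),
                                          t_stim_min=t_stim))
        shifted = extract_features(
            CellTrace("c", t, y + shift + 1.0, np.zeros_like(t),
                      t_stim_min=t_stim)
        )
        assert shifted.auc_steady == pytest.approx(base.auc_steady, rel=1e-9)


class TestResponderCalling:
    def test_strict_exceedance(self):
        calls = classify_responders({"a": 1.5, "b": 1.2, "c": 1.0},
                                    [1.0, 1.1, 1.2] * 4)
        status = {c.cell_id: c.status for c in calls}
        assert status == {"a": "responder", "b": "non_responder",
                          "c": "non_responder"}

    def test_quantile_rule(self):
        controls = np.linspace(1, 2, 101)
        calls = classify_responders({"a": 1.95, "b": 2.5}, controls,
                                    rule="quantile:0.9")
        assert [c.status for c in calls] == ["responder", "responder"]

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            classify_responders({"a": 1.0}, [])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        scores = dict(enumerate(rng.lognormal(0, 0.5, 50)))
        controls = rng.lognormal(0, 0.5, 40)
        base = [c.status for c in classify_responders(scores, controls)]
        for k in (0.1, 7.3):
            scaled = {i: k * v for i, v in scores.items()}
            got = [c.status for c in classify_responders(scaled, k * controls)]
            assert got == base

    def test_bimodal_population_recovers_fraction(self):
        rng = np.random.default_rng(12)
        n = 1000
        is_resp = rng.random(n) < 0.15
        scores = np.where(is_resp, rng.normal(3, 0.3, n), rng.normal(1, 0.05, n))
        controls = rng.normal(1, 0.05, n)
        calls = classify_responders(dict(enumerate(scores)), controls)
        frac, (lo, hi) = responder_fraction(calls)
        assert lo <= 0.15 <= hi

    def test_wilson_interval_values(self):
        calls = classify_responders(
            dict(enumerate([2.0] * 15 + [1.0] * 85)), [1.5] * 20
        )
        frac, (lo, hi) = responder_fraction(calls)
        assert frac == pytest.approx(0.15)
        assert lo == pytest.approx(0.0931, abs=5e-4)
        assert hi == pytest.approx(0.2328, abs=5e-4)

    def test_degenerate_fractions(self):
        calls = classify_responders(dict(enumerate([0.5] * 30)), [1.0] * 10)
        frac, (lo, hi) = responder_fraction(calls)
        assert frac == 0.0 and lo == 0.0


class TestBimodalityCoefficient:
    def test_uniform_reference_value(self):
        x = np.linspace(0.01, 1, 20001)
        assert bimodality_coefficient(x, log_transform=False) == pytest.approx(
            5 / 9, abs=1e-3
        )

    def test_gaussian_is_one_third(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200_000)
        assert bimodality_coefficient(x, log_transform=False) == pytest.approx(
            1 / 3, abs=0.01
        )

    def test_separated_mixture_flags_bimodal(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(1, 0.02, 500), rng.normal(3, 0.02, 500)])
        assert bimodality_coefficient(np.exp(x)) > 5 / 9  # log-scores

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bimodality_coefficient([2.0, 2.0, 2.0, 2.0], log_transform=False)


class TestFeatureCorrelations:
    def test_self_correlation_and_perfect_regression(self):
        conc = np.repeat([0.01, 0.1, 1.0], 10)
        rng = np.random.default_rng(4)
        amp = rng.normal(2, 0.5, 30)
        df = pd.DataFrame(
            {
                "peak_amplitude": amp,
                "expr_p95": 2 * np.log10(conc),
                "concentration": conc,
                "stimulus": "x",
            }
        )
        corr, r2 = feature_correlations(df)
        assert corr.loc["peak_amplitude", "peak_amplitude"] == pytest.approx(1.0)
        assert r2.loc["x", "expr_p95"] == pytest.approx(1.0)

    def test_constant_feature_is_undefined_not_zero(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 1.0, 1.0, 1.0],
                "b": [1.0, 2.0, 3.0, 4.0],
                "concentration": [0.1, 0.1, 1.0, 1.0],
                "stimulus": "x",
            }
        )
        corr, r2 = feature_correlations(df)
        assert np.isnan(corr.loc["a", "b"])
        assert np.isnan(r2.loc["x", "a"])

    def test_independent_latent_state_gives_low_correlation(self):
        rng = np.random.default_rng(9)
        n = 2000
        amp = rng.normal(2, 0.5, n)
        expr = rng.normal(10, 2, n)  # driven by an unrelated latent state
        df = pd.DataFrame(
            {"peak_amplitude": amp, "expr_p95": expr,
             "concentration": np.tile([0.1, 1.0], n // 2), "stimulus": "x"}
        )
        corr, _ = feature_correlations(df)
        assert abs(corr.loc["peak_amplitude", "expr_p95"]) < 0.08


class TestCompareCountDistributions:
    def test_identical_distributions_are_null(self):
        a = np.arange(100)
        chi2, df, p = compare_count_distributions(a, a)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_ten_surviving_bins_give_nine_df(self):
        """When all 10 bins stay above the expected-count floor, df = 9."""
        rng = np.random.default_rng(0)
        a = rng.integers(0, 30, 150)
        b = rng.integers(5, 35, 200)
        chi2, df, p = compare_count_distributions(a, b)
        assert df == 9

    def test_separated_poissons_are_detected(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(2, 150)
        b = rng.poisson(20, 200)
        chi2, df, p = compare_count_distributions(a, b)
        assert p < 1e-10
        assert 2 <= df <= 9

    def test_label_symmetry(self):
        rng = np.random.default_rng(5)
        a = rng.poisson(5, 120)
        b = rng.poisson(8, 150)
        assert compare_count_distributions(a, b)[0] == pytest.approx(
            compare_count_distributions(b, a)[0]
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_count_distributions([], [1, 2])


class TestResponderScores:
    def test_window_restricts_scoring(self):
        t = np.arange(0, 300, 5.0)
        y = np.ones_like(t)
        y[t > 200] = 5.0  # late excursion
        tr = CellTrace("c", t, y, np.zeros_like(t), t_stim_min=60.0)
        assert responder_scores([tr], window_min=30).iloc[0] == pytest.approx(1.0)
        assert responder_scores([tr]).iloc[0] == pytest.approx(5.0)
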