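"""Reproducible simulation experiments at the study's scale.

Each function simulates data under the study conditions (switching
probabilities 0.01 / 0.055 per generation, ~15% stationary responder
fraction), runs the corresponding analysis stage, and reports recovery /
calibration summaries.  All randomness is derived from a single seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import lineage as ln
from . import methylation as meth
from . import spatial as sp
from . import synth
from . import traces as tr

__all__ = [
    "child_seeds",
    "parameter_recovery",
    "ci_halfwidth_study",
    "spatial_calibration",
    "methyl_mixture_recovery",
    "responder_fraction_recovery",
]

PAPER_RATES = ln.SwitchingRates(0.01, 0.055)


def child_seeds(seed: int, n: int) -> list[int]:
    """n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def parameter_recovery(
    seed: int = 0,
    n_replicates: int = 20,
    n_lineages: int = 500,
    max_generations: int = 5,
    rates: ln.SwitchingRates = PAPER_RATES,
    ci: bool = False,
) -> dict:
    """Simulate complete lineage forests and refit the switching rates.

    Roots are drawn from the stationary distribution and the fit ties the
    root fraction to it (model-consistent).  Returns per-replicate
    estimates and their medians; with ``ci=True`` profile intervals are
    computed per replicate and their coverage of the truth reported.
    """
    f_ss = ln.stationary_fraction(rates)
    est_on, est_off, cover_on, cover_off = [], [], [], []
    for s in child_seeds(seed, n_replicates):
        trees = ln.simulate_lineages(
            rates, f_ss, n_lineages, max_generations, death_prob=0.0, seed=s
        )
        fit = ln.fit_switching_rates(
            trees,
            root_dist_mode="stationary",
            ci_method="profile" if ci else "none",
            n_starts=3,
        )
        est_on.append(fit.p_on)
        est_off.append(fit.p_off)
        if ci:
            cover_on.append(fit.ci_on[0] <= rates.p_on <= fit.ci_on[1])
            cover_off.append(fit.ci_off[0] <= rates.p_off <= fit.ci_off[1])
    out = {
        "p_on_estimates": np.array(est_on),
        "p_off_estimates": np.array(est_off),
        "p_on_median": float(np.median(est_on)),
        "p_off_median": float(np.median(est_off)),
        "n_replicates": n_replicates,
        "n_lineages": n_lineages,
    }
    if ci:
        out["coverage_on"] = float(np.mean(cover_on))
        out["coverage_off"] = float(np.mean(cover_off))
    return out


def ci_halfwidth_study(
    seed: int = 0,
    n_replicates: int = 100,
    rates: ln.SwitchingRates = PAPER_RATES,
) -> dict:
    """Profile-CI width and coverage at the lineage-tracing study scale.

    Each replicate simulates 58 lineages of up to five generations with
    censoring tuned to ~273 divisions total, fits by maximum likelihood and
    computes 95% profile-likelihood intervals for both rates.
    """
    design = ln.study_scale_design()
    f_ss = ln.stationary_fraction(rates)
    hw_on, hw_off, cover_on, cover_off, divisions = [], [], [], [], []
    for s in child_seeds(seed, n_replicates):
        trees = ln.simulate_lineages(rates, f_ss, seed=s, **design)
        if sum(len(t.observed_leaves) for t in trees) < 10:
            continue
        fit = ln.fit_switching_rates(
            trees, root_dist_mode="stationary", ci_method="profile"
        )
        hw_on.append((fit.ci_on[1] - fit.ci_on[0]) / 2)
        hw_off.append((fit.ci_off[1] - fit.ci_off[0]) / 2)
        cover_on.append(fit.ci_on[0] <= rates.p_on <= fit.ci_on[1])
        cover_off.append(fit.ci_off[0] <= rates.p_off <= fit.ci_off[1])
        divisions.append(sum(t.n_divisions for t in trees))
    return {
        "halfwidth_on_median": float(np.median(hw_on)),
        "halfwidth_off_median": float(np.median(hw_off)),
        "coverage_on": float(np.mean(cover_on)),
        "coverage_off": float(np.mean(cover_off)),
        "mean_divisions": float(np.mean(divisions)),
        "n_replicates": len(hw_on),
    }


def spatial_calibration(
    seed: int = 0,
    n_null_fields: int = 500,
    n_power_fields: int = 150,
    n_perm: int = 499,
    alpha: float = 0.05,
) -> dict:
    """False-positive rate on label-shuffled fields and power on grown ones.

    Fields are grown by lineage expansion (depth 3, heritable state); the
    null fields are the same geometries with responder labels shuffled.
    """
    seeds = child_seeds(seed, 3)
    rng = np.random.default_rng(seeds[0])
    null_rej = []
    for i, s in enumerate(child_seeds(seeds[1], n_null_fields)):
        field, _ = synth.gen_monolayer_field(synth.GeneratorConfig(seed=s))
        labels = field.labels.copy()
        rng.shuffle(labels)
        shuffled = sp.MonolayerField(field.positions, labels, f"null{i}")
        res = sp.permutation_test(shuffled, n_perm=n_perm, seed=s)
        null_rej.append(res.p_value <= alpha)
    power_rej = []
    for s in child_seeds(seeds[2], n_power_fields):
        field, _ = synth.gen_monolayer_field(synth.GeneratorConfig(seed=s))
        res = sp.permutation_test(field, n_perm=n_perm, seed=s)
        power_rej.append(res.p_value <= alpha)
    return {
        "false_positive_rate": float(np.mean(null_rej)),
        "power": float(np.mean(power_rej)),
        "n_null_fields": n_null_fields,
        "n_power_fields": n_power_fields,
    }


def methyl_mixture_recovery(
    seed: int = 0, n_seeds: int = 100, tolerance: float = 0.05
) -> dict:
    """EM mixture-weight recovery over replicate 500-read synthetic matrices."""
    window = meth.PromoterWindow(-110, -60)
    hits, errors = [], []
    for s in child_seeds(seed, n_seeds):
        cfg = synth.GeneratorConfig(seed=s)
        mat, states = synth.gen_methyl_reads(cfg)
        counts = meth.window_unmethylated_counts(mat, window)
        n_sites = int(window.contains(mat.cpg_positions).sum())
        fit = meth.fit_binomial_mixture(counts, n_sites, seed=s)
        err = abs(fit.weight_unmeth - cfg.methyl.weight_unmeth)
        errors.append(err)
        hits.append(err <= tolerance)
    return {
        "fraction_within_tolerance": float(np.mean(hits)),
        "median_abs_error": float(np.median(errors)),
        "n_seeds": n_seeds,
    }


def responder_fraction_recovery(
    seed: int = 0,
    n_seeds: int = 100,
    n_cells: int = 300,
    true_fraction: float = 0.15,
) -> dict:
    """End-to-end responder-fraction recovery with Wilson-CI coverage.

    Each replicate generates a stimulated population and an equal-size
    media-control population, scores the maximum post-stimulus N/C ratio,
    calls responders against the control maximum, and checks whether the
    Wilson interval covers the generating fraction.
    """
    covered, fracs = [], []
    for s in child_seeds(seed, n_seeds):
        s2 = (s + 1) % (2**31)
        params = synth.TraceParams(n_cells=n_cells,
                                   responder_fraction=true_fraction)
        cfg = synth.GeneratorConfig(seed=s, trace=params)
        cells, _ = synth.gen_trace_set(cfg)
        ctrl_cfg = replace(cfg, trace=replace(params, responder_fraction=0.0))
        controls, _ = synth.gen_trace_set(ctrl_cfg, seed=s2)
        calls = tr.classify_responders(
            tr.responder_scores(cells), tr.responder_scores(controls)
        )
        frac, (lo, hi) = tr.responder_fraction(calls)
        covered.append(lo <= true_fraction <= hi)
        fracs.append(frac)
    return {
        "ci_coverage": float(np.mean(covered)),
        "mean_called_fraction": float(np.mean(fracs)),
        "n_seeds": n_seeds,
        "n_cells": n_cells,
    }
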