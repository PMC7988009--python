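"""Seeded synthetic-data generators for every analysis stage.

The generators reproduce the statistical structure the analyses assume —
heritable binary responder state with rare per-generation switching on
expanding lineages, single-pulse vs. flat NF-κB traces with a delayed
destabilized reporter, spatially clustered responders arising from lineage
expansion, en-bloc bimodal promoter methylation reads, and a capped Hill
dose response — so the whole pipeline is testable without any download.

Defaults are anchored to the study conditions: switching probabilities
(0.01, 0.055) per generation, a ~15% stationary responder fraction
(= 0.01/0.065), 5-minute imaging frames, lineages of up to five
generations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import lineage as _lineage
from .lineage import LineageTree, SwitchingRates, stationary_fraction
from .methylation import M, MISSING, U, MethylReadMatrix, PromoterWindow
from .spatial import MonolayerField
from .traces import CellTrace

__all__ = [
    "LineageParams",
    "TraceParams",
    "SpatialParams",
    "MethylParams",
    "DoseParams",
    "GeneratorConfig",
    "gen_trace_set",
    "gen_monolayer_field",
    "gen_methyl_reads",
    "gen_dose_response",
]

_RATES = SwitchingRates(0.01, 0.055)
_F_SS = stationary_fraction(_RATES)  # 0.1538...


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name}={p} is not a probability")


@dataclass(frozen=True)
class LineageParams:
    """Lineage simulation parameters (study-scale defaults)."""

    p_on: float = 0.01
    p_off: float = 0.055
    initial_fraction: float | None = None  # None -> stationary fraction
    n_lineages: int = 58
    max_generations: int = 5
    death_prob: float = 0.39

    @property
    def rates(self) -> SwitchingRates:
        return SwitchingRates(self.p_on, self.p_off)

    @property
    def root_fraction(self) -> float:
        if self.initial_fraction is not None:
            return self.initial_fraction
        return stationary_fraction(self.rates)


@dataclass(frozen=True)
class TraceParams:
    """NF-κB trace generator parameters.

    Responders emit a single translocation pulse (``mode="pulsatile"``) or
    sustained damped oscillations (``mode="oscillatory"``) on top of a noisy
    baseline ratio; non-responders stay flat.  The reporter integrates
    supra-threshold nuclear activity with first-order decay mimicking a
    destabilized (PEST) fluorophore.
    """

    n_cells: int = 400
    responder_fraction: float = _F_SS
    frame_min: float = 5.0
    duration_min: float = 480.0
    t_stim_min: float = 45.0
    mode: str = "pulsatile"  # or "oscillatory"
    baseline_mean: float = 1.0
    baseline_sd: float = 0.05
    noise_sd: float = 0.03
    peak_amplitude_mean: float = 2.0
    peak_amplitude_sd: float = 0.4
    time_to_peak_min: float = 15.0
    osc_period_min: float = 75.0
    osc_plateau: float = 0.45
    osc_decay_min: float = 600.0
    reporter_basal: float = 20.0
    reporter_k_prod: float = 10.0
    reporter_halflife_min: float = 90.0
    reporter_threshold: float = 0.3
    total_p65_mean: float = 500.0
    total_p65_cv: float = 0.3


@dataclass(frozen=True)
class SpatialParams:
    """Monolayer growth parameters for lineage-coupled cell placement."""

    n_lineages: int = 40
    max_generations: int = 3
    death_prob: float = 0.0
    displacement_sd_um: float = 15.0
    field_size_um: float = 500.0


@dataclass(frozen=True)
class MethylParams:
    """Per-read promoter methylation generator parameters.

    Each read carries a hidden block state (unmethylated with probability
    ``weight_unmeth``); per-site calls flip with ``error_rate`` and drop out
    with ``missing_rate``.  With ``group_10bp`` the caller's resolution
    limit is emulated: CpGs within 10 bp share a single call draw.
    """

    n_reads: int = 500
    weight_unmeth: float = 0.6
    error_rate: float = 0.05
    missing_rate: float = 0.05
    group_10bp: bool = False
    cpg_positions: tuple[int, ...] = (
        -125, -118, -110, -103, -96, -89, -82, -75, -68, -61, -50, -40,
    )


@dataclass(frozen=True)
class DoseParams:
    """Capped Hill dose response: P(respond | c) = f_max c^h/(c^h + EC50^h)."""

    ec50: float = 0.1  # stimulus units (e.g. µg/ml)
    hill: float = 1.5
    f_max: float | None = None  # None -> stationary fraction of the rates
    n_cells_per_dose: int = 2000


@dataclass(frozen=True)
class GeneratorConfig:
    """Bundle of all generator parameter groups plus the master seed."""

    seed: int = 0
    lineage: LineageParams = field(default_factory=LineageParams)
    trace: TraceParams = field(default_factory=TraceParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    methyl: MethylParams = field(default_factory=MethylParams)
    dose: DoseParams = field(default_factory=DoseParams)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


def _pulse(dt: np.ndarray, amp: float, tp: float) -> np.ndarray:
    """Alpha-function pulse peaking at ``tp`` minutes after onset."""
    x = np.maximum(dt, 0.0) / tp
    return amp * x * np.exp(1.0 - x)


def gen_trace_set(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[list[CellTrace], pd.DataFrame]:
    """Generate a trace set and its ground-truth responder labels.

    Returns ``(traces, truth)`` where ``truth`` has columns ``cell_id`` and
    ``responder``.  Setting ``responder_fraction=0`` yields a media-control
    population.
    """
    p = config.trace
    if p.mode not in ("pulsatile", "oscillatory"):
        raise ValueError(f"unknown trace mode {p.mode!r}")
    _check_prob("responder_fraction", p.responder_fraction)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    t = np.arange(0.0, p.duration_min + p.frame_min / 2, p.frame_min)
    dt = t - p.t_stim_min
    k_dec = np.log(2.0) / p.reporter_halflife_min
    n, T = p.n_cells, len(t)

    responder = rng.random(n) < p.responder_fraction
    base = np.maximum(rng.normal(p.baseline_mean, p.baseline_sd, size=n), 0.3)
    amp = np.maximum(
        rng.normal(p.peak_amplitude_mean, p.peak_amplitude_sd, size=n), 0.5
    )
    amp = np.where(responder, amp, 0.0)

    nc = base[:, None] + amp[:, None] * (_pulse(dt, 1.0, p.time_to_peak_min))[None, :]
    if p.mode == "oscillatory":
        osc = (
            p.osc_plateau
            * (0.75 + 0.25 * np.cos(2 * np.pi * dt / p.osc_period_min))
            * np.exp(-np.maximum(dt, 0.0) / p.osc_decay_min)
        )
        nc = nc + amp[:, None] * np.where(dt > p.time_to_peak_min, osc, 0.0)[None, :]
    if p.noise_sd > 0:
        nc = nc + rng.normal(0.0, p.noise_sd, size=(n, T))
    nc = np.maximum(nc, 0.05)

    # destabilized reporter: produce while activity above threshold, decay
    rep = np.empty((n, T))
    rep[:, 0] = p.reporter_basal
    active = (nc - base[:, None]) > p.reporter_threshold
    for j in range(1, T):
        prod = np.where(active[:, j - 1], p.reporter_k_prod, 0.0)
        rep[:, j] = rep[:, j - 1] + p.frame_min * (
            prod - k_dec * (rep[:, j - 1] - p.reporter_basal)
        )
    if p.noise_sd > 0:
        rep = rep + rng.normal(0.0, p.noise_sd * p.reporter_basal * 0.1, size=(n, T))
    rep = np.maximum(rep, 0.0)

    total = p.total_p65_mean * rng.lognormal(0.0, p.total_p65_cv, size=n)
    cyt = total[:, None] / (1.0 + nc)
    nuc = total[:, None] - cyt
    stim = "Pam3CSK4" if p.responder_fraction > 0 else "media"
    traces = [
        CellTrace(
            cell_id=f"cell{i:04d}",
            time_min=t,
            nc_ratio=nc[i],
            reporter=rep[i],
            stimulus=stim,
            concentration=1.0,
            t_stim_min=p.t_stim_min,
            nuc_p65=nuc[i],
            cyt_p65=cyt[i],
        )
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {"cell_id": [tr.cell_id for tr in traces], "responder": responder}
    )
    return traces, truth


# ---------------------------------------------------------------------------
# Monolayer fields
# ---------------------------------------------------------------------------


def gen_monolayer_field(
    config: GeneratorConfig, seed: int | None = None, field_id: str = "field"
) -> tuple[MonolayerField, list[LineageTree]]:
    """Grow a monolayer by lineage expansion with local daughter placement.

    Lineages are simulated with the switching model; each daughter is placed
    at its mother's position plus isotropic Gaussian displacement.  The
    terminal observed cells form the field; the generating trees are
    returned for ground truth.
    """
    sp, lp = config.spatial, config.lineage
    rng = np.random.default_rng(config.seed if seed is None else seed)
    trees = _lineage.simulate_lineages(
        lp.rates,
        lp.root_fraction,
        sp.n_lineages,
        sp.max_generations,
        death_prob=sp.death_prob,
        rng=rng,
    )
    positions, labels = [], []
    for tree in trees:
        pos = np.empty((tree.n_nodes, 2))
        order = np.argsort(tree.generation, kind="stable")
        for i in order:
            par = tree.parent[i]
            if par < 0:
                pos[i] = rng.uniform(0.0, sp.field_size_um, size=2)
            else:
                pos[i] = pos[par] + rng.normal(0.0, sp.displacement_sd_um, size=2)
        obs = tree.observed_leaves
        positions.append(pos[obs])
        labels.append(tree.status[obs] == _lineage.R)
    field_obj = MonolayerField.from_arrays(
        np.concatenate(positions),
        np.concatenate(labels),
        field_id=field_id,
        jitter_seed=int(rng.integers(2**31)),
    )
    return field_obj, trees


# ---------------------------------------------------------------------------
# Methylation reads
# ---------------------------------------------------------------------------


def _grouping(positions: np.ndarray) -> list[np.ndarray]:
    """Partition sorted positions into runs whose successive gaps are <10 bp."""
    groups = [[0]]
    for j in range(1, len(positions)):
        if positions[j] - positions[j - 1] < 10:
            groups[-1].append(j)
        else:
            groups.append([j])
    return [np.asarray(g) for g in groups]


def gen_methyl_reads(
    config: GeneratorConfig,
    window: PromoterWindow | None = None,
    seed: int | None = None,
) -> tuple[MethylReadMatrix, np.ndarray]:
    """Generate per-read CpG calls with hidden en-bloc states.

    Returns ``(matrix, true_states)`` where ``true_states[i]`` is True for
    reads whose hidden block state is unmethylated.
    """
    mp = config.methyl
    _check_prob("weight_unmeth", mp.weight_unmeth)
    _check_prob("error_rate", mp.error_rate)
    _check_prob("missing_rate", mp.missing_rate)
    positions = np.asarray(sorted(mp.cpg_positions), dtype=int)
    if window is not None and int(window.contains(positions).sum()) < 2:
        raise ValueError("fewer than 2 CpGs in the requested window")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    unmeth = rng.random(mp.n_reads) < mp.weight_unmeth
    n_sites = len(positions)
    if mp.group_10bp:
        groups = _grouping(positions)
        calls = np.empty((mp.n_reads, n_sites), dtype=np.int8)
        for g in groups:
            err = rng.random(mp.n_reads) < mp.error_rate
            call = np.where(unmeth ^ err, U, M).astype(np.int8)
            calls[:, g] = call[:, None]
    else:
        err = rng.random((mp.n_reads, n_sites)) < mp.error_rate
        calls = np.where(unmeth[:, None] ^ err, U, M).astype(np.int8)
    miss = rng.random((mp.n_reads, n_sites)) < mp.missing_rate
    calls[miss] = MISSING

    keep = ~np.all(calls == MISSING, axis=1)
    if not keep.any():
        raise ValueError("all reads are entirely missing")
    read_ids = [f"read{i:05d}" for i in np.flatnonzero(keep)]
    return (
        MethylReadMatrix(read_ids, positions, calls[keep], region_label="synthetic"),
        unmeth[keep],
    )


# ---------------------------------------------------------------------------
# Dose response
# ---------------------------------------------------------------------------


def gen_dose_response(
    config: GeneratorConfig,
    concentrations: Sequence[float],
    seed: int | None = None,
) -> pd.DataFrame:
    """Binomial responder counts along a capped Hill dose-response curve."""
    dp, lp = config.dose, config.lineage
    conc = np.asarray(list(concentrations), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    f_max = dp.f_max if dp.f_max is not None else stationary_fraction(lp.rates)
    _check_prob("f_max", f_max)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    p = f_max * conc**dp.hill / (conc**dp.hill + dp.ec50**dp.hill)
    k = rng.binomial(dp.n_cells_per_dose, p)
    return pd.DataFrame(
        {
            "concentration": conc,
            "n_cells": dp.n_cells_per_dose,
            "n_responders": k,
            "fraction": k / dp.n_cells_per_dose,
            "p_true": p,
        }
    )
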