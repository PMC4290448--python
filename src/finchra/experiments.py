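"""Sweep experiments linking circuit parameters to RA variability.

Each *realization* draws one HVC->RA weight vector and simulates N song
renditions with independent LMAN noise against the fixed HVC raster; the
rendition-to-rendition CC is averaged across realizations.  The sweep axes
mirror the model manipulations: moving jointly along the
strengthening-and-pruning axis (rho with its anchored mean/SD), either arm
alone, scaling LMAN strength, changing the AMPA fraction, the membrane time
constant (neuron gain), LMAN burstiness, and song-locked sine modulation.
Tonic inhibition is recomputed from each grid point's (m, rho) on every
axis, since V_INH is defined as a function of the HVC drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import spikegen, weights
from .ra_model import ModelParams, simulate_renditions, tonic_inhibition
from .spikegen import LMANConfig
from .variability import cc_average

__all__ = [
    "SweepSpec",
    "SweepResult",
    "PointResult",
    "run_point",
    "run_sweep",
    "lman_weakening_share",
    "SWEEP_AXES",
]

SWEEP_AXES = (
    "strengthen_and_prune",
    "strengthen_only",
    "prune_only",
    "lman_strength",
    "nmda_ratio",
    "gain_tau_m",
    "burstiness",
    "song_lock",
)

# Desk-scale defaults; the original study averaged 5000 realizations of
# 200 renditions each.
DEFAULT_N_REALIZATIONS = 50
DEFAULT_N_RENDITIONS = 200


@dataclass
class SweepSpec:
    """One sweep: an axis, its grid, and the simulation budget."""

    axis: str
    grid: list[float] | np.ndarray
    n_realizations: int = DEFAULT_N_REALIZATIONS
    n_renditions: int = DEFAULT_N_RENDITIONS
    base_params: ModelParams = field(default_factory=ModelParams)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.axis not in SWEEP_AXES:
            raise ValueError(f"unknown axis {self.axis!r}; one of {SWEEP_AXES}")
        self.grid = np.asarray(self.grid, dtype=float)


@dataclass
class SweepResult:
    """Per-grid-point mean CC, its SE over realizations, and mean RA rate."""

    spec: SweepSpec
    table: pd.DataFrame  # columns: axis_value, mean_cc, se, mean_rate_hz

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class PointResult:
    mean_cc: float
    se: float
    mean_rate_hz: float
    cc_values: np.ndarray = field(repr=False)
    rate_values: np.ndarray = field(repr=False)


def run_point(
    connectivity: tuple[float, float, float],
    lman: LMANConfig,
    params: ModelParams = ModelParams(),
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    n_renditions: int = DEFAULT_N_RENDITIONS,
    seed: int | np.random.SeedSequence | None = None,
) -> PointResult:
    """Mean CC +/- SE and mean RA rate at one parameter point.

    ``connectivity`` is (rho, m, s).  Each realization redraws the weight
    vector and all LMAN trains; the HVC raster is fixed by construction.
    """
    if n_renditions < 2:
        raise ValueError("need at least two renditions for a CC")
    rho, m, s = connectivity
    hvc = spikegen.hvc_song(params.n_hvc, params.song_dur)
    v_inh = tonic_inhibition(m, rho, params)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ccs = np.empty(n_realizations)
    rates = np.empty(n_realizations)
    for i, child in enumerate(ss.spawn(n_realizations)):
        rng = np.random.default_rng(child)
        profile = weights.sample_weights(rho, m, s, params.n_hvc, rng)
        lman_trains = [lman.make(params.song_dur, rng) for _ in range(n_renditions)]
        ra = simulate_renditions(profile, hvc, lman_trains, params, v_inh=v_inh)
        ccs[i] = cc_average(ra, keep_matrix=False).mean_cc
        rates[i] = float(np.mean([t.rate_hz for t in ra]))
    se = float(ccs.std(ddof=1) / np.sqrt(n_realizations)) if n_realizations > 1 else 0.0
    return PointResult(
        mean_cc=float(ccs.mean()),
        se=se,
        mean_rate_hz=float(rates.mean()),
        cc_values=ccs,
        rate_values=rates,
    )


def _point_config(
    axis: str, value: float, base: ModelParams
) -> tuple[tuple[float, float, float], LMANConfig, ModelParams]:
    """Map one grid value on one axis to (connectivity, LMAN config, params).

    The standard model sits at rho = 0.9 with (m, s) = (50, 35) pA; the
    strengthen-only and prune-only arms are anchored there and vary one
    ingredient of profile_at's joint trajectory at a time.
    """
    rho0 = 0.9
    m0, s0 = weights.profile_at(rho0)
    conn = (rho0, m0, s0)
    lman = LMANConfig()
    params = base
    if axis == "strengthen_and_prune":
        m, s = weights.profile_at(value)
        conn = (value, m, s)
    elif axis == "strengthen_only":
        m, s = weights.profile_at(value)  # value indexes the (m, s) trajectory
        conn = (rho0, m, s)
    elif axis == "prune_only":
        conn = (value, m0, s0)
    elif axis == "lman_strength":
        params = base.with_(W_LMAN=base.W_LMAN * value)
    elif axis == "nmda_ratio":
        params = base.with_(r=value)
    elif axis == "gain_tau_m":
        params = base.with_(tau_m=value)
    elif axis == "burstiness":
        lman = LMANConfig(burst_fraction=value)
    elif axis == "song_lock":
        lman = LMANConfig(mod_depth=value)
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return conn, lman, params


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Run one sweep axis over its grid; seed-deterministic."""
    ss = np.random.SeedSequence(spec.seed)
    rows = []
    for value, child in zip(spec.grid, ss.spawn(len(spec.grid))):
        conn, lman, params = _point_config(spec.axis, float(value), spec.base_params)
        res = run_point(
            conn, lman, params, spec.n_realizations, spec.n_renditions, child
        )
        rows.append(
            {
                "axis_value": float(value),
                "mean_cc": res.mean_cc,
                "se": res.se,
                "mean_rate_hz": res.mean_rate_hz,
            }
        )
    return SweepResult(spec=spec, table=pd.DataFrame(rows))


def lman_weakening_share(
    seed: int | None = None,
    n_realizations: int = DEFAULT_N_REALIZATIONS,
    n_renditions: int = DEFAULT_N_RENDITIONS,
    params: ModelParams = ModelParams(),
    lman_scale: float = 0.5,
) -> float:
    """Percentage of the CC change along the learning axis attributable to
    weakening LMAN input at juvenile connectivity:

        100 * (CC[rho=0.9, scaled W_LMAN] - CC[rho=0.9])
            / (CC[rho=0.37] - CC[rho=0.9])

    With the standard model this share stays well below the full axis
    effect — weakened LMAN drive alone cannot explain the developmental
    drop in variability.
    """
    ss = np.random.SeedSequence(seed)
    s_young, s_adult = (int(x) for x in ss.generate_state(2))
    rho_y, rho_a = 0.9, 0.37
    conn_y = (rho_y, *weights.profile_at(rho_y))
    conn_a = (rho_a, *weights.profile_at(rho_a))
    lman = LMANConfig()
    # common random numbers for the weakened vs standard juvenile points:
    # the share is a difference, and sharing weights/LMAN noise removes most
    # of its Monte-Carlo variance (and makes lman_scale=1 give exactly 0)
    cc_young = run_point(conn_y, lman, params, n_realizations, n_renditions, s_young).mean_cc
    cc_halved = run_point(
        conn_y, lman, params.with_(W_LMAN=params.W_LMAN * lman_scale),
        n_realizations, n_renditions, s_young,
    ).mean_cc
    cc_adult = run_point(conn_a, lman, params, n_realizations, n_renditions, s_adult).mean_cc
    denom = cc_adult - cc_young
    if denom <= 0:
        raise RuntimeError(
            "CC did not increase from rho=0.9 to rho=0.37; simulation misconfigured"
        )
    return 100.0 * (cc_halved - cc_young) / denom
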