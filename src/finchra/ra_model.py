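"""Leaky integrate-and-fire model of an RA projection neuron.

The membrane potential obeys

    tau_m dV/dt = (V_R - V) + R*I_HVC + R*I_LMAN - V_INH

with exponential HVC synapses (tau_s = 5 ms), LMAN input split into a fast
AMPA component and a slow NMDA component (tau_NMDA = 100 ms) whose
increments are scaled by the Jahr-Stevens-style magnesium-block factor
G(V) = 1 / (1 + [Mg]/3.57 mM * exp(-V/16.13 mV)), and tonic inhibition
proportional to the mean HVC drive, V_INH = R_INH * m * rho.  Crossing
V_th emits a spike, resets V to V_R and clamps it there for 1.5 ms while
the synaptic currents keep evolving.

Units are fixed at mV / ms / pA / GOhm so that R[GOhm] * I[pA] = V[mV];
resistances given in MOhm are converted internally.  Integration is forward
Euler on a 0.2 ms grid; spike events are snapped to the grid by flooring,
synaptic increments are applied at the start of the step containing the
event, NMDA increments use the membrane potential *before* that step's
voltage update, and threshold crossings are detected after the update.

Because all renditions of one realization share the HVC raster and weight
vector, many renditions are integrated simultaneously as a vector of
membrane potentials, which is what makes the sweep experiments tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .spikegen import SpikeTrain
from .weights import ConnectivityProfile

__all__ = [
    "ModelParams",
    "NeuronState",
    "nmda_gating",
    "tonic_inhibition",
    "simulate_rendition",
    "simulate_renditions",
]


@dataclass(frozen=True)
class ModelParams:
    """Biophysical constants of the RA neuron model (defaults = standard model)."""

    tau_m: float = 20.0        # membrane time constant, ms (gain axis sweeps 16-25)
    V_R: float = -70.0         # resting / reset potential, mV
    V_th: float = -50.0        # spike threshold, mV
    R: float = 260.0           # input resistance, MOhm
    t_ref: float = 1.5         # refractory period, ms
    tau_s: float = 5.0         # fast (HVC / AMPA) synaptic time constant, ms
    tau_NMDA: float = 100.0    # NMDA synaptic time constant, ms
    W_LMAN: float = 120.0      # LMAN peak EPSC, pA
    r: float = 0.1             # AMPA fraction of the LMAN input
    Mg: float = 0.5            # extracellular Mg2+, mM
    Mg_scale: float = 3.57     # Mg-block concentration scale, mM
    Mg_slope: float = 16.13    # Mg-block voltage scale, mV
    R_INH: float = 800.0       # inhibitory proportionality constant, MOhm
    dt: float = 0.2            # Euler step, ms
    n_hvc: int = 100           # HVC population size
    song_dur: float = 1000.0   # song duration, ms
    E_rev: float = 0.0         # excitatory reversal potential, mV

    def __post_init__(self) -> None:
        if min(self.tau_m, self.tau_s, self.tau_NMDA, self.t_ref) <= 0:
            raise ValueError("time constants must be positive")
        if self.dt <= 0 or self.dt >= min(self.tau_s, self.t_ref):
            raise ValueError("require 0 < dt < min(tau_s, t_ref)")
        if self.V_th <= self.V_R:
            raise ValueError("V_th must exceed V_R")
        if not 0 <= self.r <= 1:
            raise ValueError("AMPA fraction r must be in [0, 1]")

    def with_(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Instantaneous model state (mainly for introspection and tests)."""

    V: float
    I_HVC: float = 0.0
    I_LMAN_AMPA: float = 0.0
    I_LMAN_NMDA: float = 0.0
    refractory_remaining: float = 0.0


def nmda_gating(V: np.ndarray | float, params: ModelParams = ModelParams()):
    """Voltage-dependent magnesium-block factor of the NMDA current,
    G(V) = 1 / (1 + [Mg]/Mg_scale * exp(-V/Mg_slope)); in (0, 1], strictly
    increasing in V, approaching 1 at depolarized potentials."""
    return 1.0 / (1.0 + (params.Mg / params.Mg_scale) * np.exp(-np.asarray(V, dtype=float) / params.Mg_slope))


def tonic_inhibition(m: float, rho: float, params: ModelParams = ModelParams()) -> float:
    """Tonic inhibitory drive V_INH = R_INH * m * rho in mV.

    Proportional to the mean HVC drive so the RA firing rate stays near its
    in-vivo ~50 Hz as connectivity strengthens and prunes; uses the
    distribution mean m, not the realized sample mean.
    """
    if m <= 0 or not 0 < rho <= 1:
        raise ValueError("require m > 0 and rho in (0, 1]")
    return (params.R_INH / 1000.0) * m * rho  # GOhm * pA = mV


def _event_counts(times: np.ndarray, n_steps: int, dt: float) -> np.ndarray:
    """Histogram event times onto Euler steps (floored; t = T goes to the
    last step)."""
    idx = np.minimum((times / dt).astype(int), n_steps - 1)
    counts = np.zeros(n_steps)
    np.add.at(counts, idx, 1.0)
    return counts


def simulate_renditions(
    profile: ConnectivityProfile,
    hvc: list[SpikeTrain],
    lman: list[SpikeTrain],
    params: ModelParams = ModelParams(),
    v_inh: float | None = None,
    i_ext_pA: float = 0.0,
    record_v: bool = False,
    warmup_passes: int = 1,
):
    """Integrate one song rendition per LMAN train, sharing the HVC raster
    and weight vector across renditions.

    Returns a list of RA spike trains (one per rendition), plus the
    (n_steps+1, n_renditions) voltage array when ``record_v`` is set.
    ``v_inh`` defaults to tonic_inhibition(profile.m, profile.rho);
    ``i_ext_pA`` injects a constant current (used by the closed-form LIF
    checks and current-clamp emulation).

    Renditions model excerpts of ongoing singing rather than the first
    note after silence, so by default each is preceded by one uncounted
    warm-up pass of the same inputs that brings the slow NMDA pool
    (tau_NMDA = 100 ms) and membrane to their periodic steady state;
    ``warmup_passes=0`` starts cold from V_R with empty synapses.
    """
    if len(hvc) != profile.weights.size:
        raise ValueError("one HVC train per weight required")
    durations = {t.duration for t in hvc} | {t.duration for t in lman}
    if durations != {params.song_dur}:
        raise ValueError("all trains must span params.song_dur")

    dt = params.dt
    n_steps = int(round(params.song_dur / dt))
    n_rend = len(lman)
    R_g = params.R / 1000.0  # GOhm
    if v_inh is None:
        v_inh = tonic_inhibition(profile.m, profile.rho, params)

    # HVC drive is identical across renditions: per-step weight increments.
    hvc_inc = np.zeros(n_steps)
    for train, w in zip(hvc, profile.weights):
        if w > 0 and train.times.size:
            hvc_inc += w * _event_counts(train.times, n_steps, dt)

    # Per-rendition LMAN spike counts per step (bursts can stack).
    lman_counts = np.zeros((n_steps, n_rend))
    for j, train in enumerate(lman):
        if train.times.size:
            lman_counts[:, j] = _event_counts(train.times, n_steps, dt)

    decay_s = 1.0 - dt / params.tau_s
    decay_n = 1.0 - dt / params.tau_NMDA
    lam = dt / params.tau_m
    w_ampa = params.r * params.W_LMAN
    w_nmda = (1.0 - params.r) * params.W_LMAN

    V = np.full(n_rend, params.V_R)
    I_hvc = 0.0
    I_ampa = np.zeros(n_rend)
    I_nmda = np.zeros(n_rend)
    refrac = np.zeros(n_rend)
    spike_steps: list[tuple[int, np.ndarray]] = []
    v_trace = np.empty((n_steps + 1, n_rend)) if record_v else None

    for p in range(warmup_passes + 1):
        counted = p == warmup_passes
        if counted and record_v:
            v_trace[0] = V
        for k in range(n_steps):
            I_hvc = I_hvc * decay_s + hvc_inc[k]
            c = lman_counts[k]
            I_ampa *= decay_s
            I_nmda *= decay_n
            if c.any():
                I_ampa += w_ampa * c
                # gating uses V before this step's voltage update
                I_nmda += w_nmda * nmda_gating(V, params) * c

            refrac = np.maximum(refrac - dt, 0.0)
            active = refrac <= 0.0
            drive = (params.V_R - V) + R_g * (I_hvc + I_ampa + I_nmda + i_ext_pA) - v_inh
            V = np.where(active, V + lam * drive, params.V_R)

            spiked = active & (V >= params.V_th)
            if spiked.any():
                if counted:
                    spike_steps.append((k, np.flatnonzero(spiked)))
                V[spiked] = params.V_R
                refrac[spiked] = params.t_ref
            if counted and record_v:
                v_trace[k + 1] = V

    out_times: list[list[float]] = [[] for _ in range(n_rend)]
    for k, idx in spike_steps:
        t = (k + 1) * dt
        for j in idx:
            out_times[j].append(t)
    trains = [
        SpikeTrain(np.asarray(ts), params.song_dur, source="RA")
        for ts in out_times
    ]
    if record_v:
        return trains, v_trace
    return trains


def simulate_rendition(
    profile: ConnectivityProfile,
    hvc: list[SpikeTrain],
    lman: SpikeTrain,
    params: ModelParams = ModelParams(),
    **kwargs,
):
    """Single-rendition convenience wrapper around :func:`simulate_renditions`."""
    out = simulate_renditions(profile, hvc, [lman], params, **kwargs)
    if kwargs.get("record_v"):
        trains, v = out
        return trains[0], v[:, 0]
    return out[0]
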