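"""Spike-train generators for the HVC-RA-LMAN circuit model.

HVC projection neurons act as a song time-keeper: each fires one
stereotyped 5-spike burst per rendition, and the 100 bursts tile the
1000 ms song in non-overlapping 10 ms slots.  LMAN, the outflow of the
basal-ganglia pathway, injects variability; its drive onto one RA neuron is
modeled as two ~40 Hz neurons merged into a single 80 Hz Poisson process,
with bursty and sinusoidally rate-modulated variants used to probe how the
LMAN firing pattern shapes RA variability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "LMANConfig",
    "hvc_song",
    "lman_poisson",
    "lman_bursty",
    "lman_bursty_pair",
    "lman_modulated",
    "merge_trains",
    "save_trains",
    "load_trains",
]

BURST_SPIKES = 5          # spikes per burst (HVC and LMAN bursts alike)
BURST_ISI_MS = 2.0        # intra-burst inter-spike interval
HVC_SLOT_MS = 10.0        # one HVC neuron's slot in the song tiling


@dataclass
class SpikeTrain:
    """Sorted event times in ms on [0, duration], tagged with their source."""

    times: np.ndarray
    duration: float
    source: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and (
            np.any(np.diff(self.times) < 0)
            or self.times[0] < 0
            or self.times[-1] > self.duration
        ):
            raise ValueError("times must be sorted within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def rate_hz(self) -> float:
        return 1000.0 * self.times.size / self.duration


def hvc_song(n_hvc: int = 100, song_dur: float = 1000.0) -> list[SpikeTrain]:
    """Deterministic HVC raster: neuron i (1-based) bursts 5 spikes 2 ms
    apart starting at (i-1)*10 ms; identical on every rendition."""
    if n_hvc < 1:
        raise ValueError("n_hvc must be >= 1")
    if abs(song_dur - n_hvc * HVC_SLOT_MS) > 1e-9:
        raise ValueError(
            f"song_dur = {song_dur} ms inconsistent with {n_hvc} HVC neurons "
            f"tiling {HVC_SLOT_MS} ms slots"
        )
    offsets = BURST_ISI_MS * np.arange(BURST_SPIKES)
    return [
        SpikeTrain((i * HVC_SLOT_MS) + offsets, song_dur, source=f"HVC{i + 1}")
        for i in range(n_hvc)
    ]


def lman_poisson(
    rate: float,
    duration: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrain:
    """Homogeneous Poisson spike train at ``rate`` Hz."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate * duration / 1000.0)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return SpikeTrain(times, duration, source="LMAN")


def lman_bursty(
    b: float,
    per_neuron_rate: float = 40.0,
    duration: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrain:
    """Bursty LMAN train for one neuron with overall rate held fixed.

    A fraction ``b`` of the spikes sits in stereotyped 5-spike bursts
    (2 ms apart); burst onsets are themselves Poisson at rate*b/5 Hz and the
    remaining tonic spikes are Poisson at rate*(1-b) Hz, so the expected
    total rate equals ``per_neuron_rate`` for every b.  Burst spikes past
    the end of the song are dropped.
    """
    if not 0 <= b <= 1:
        raise ValueError("burst fraction b must be in [0, 1]")
    rng = np.random.default_rng(seed)
    tonic = lman_poisson(per_neuron_rate * (1 - b), duration, rng).times
    onsets = lman_poisson(per_neuron_rate * b / BURST_SPIKES, duration, rng).times
    burst = (onsets[:, None] + BURST_ISI_MS * np.arange(BURST_SPIKES)).ravel()
    burst = burst[burst <= duration]
    times = np.sort(np.concatenate([tonic, burst]))
    return SpikeTrain(times, duration, source="LMAN")


def lman_bursty_pair(
    b: float,
    per_neuron_rate: float = 40.0,
    duration: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrain:
    """Superposition of two independent bursty 40 Hz LMAN neurons — the
    drive used on the burstiness axis, where the per-neuron rate stays
    fixed at 40 Hz rather than merging into one 80 Hz process."""
    rng = np.random.default_rng(seed)
    a = lman_bursty(b, per_neuron_rate, duration, rng)
    c = lman_bursty(b, per_neuron_rate, duration, rng)
    return merge_trains([a, c])


def lman_modulated(
    rate: float,
    mod_depth: float,
    duration: float = 1000.0,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrain:
    """Inhomogeneous Poisson train, rate(t) = rate*(1 + d*sin(2*pi*t/T)).

    One full sine period spans the song, phase 0, so the sine integrates to
    zero and the expected total count is rate*T regardless of depth.
    Generated by thinning a homogeneous process at the peak rate.
    """
    if not 0 <= mod_depth < 1:
        raise ValueError("mod_depth must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lam_max = rate * (1 + mod_depth)
    cand = lman_poisson(lam_max, duration, rng).times
    lam = rate * (1 + mod_depth * np.sin(2 * np.pi * cand / duration))
    keep = rng.uniform(0.0, lam_max, size=cand.size) < lam
    return SpikeTrain(cand[keep], duration, source="LMAN")


def merge_trains(trains: list[SpikeTrain], source: str = "LMAN") -> SpikeTrain:
    """Merge simultaneous trains of equal duration into one sorted train."""
    durations = {t.duration for t in trains}
    if len(durations) != 1:
        raise ValueError("all trains must share a duration")
    times = np.sort(np.concatenate([t.times for t in trains]))
    return SpikeTrain(times, durations.pop(), source=source)


@dataclass
class LMANConfig:
    """Recipe for the LMAN drive onto one RA neuron.

    The default is the standard model: two ~40 Hz neurons merged into one
    80 Hz Poisson process.  A nonzero ``burst_fraction`` switches to two
    independent bursty 40 Hz neurons superposed; a nonzero ``mod_depth``
    applies single-period sine rate modulation to the merged process.
    """

    total_rate: float = 80.0
    burst_fraction: float = 0.0
    spikes_per_burst: int = BURST_SPIKES
    intra_burst_isi: float = BURST_ISI_MS
    mod_depth: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burst_fraction and self.mod_depth:
            raise ValueError("bursts and sine modulation are separate axes")

    def make(
        self, duration: float, seed: int | np.random.Generator | None = None
    ) -> SpikeTrain:
        rng = np.random.default_rng(self.seed if seed is None else seed)
        if self.burst_fraction > 0:
            return lman_bursty_pair(
                self.burst_fraction, self.total_rate / 2, duration, rng
            )
        if self.mod_depth > 0:
            return lman_modulated(self.total_rate, self.mod_depth, duration, rng)
        return lman_poisson(self.total_rate, duration, rng)


def save_trains(trains: list[SpikeTrain], path: str | Path) -> None:
    """Write spike trains as tidy CSV (source, time_ms)."""
    rows = [
        {"source": t.source, "time_ms": time} for t in trains for time in t.times
    ]
    pd.DataFrame(rows, columns=["source", "time_ms"]).to_csv(path, index=False)


def load_trains(path: str | Path, duration: float) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(np.sort(g["time_ms"].to_numpy()), duration, source=str(src))
        for src, g in df.groupby("source", sort=True)
    ]
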