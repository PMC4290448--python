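"""Rendition-to-rendition variability of RA firing.

Each rendition's spike train is converted to an instantaneous firing rate
R(t) = 1/(t_{k+1} - t_k) between consecutive spikes, smoothed with a 10 ms
Gaussian, mean-subtracted, and correlated pairwise across renditions.  The
mean pairwise Pearson correlation (CC) is the variability statistic: CC = 1
means perfectly repeated firing, CC near 0 means the song-locked component
is swamped by trial-to-trial noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .spikegen import SpikeTrain

__all__ = [
    "RateTrace",
    "CCResult",
    "default_grid",
    "instantaneous_rate",
    "smooth_rate",
    "cc_average",
]

GRID_DT_MS = 1.0       # rate-trace sampling, 10x finer than the kernel sigma
SMOOTH_SIGMA_MS = 10.0


@dataclass
class RateTrace:
    """Firing rate (Hz) on a regular time grid (ms)."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.size != self.values.size:
            raise ValueError("grid and values must have equal length")
        if self.grid.size > 1:
            steps = np.diff(self.grid)
            if not np.allclose(steps, steps[0]):
                raise ValueError("grid must be regular")

    @property
    def dt(self) -> float:
        return float(self.grid[1] - self.grid[0]) if self.grid.size > 1 else np.nan


@dataclass
class CCResult:
    """Mean pairwise correlation across renditions."""

    mean_cc: float
    n_renditions: int
    matrix: np.ndarray | None = field(default=None, repr=False)
    degenerate: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix)


def default_grid(duration: float, dt_ms: float = GRID_DT_MS) -> np.ndarray:
    return np.arange(0.0, duration, dt_ms)


def instantaneous_rate(train: SpikeTrain, grid: np.ndarray) -> RateTrace:
    """ISI-reciprocal rate: R(t) = 1/(t_{k+1} - t_k) for t between spikes
    k and k+1, converted to Hz; zero before the first and after the last
    spike, and zero everywhere for trains with fewer than two spikes."""
    values = _rate_values(train.times, np.asarray(grid, dtype=float))
    return RateTrace(grid=grid, values=values)


def _rate_values(times: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if times.size < 2:
        return np.zeros(grid.size)
    idx = np.searchsorted(times, grid, side="right")
    inside = (idx >= 1) & (idx <= times.size - 1)
    values = np.zeros(grid.size)
    i = idx[inside]
    values[inside] = 1000.0 / (times[i] - times[i - 1])
    return values


def smooth_rate(trace: RateTrace, sigma_ms: float = SMOOTH_SIGMA_MS) -> RateTrace:
    """Convolve with a unit-area Gaussian kernel (sigma in ms).

    Edges are handled by renormalizing the kernel mass that falls inside
    the window, so a constant trace passes through exactly unchanged.
    """
    if sigma_ms <= 0:
        raise ValueError("sigma must be positive")
    return RateTrace(grid=trace.grid, values=_smooth_matrix(trace.values[None, :], trace.dt, sigma_ms)[0])


def _smooth_matrix(values: np.ndarray, dt: float, sigma_ms: float) -> np.ndarray:
    sigma = sigma_ms / dt
    out = gaussian_filter1d(values, sigma, axis=-1, mode="constant", truncate=6.0)
    norm = gaussian_filter1d(
        np.ones(values.shape[-1]), sigma, mode="constant", truncate=6.0
    )
    return out / norm


def cc_average(
    renditions: list[SpikeTrain],
    grid: np.ndarray | None = None,
    sigma_ms: float = SMOOTH_SIGMA_MS,
    keep_matrix: bool = True,
) -> CCResult:
    """Mean pairwise Pearson correlation of smoothed, mean-subtracted rate
    traces: CC = 2/(N(N-1)) * sum_{i<j} <r_i r_j> / sqrt(<r_i^2><r_j^2>).

    A rendition whose smoothed trace has zero variance (e.g. < 2 spikes)
    contributes 0 to all its pairs and is flagged in ``degenerate``.
    """
    n = len(renditions)
    if n < 2:
        raise ValueError("need at least two renditions")
    durations = {t.duration for t in renditions}
    if len(durations) != 1:
        raise ValueError("renditions must share a duration")
    if grid is None:
        grid = default_grid(durations.pop())
    grid = np.asarray(grid, dtype=float)
    dt = grid[1] - grid[0]

    raw = np.stack([_rate_values(t.times, grid) for t in renditions])
    smoothed = _smooth_matrix(raw, dt, sigma_ms)
    centered = smoothed - smoothed.mean(axis=1, keepdims=True)
    power = np.mean(centered**2, axis=1)
    degenerate = power <= 0
    norm = np.sqrt(np.where(degenerate, 1.0, power))
    unit = centered / norm[:, None]
    mat = (unit @ unit.T) / grid.size
    mat[degenerate, :] = 0.0
    mat[:, degenerate] = 0.0
    np.fill_diagonal(mat, 1.0)
    iu = np.triu_indices(n, k=1)
    mean_cc = float(mat[iu].mean())
    return CCResult(
        mean_cc=mean_cc,
        n_renditions=n,
        matrix=mat if keep_matrix else None,
        degenerate=degenerate,
    )
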