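"""Log-normal HVC->RA synaptic weight distributions and the learning axis.

Single-fiber EPSC amplitudes recorded in RA are well described by a
log-normal distribution at every stage of song learning.  This module fits
that distribution by maximum likelihood, converts between (mean, SD) moments
and log-scale parameters, and parameterizes the developmental
strengthening-and-pruning axis: as the fraction ``rho`` of active HVC inputs
falls, the mean and SD of the surviving weights rise, with the two measured
age points (rho=0.9 -> 50/35 pA, rho=0.37 -> 70/70 pA) as linear anchors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LogNormalFit",
    "ConnectivityProfile",
    "fit_lognormal",
    "lognormal_pdf",
    "params_from_moments",
    "profile_at",
    "sample_weights",
    "save_profile",
    "load_profile",
]

# Anchor points of the strengthening-and-pruning axis: (rho, mean pA, SD pA)
# measured in the plastic-song and adult age groups.
ANCHOR_PLASTIC = (0.9, 50.0, 35.0)
ANCHOR_ADULT = (0.37, 70.0, 70.0)


@dataclass(frozen=True)
class LogNormalFit:
    """Log-normal parameters on the natural-log scale.

    ``mu`` and ``sigma`` are the location and spread of log(amplitude/pA);
    ``n`` is the number of samples behind a fit (0 for analytic parameter
    sets derived from moments).
    """

    mu: float
    sigma: float
    n: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if not np.isfinite(self.mean):
            raise ValueError("implied mean is not finite")

    @property
    def mean(self) -> float:
        """Implied distribution mean, exp(mu + sigma^2/2), in pA."""
        return float(np.exp(self.mu + self.sigma**2 / 2))

    @property
    def sd(self) -> float:
        """Implied distribution SD in pA."""
        var = (np.exp(self.sigma**2) - 1) * np.exp(2 * self.mu + self.sigma**2)
        return float(np.sqrt(var))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mu": self.mu, "sigma": self.sigma, "n": self.n})
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "LogNormalFit":
        d = json.loads(Path(path).read_text())
        return cls(mu=d["mu"], sigma=d["sigma"], n=d["n"])


@dataclass
class ConnectivityProfile:
    """One realized HVC->RA weight vector on the learning axis.

    ``rho`` is the fraction of active (unpruned) HVC inputs; ``m`` and ``s``
    the mean and SD (pA) of the log-normal from which active weights were
    drawn; ``weights`` holds one peak-EPSC amplitude per HVC neuron, with
    exact zeros marking pruned inputs.
    """

    rho: float
    m: float
    s: float
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.m <= 0 or self.s < 0:
            raise ValueError("require m > 0 and s >= 0")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        expected = int(round(self.rho * self.weights.size))
        if int(np.count_nonzero(self.weights)) != expected:
            raise ValueError(
                f"active count {np.count_nonzero(self.weights)} != "
                f"round(rho*n) = {expected}"
            )

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.weights))


def fit_lognormal(samples: np.ndarray) -> LogNormalFit:
    """Maximum-likelihood log-normal fit to positive EPSC amplitudes.

    mu is the mean of the logs; sigma^2 is the *population* (1/n) variance
    of the logs — the plain MLE, not the unbiased 1/(n-1) form.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one sample")
    if np.any(x <= 0):
        raise ValueError("all samples must be positive")
    if x.size < 2:
        raise ValueError("need n >= 2 to estimate sigma")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(np.sqrt(np.mean((logs - mu) ** 2)))
    return LogNormalFit(mu=mu, sigma=sigma, n=x.size)


def lognormal_pdf(x: np.ndarray | float, fit: LogNormalFit) -> np.ndarray | float:
    """Log-normal density, exp(-(log x - mu)^2 / 2 sigma^2) / (x sigma sqrt(2 pi))."""
    if fit.sigma == 0:
        raise ValueError("degenerate fit (sigma = 0) has no density")
    xa = np.asarray(x, dtype=float)
    if np.any(xa <= 0):
        raise ValueError("x must be positive")
    z = (np.log(xa) - fit.mu) / fit.sigma
    out = np.exp(-0.5 * z**2) / (xa * fit.sigma * np.sqrt(2 * np.pi))
    return out if isinstance(x, np.ndarray) else float(out)


def params_from_moments(m: float, s: float) -> LogNormalFit:
    """Invert (mean, SD) in pA to log-normal (mu, sigma).

    sigma^2 = ln(1 + s^2/m^2), mu = ln(m) - sigma^2/2, so sampling with the
    returned parameters reproduces mean ``m`` and SD ``s`` exactly.
    """
    if m <= 0:
        raise ValueError("mean must be positive")
    if s < 0:
        raise ValueError("SD must be non-negative")
    sigma2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sigma2 / 2
    return LogNormalFit(mu=float(mu), sigma=float(np.sqrt(sigma2)), n=0)


def profile_at(rho: float) -> tuple[float, float]:
    """(mean, SD) pA of the active-weight distribution at a point on the axis.

    Linear in rho through the two measured anchors; extrapolated linearly
    outside them (valid for the swept range rho in [0.2, 1]) and clipped so
    the mean stays positive and the SD non-negative.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    r1, m1, s1 = ANCHOR_PLASTIC
    r2, m2, s2 = ANCHOR_ADULT
    t = (rho - r1) / (r2 - r1)
    m = m1 + t * (m2 - m1)
    s = s1 + t * (s2 - s1)
    return max(m, np.finfo(float).tiny), max(s, 0.0)


def sample_weights(
    rho: float,
    m: float,
    s: float,
    n_hvc: int = 100,
    seed: int | np.random.Generator | None = None,
) -> ConnectivityProfile:
    """Draw one HVC->RA weight vector: a random rho-fraction of the n_hvc
    inputs gets i.i.d. log-normal weights with moments (m, s); the rest are
    pruned to exactly zero.

    The pruned subset is chosen uniformly at random: HVC index maps to song
    time, so deterministic pruning would impose artifactual temporal
    structure.
    """
    if n_hvc < 1:
        raise ValueError("n_hvc must be >= 1")
    n_active = int(round(rho * n_hvc))
    if n_active == 0:
        raise ValueError(f"rho = {rho} leaves no active inputs out of {n_hvc}")
    fit = params_from_moments(m, s)
    rng = np.random.default_rng(seed)
    weights = np.zeros(n_hvc)
    active = rng.choice(n_hvc, size=n_active, replace=False)
    weights[active] = rng.lognormal(fit.mu, fit.sigma, size=n_active)
    return ConnectivityProfile(rho=rho, m=m, s=s, weights=weights)


def save_profile(profile: ConnectivityProfile, path: str | Path) -> None:
    """Write the weight vector as CSV (hvc_index, weight_pA)."""
    pd.DataFrame(
        {"hvc_index": np.arange(profile.weights.size), "weight_pA": profile.weights}
    ).to_csv(path, index=False)


def load_profile(path: str | Path, rho: float, m: float, s: float) -> ConnectivityProfile:
    df = pd.read_csv(path)
    return ConnectivityProfile(
        rho=rho, m=m, s=s, weights=df["weight_pA"].to_numpy()
    )
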