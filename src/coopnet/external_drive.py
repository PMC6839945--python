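"""Stochastic external drive: OU-modulated inhomogeneous Poisson input.

The instantaneous rate of external spikes onto pyramidal cell i is an
Ornstein-Uhlenbeck process (mean mu, correlation time tau) multiplied by
a Gaussian receptive-field gain for the cell's position in input space.
Spikes are drawn per time bin and convolved with the AMPA kernel of the
target cell class. The interneuron's drive is the mean of its afferent
pyramidal cells' conductance traces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .synapse_kernels import BiExpParams

__all__ = [
    "OUParams",
    "DriveProfile",
    "ou_path",
    "receptive_field_gains",
    "poisson_spikes",
    "drive_conductance",
    "pv_drive",
    "theta_modulate",
]


@dataclass(frozen=True)
class OUParams:
    """Mean rate (spikes/s), correlation time (ms) and stationary CV.

    The printed volatility expression is typographically garbled, so the
    fluctuation size is parameterized by the coefficient of variation of
    the stationary process instead (0 = constant rate).
    """

    mu: float = 5000.0
    tau: float = 50.0
    stationary_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.stationary_cv < 0:
            raise ValueError("stationary_cv must be non-negative")

    def with_overrides(self, **kwargs) -> "OUParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DriveProfile:
    """Per-cell receptive-field gains in [0, 1] plus the generating spec."""

    gains: np.ndarray
    mode: str          # "clustered" | "dispersed"
    center: int
    width: float

    def __post_init__(self) -> None:
        g = np.asarray(self.gains, dtype=float)
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("gains must lie in [0, 1]")
        object.__setattr__(self, "gains", g)


def ou_path(
    params: OUParams,
    dt: float,
    T: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Exact-discretization OU rate path, clipped at zero.

    Initialized at the stationary distribution; the lag-1 autocorrelation
    of the unclipped process is exactly ``exp(-dt/tau)``. Returns one rate
    value (spikes/s) per time bin.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if T < dt:
        raise ValueError("T must be at least dt")
    rng = np.random.default_rng(rng)
    n = int(round(T / dt))
    sd = params.stationary_cv * params.mu
    if sd == 0:
        return np.full(n, params.mu)
    rho = np.exp(-dt / params.tau)
    # stationary AR(1): x_k = rho x_{k-1} + sd sqrt(1-rho^2) xi_k
    noise = rng.standard_normal(n) * sd * np.sqrt(1.0 - rho**2)
    noise[0] = rng.standard_normal() * sd
    x = lfilter([1.0], [1.0, -rho], noise)
    return np.clip(params.mu + x, 0.0, None)


def receptive_field_gains(
    n_pyr: int,
    center: int = 125,
    width: float = 25.0,
    mode: str = "clustered",
    rng: np.random.Generator | int | None = None,
) -> DriveProfile:
    """Gaussian receptive-field bump, or its seeded random permutation.

    ``clustered`` puts a unit-peak Gaussian hump at ``center``;
    ``dispersed`` permutes the same gain vector so total drive is
    conserved exactly.
    """
    if not 0 <= center < n_pyr:
        raise ValueError(f"center must lie in [0, {n_pyr}), got {center}")
    if width <= 0:
        raise ValueError("width must be positive")
    idx = np.arange(n_pyr, dtype=float)
    gains = np.exp(-((idx - center) ** 2) / (2.0 * width**2))
    if mode == "dispersed":
        gains = np.random.default_rng(rng).permutation(gains)
    elif mode != "clustered":
        raise ValueError(f"unknown mode {mode!r}")
    return DriveProfile(gains=gains, mode=mode, center=center, width=width)


def poisson_spikes(
    rates: np.ndarray,
    dt: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Per-bin spike counts from an inhomogeneous Poisson process.

    ``rates`` is in spikes/s with time bins of ``dt`` ms along the last
    axis; counts are Poisson(rate * dt / 1000), independent across cells
    and bins.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    lam = rates * dt / 1000.0
    if np.any(lam > 10.0):
        warnings.warn(
            "rate * dt exceeds 10 expected spikes per bin; binning too coarse",
            stacklevel=2,
        )
    return np.random.default_rng(rng).poisson(lam)


def drive_conductance(
    spikes: np.ndarray,
    ampa_params: BiExpParams,
    dt: float,
) -> np.ndarray:
    """Convolve per-bin spike counts with the AMPA conductance kernel.

    Equivalent to stepping :func:`coopnet.synapse_kernels.biexp_step` with
    the same impulses (impulses binned at the end of their step), but runs
    as two recursive exponential filters. ``spikes`` may be (n_bins,) or
    (n_cells, n_bins); returns the conductance trace(s) on the same grid.
    """
    s = np.asarray(spikes, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    d1 = np.exp(-dt / ampa_params.tau1)
    d2 = np.exp(-dt / ampa_params.tau2_effective)
    # g[k] = g[k-1]*decay + s[k]  (impulse lands at end of its bin)
    g1 = lfilter([1.0], [1.0, -d1], s, axis=-1)
    g2 = lfilter([1.0], [1.0, -d2], s, axis=-1)
    return (g2 - g1) / (ampa_params.tau2 - ampa_params.tau1)


def pv_drive(g_ext: np.ndarray) -> np.ndarray:
    """Interneuron drive: per-bin mean of afferent pyramidal conductances."""
    g_ext = np.asarray(g_ext, dtype=float)
    if g_ext.ndim != 2 or g_ext.shape[0] < 1:
        raise ValueError("g_ext must be (n_cells, n_bins) with n_cells >= 1")
    return g_ext.mean(axis=0)


def theta_modulate(
    rates: np.ndarray,
    f_theta: float = 8.0,
    depth: float = 1.0,
    dt: float = 1.0,
) -> np.ndarray:
    """Multiply a rate trace by a theta-band sinusoidal envelope.

    modulation(t) = 1 - depth + depth * (1 + sin(2 pi f t)) / 2, so depth 0
    is the identity and depth 1 lets the rate touch zero at troughs.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    rates = np.asarray(rates, dtype=float)
    t = np.arange(rates.shape[-1]) * dt / 1000.0  # s
    mod = 1.0 - depth + depth * 0.5 * (1.0 + np.sin(2.0 * np.pi * f_theta * t))
    return rates * mod
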