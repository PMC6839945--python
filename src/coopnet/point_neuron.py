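"""Two-dimensional Izhikevich dynamics with a two-piece quadratic gain.

The membrane equation is

    Cm dv/dt = k(v)(v - vr)(v - vt) - u + I
    du/dt    = a [b (v - vr) - u]

with ``k = k_low`` for v <= vt and ``k = k_high`` for v > vt, and the
reset rule ``v >= vpeak  ->  v = c, u = u + d``.

Units are fixed package-wide: mV, ms, pA, pF, nS.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "fs_pv_params",
    "pyramidal_params",
    "izhikevich_step",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Parameters of the two-piece quadratic integrate-and-fire model.

    Attributes
    ----------
    Cm : float
        Membrane capacitance (pF).
    k_low, k_high : float
        Quadratic gain below/above the instantaneous threshold (nS/mV).
    vr : float
        Resting potential (mV).
    vt : float
        Instantaneous threshold (mV).
    vpeak : float
        Spike cutoff (mV).
    a : float
        Recovery inverse time constant (1/ms).
    b : float
        Recovery sensitivity (nS). May be negative (fast-spiking cells).
    c : float
        Reset voltage (mV).
    d : float
        After-spike recovery increment (pA).
    """

    Cm: float
    k_low: float
    k_high: float
    vr: float
    vt: float
    vpeak: float
    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if not self.Cm > 0:
            raise ValueError(f"Cm must be positive, got {self.Cm}")
        if not (self.k_low > 0 and self.k_high > 0):
            raise ValueError("k_low and k_high must be positive")
        if not (self.vr < self.vt < self.vpeak):
            raise ValueError(
                f"need vr < vt < vpeak, got {self.vr}, {self.vt}, {self.vpeak}"
            )
        if self.c > self.vpeak:
            raise ValueError("reset voltage c must not exceed vpeak")
        if not self.a > 0:
            raise ValueError("a must be positive")

    def with_overrides(self, **kwargs) -> "IzhikevichParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class NeuronState:
    """Membrane potential ``v`` (mV) and recovery current ``u`` (pA)."""

    v: np.ndarray
    u: np.ndarray

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        if self.v.shape != self.u.shape:
            raise ValueError("v and u must have the same shape")

    @classmethod
    def at_rest(cls, params: IzhikevichParams, n: int) -> "NeuronState":
        """State with every neuron at (vr, 0) — the zero-input fixed point."""
        return cls(np.full(n, params.vr), np.zeros(n))


def fs_pv_params() -> IzhikevichParams:
    """Published fast-spiking PV+ interneuron parameter set."""
    return IzhikevichParams(
        Cm=90.0, k_low=1.7, k_high=14.0, vr=-60.6, vt=-43.1,
        vpeak=2.5, a=0.1, b=-0.1, c=-67.0, d=0.1,
    )


def pyramidal_params() -> IzhikevichParams:
    """Published CA1 pyramidal cell parameter set."""
    return IzhikevichParams(
        Cm=115.0, k_low=0.1, k_high=3.3, vr=-65.8, vt=-57.0,
        vpeak=22.6, a=0.0012, b=3.0, c=-65.8, d=10.0,
    )


def izhikevich_step(
    state: NeuronState,
    params: IzhikevichParams,
    I_applied: np.ndarray | float,
    dt: float,
) -> tuple[NeuronState, np.ndarray]:
    """Advance all neurons by one forward-Euler step and apply resets.

    The piecewise gain is chosen from the pre-step voltage, with ties
    (v == vt) using ``k_low``. Any neuron whose updated voltage reaches
    ``vpeak`` is flagged as spiking, its voltage set to ``c`` and its
    recovery variable incremented by ``d`` within the same step.

    Parameters
    ----------
    state : NeuronState
    params : IzhikevichParams
    I_applied : array_like
        Applied current per neuron (pA); broadcastable to ``state.v``.
    dt : float
        Time step (ms).

    Returns
    -------
    (NeuronState, ndarray of bool)
        The new state and the per-neuron spike flags.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    v, u = state.v, state.u
    I = np.broadcast_to(np.asarray(I_applied, dtype=float), v.shape)
    if not np.all(np.isfinite(I)):
        bad = int(np.flatnonzero(~np.isfinite(I))[0])
        raise ValueError(f"non-finite applied current at neuron index {bad}")

    k = np.where(v <= params.vt, params.k_low, params.k_high)
    dv = (k * (v - params.vr) * (v - params.vt) - u + I) / params.Cm
    du = params.a * (params.b * (v - params.vr) - u)
    v_new = v + dt * dv
    u_new = u + dt * du

    spikes = v_new >= params.vpeak
    v_new = np.where(spikes, params.c, v_new)
    u_new = np.where(spikes, u_new + params.d, u_new)
    return NeuronState(v_new, u_new), spikes
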