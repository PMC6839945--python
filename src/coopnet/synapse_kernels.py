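"""Bi-exponential conductance-based synapse kernels.

Each channel family is described by a rise/decay pair (g1, g2) driven by
impulse trains:

    dg1/dt = delta(t) - g1/tau1
    dg2/dt = delta(t) - g2/tau2
    g = G(v_syn) * (g2 - g1) / (tau2 - tau1)

with G = 1 for AMPA/GABA/external channels and the instantaneous
Mg-unblock sigmoid :func:`nmda_gate` for NMDA channels. The kernel is
normalized: its time integral is 1 for every valid (tau1, tau2).

The decay between impulses is applied exactly (no Euler error); impulses
falling within a step are binned to the end of that step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BiExpParams",
    "SynapticState",
    "biexp_step",
    "biexp_conductance",
    "biexp_impulse_response",
    "biexp_peak_time",
    "nmda_gate",
    # published kinetics
    "AMPA_ONTO_PV", "AMPA_ONTO_PYR", "GABA_ONTO_PV", "GABA_ONTO_PYR",
    "NMDA_ONTO_PV",
]


@dataclass(frozen=True)
class BiExpParams:
    """Rise (``tau1``) and decay (``tau2``) time constants in ms."""

    tau1: float
    tau2: float
    #: decay-rate multiplier on g2; 1 is the difference-of-exponentials
    #: kernel, other values exist only to probe the literal printed form.
    g2_rate_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.tau1 < self.tau2):
            raise ValueError(
                f"need 0 < tau1 < tau2, got tau1={self.tau1}, tau2={self.tau2}"
            )
        if self.g2_rate_factor <= 0:
            raise ValueError("g2_rate_factor must be positive")

    @property
    def tau2_effective(self) -> float:
        return self.tau2 / self.g2_rate_factor


# Published kinetics (ms)
AMPA_ONTO_PV = BiExpParams(0.25, 0.77)
AMPA_ONTO_PYR = BiExpParams(0.2, 1.7)
GABA_ONTO_PV = BiExpParams(0.27, 1.7)
GABA_ONTO_PYR = BiExpParams(0.3, 3.5)
NMDA_ONTO_PV = BiExpParams(2.0, 60.0)


@dataclass
class SynapticState:
    """Rise/decay state variables per synapse (unitless kernel states)."""

    g1: np.ndarray
    g2: np.ndarray

    def __post_init__(self) -> None:
        self.g1 = np.asarray(self.g1, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.g1.shape != self.g2.shape:
            raise ValueError("g1 and g2 must have the same shape")

    @classmethod
    def zeros(cls, n: int) -> "SynapticState":
        return cls(np.zeros(n), np.zeros(n))


def biexp_step(
    state: SynapticState,
    params: BiExpParams,
    impulses: np.ndarray | float = 0.0,
    dt: float = 0.05,
) -> SynapticState:
    """Decay g1/g2 exactly over ``dt`` then add the impulse counts."""
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    n = np.asarray(impulses, dtype=float)
    if np.any(n < 0):
        raise ValueError("impulse counts must be non-negative")
    g1 = state.g1 * np.exp(-dt / params.tau1) + n
    g2 = state.g2 * np.exp(-dt / params.tau2_effective) + n
    return SynapticState(g1, g2)


def biexp_conductance(
    state: SynapticState,
    params: BiExpParams,
    gate: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Conductance ``gate * (g2 - g1) / (tau2 - tau1)`` per synapse.

    Equivalent to the printed ``gate * (g1 - g2)/(tau1 - tau2)`` but written
    so that single-impulse responses are non-negative for tau1 < tau2.
    """
    if params.tau1 == params.tau2:
        raise ValueError("degenerate kernel tau1 == tau2 not supported")
    return np.asarray(gate) * (state.g2 - state.g1) / (params.tau2 - params.tau1)


def biexp_impulse_response(params: BiExpParams, t: np.ndarray | float) -> np.ndarray:
    """Closed-form unit impulse response ``(e^-t/tau2 - e^-t/tau1)/(tau2-tau1)``.

    Matches the stepped kernel at grid points to machine precision; used as
    the independent oracle in tests and for drive convolution.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    return (np.exp(-t / params.tau2) - np.exp(-t / params.tau1)) / (
        params.tau2 - params.tau1
    )


def biexp_peak_time(params: BiExpParams) -> float:
    """Time to peak of the unit impulse response (ms)."""
    t1, t2 = params.tau1, params.tau2
    return t1 * t2 / (t2 - t1) * np.log(t2 / t1)


def nmda_gate(v_syn: np.ndarray | float) -> np.ndarray | float:
    """Instantaneous NMDA voltage gate ``1/2 tanh[(v + 50)/10] + 1/2``.

    Strictly increasing, bounded in (0, 1); 0.5 at v = -50 mV.
    """
    return 0.5 * np.tanh((np.asarray(v_syn, dtype=float) + 50.0) / 10.0) + 0.5
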