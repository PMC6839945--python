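"""Cooperative NMDAR Mg-unblock via local synaptic membrane patches.

Co-active feedback synapses from ``n_pyr`` principal cells interact
through a Gaussian Toeplitz distance matrix D over afferent index space.
Each afferent i owns a local membrane-patch voltage v_i obeying

    C_syn dv_i/dt = k_syn * I_i + g_leak (e_leak - v_i)
    I_i = sum_j D_ij (k_AMPA g_j^AMPA + k_NMDA g_j^NMDA G(v_j)) (e_glu - v_i)

where G is the NMDA gate evaluated at the *sending* afferent's patch
voltage (a config flag switches to receiver-side gating). The same gated
conductances feed the interneuron's total applied current, and pyramidal
cells receive external and GABA currents only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.linalg import toeplitz

from .synapse_kernels import nmda_gate

__all__ = [
    "CooperativityParams",
    "GainTable",
    "PatchState",
    "build_distance_matrix",
    "default_sigma_d",
    "patch_step",
    "interneuron_current",
    "pyramidal_current",
    "CurrentDecomposition",
]

#: cooperation width as a fraction of the afferent population: the
#: printed width is dimensionally inconsistent (it collapses D to a
#: near-delta), so the Gaussian is read as acting on normalized input
#: position; 5% of the population gives local cooperation on the scale
#: of the drawn input humps and a robust clustered/dispersed contrast.
_SIGMA_D_COEFF = 0.05


def default_sigma_d(n_pyr: int) -> float:
    """Default cooperation width in afferent-index units (12.5 for n=250)."""
    return _SIGMA_D_COEFF * n_pyr


@dataclass(frozen=True)
class CooperativityParams:
    """Patch dynamics and reversal-potential parameters (published defaults)."""

    n_pyr: int = 250
    sigma_D: float | None = None  # defaults to sqrt(0.015) * n_pyr
    C_syn: float = 9.0      # pF
    k_syn: float | None = None  # defaults to 3 / n_pyr
    g_leak: float = 5.0     # nS
    e_leak: float = -60.6   # mV
    e_glu: float = 0.0      # mV
    e_GABA: float = -70.0   # mV
    #: gate NMDA conductance at the sending afferent's patch (as printed);
    #: False gates at the receiving patch instead.
    gate_at_sender: bool = True

    def __post_init__(self) -> None:
        if self.n_pyr < 1:
            raise ValueError("n_pyr must be >= 1")
        if self.sigma_D is None:
            object.__setattr__(self, "sigma_D", default_sigma_d(self.n_pyr))
        if self.sigma_D <= 0:
            raise ValueError("sigma_D must be positive")
        if self.k_syn is None:
            object.__setattr__(self, "k_syn", 3.0 / self.n_pyr)
        if self.C_syn <= 0 or self.g_leak <= 0:
            raise ValueError("C_syn and g_leak must be positive")
        if not self.e_GABA < self.e_glu:
            raise ValueError("need e_GABA < e_glu")

    def with_overrides(self, **kwargs) -> "CooperativityParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GainTable:
    """Channel gain constants (published defaults) and global scale factors."""

    k_pv_ampa: float = 2.0**8
    k_pv_nmda: float = 2.0**12
    k_pv_gaba: float = 2.0**8
    k_pv_ext: float = 5.0
    k_pyr_gaba: float = 2.0**7
    k_pyr_ext: float = 1.0
    nmdar_scale: float = 1.0
    ampar_scale: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "k_pv_ampa", "k_pv_nmda", "k_pv_gaba", "k_pv_ext",
            "k_pyr_gaba", "k_pyr_ext", "nmdar_scale", "ampar_scale",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def with_overrides(self, **kwargs) -> "GainTable":
        return replace(self, **kwargs)


@dataclass
class PatchState:
    """Local synaptic membrane-patch voltage per afferent (mV)."""

    v_syn: np.ndarray

    def __post_init__(self) -> None:
        self.v_syn = np.asarray(self.v_syn, dtype=float)

    @classmethod
    def at_rest(cls, params: CooperativityParams) -> "PatchState":
        return cls(np.full(params.n_pyr, params.e_leak))


def build_distance_matrix(n_pyr: int, sigma_D: float) -> np.ndarray:
    """Symmetric, non-circular Gaussian Toeplitz matrix over afferent pairs.

    ``D[i, j] = exp(-(i-j)^2 / (2 sigma_D^2)) / sqrt(2 pi sigma_D^2)``
    """
    if n_pyr < 1:
        raise ValueError("n_pyr must be >= 1")
    if sigma_D <= 0:
        raise ValueError(f"sigma_D must be positive, got {sigma_D}")
    offsets = np.arange(n_pyr, dtype=float)
    col = np.exp(-(offsets**2) / (2.0 * sigma_D**2)) / np.sqrt(
        2.0 * np.pi * sigma_D**2
    )
    return toeplitz(col)


class CurrentDecomposition(NamedTuple):
    """Per-channel summands of the interneuron applied current (pA)."""

    nmda: float
    ampa: float
    gaba: float
    ext: float

    @property
    def total(self) -> float:
        return self.nmda + self.ampa + self.gaba + self.ext


def _weighted_glu_drive(
    D: np.ndarray,
    g_ampa: np.ndarray,
    g_nmda: np.ndarray,
    gate: np.ndarray,
    gains: GainTable,
) -> np.ndarray:
    """D-weighted glutamatergic conductance seen by each patch."""
    w = (
        gains.k_pv_ampa * gains.ampar_scale * g_ampa
        + gains.k_pv_nmda * gains.nmdar_scale * g_nmda * gate
    )
    return D @ w


def patch_step(
    patch: PatchState,
    D: np.ndarray,
    g_ampa: np.ndarray,
    g_nmda: np.ndarray,
    gate: np.ndarray,
    params: CooperativityParams,
    gains: GainTable,
    dt: float,
) -> PatchState:
    """Advance all patch voltages one step (exponential Euler on the leak).

    The synaptic current is evaluated at the pre-step voltages and held
    constant over the step. ``gate`` is the NMDA gate of each *sending*
    afferent, evaluated by the caller before the step.
    """
    v = patch.v_syn
    n = params.n_pyr
    for name, arr in (("g_ampa", g_ampa), ("g_nmda", g_nmda), ("gate", gate)):
        if np.shape(arr) != (n,):
            raise ValueError(f"{name} must have shape ({n},), got {np.shape(arr)}")
    if D.shape != (n, n):
        raise ValueError(f"D must have shape ({n}, {n})")
    if dt <= 0:
        raise ValueError("dt must be positive")

    if not params.gate_at_sender:
        gate = nmda_gate(v)
    s = _weighted_glu_drive(D, g_ampa, g_nmda, gate, gains)
    # k_syn * s acts as a glutamatergic conductance onto the patch;
    # exponential-Euler on the full conductance keeps v bounded by e_glu
    g_syn = params.k_syn * s
    g_tot = params.g_leak + g_syn
    v_inf = (params.g_leak * params.e_leak + g_syn * params.e_glu) / g_tot
    decay = np.exp(-dt * g_tot / params.C_syn)
    return PatchState(v_inf + (v - v_inf) * decay)


def interneuron_current(
    patch: PatchState,
    g_ampa: np.ndarray,
    g_nmda: np.ndarray,
    g_ext: np.ndarray | float,
    g_gaba: np.ndarray | float,
    v: float,
    params: CooperativityParams,
    gains: GainTable,
) -> tuple[float, CurrentDecomposition]:
    """Total applied current onto the interneuron, plus its decomposition.

    ``g_ext`` is the (already averaged) external conductance; ``g_gaba``
    holds one kernel value per presynaptic interneuron (autapse included).
    """
    gate = nmda_gate(patch.v_syn)
    drive = params.e_glu - v
    I_ampa = gains.k_pv_ampa * gains.ampar_scale * float(np.sum(g_ampa)) * drive
    I_nmda = gains.k_pv_nmda * gains.nmdar_scale * float(np.sum(g_nmda * gate)) * drive
    I_ext = gains.k_pv_ext * float(np.sum(g_ext)) * drive
    I_gaba = gains.k_pv_gaba * float(np.sum(g_gaba)) * (params.e_GABA - v)
    dec = CurrentDecomposition(nmda=I_nmda, ampa=I_ampa, gaba=I_gaba, ext=I_ext)
    return dec.total, dec


def pyramidal_current(
    g_ext: np.ndarray,
    g_gaba: np.ndarray | float,
    v: np.ndarray,
    params: CooperativityParams,
    gains: GainTable,
) -> np.ndarray:
    """Applied current per pyramidal cell: external drive plus shared GABA."""
    g_ext = np.asarray(g_ext, dtype=float)
    v = np.asarray(v, dtype=float)
    if g_ext.shape != v.shape:
        raise ValueError("g_ext and v must have the same shape")
    I_ext = gains.k_pyr_ext * g_ext * (params.e_glu - v)
    I_gaba = gains.k_pyr_gaba * float(np.sum(g_gaba)) * (params.e_GABA - v)
    return I_ext + I_gaba
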