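"""Discretization and integration of the branched cable model.

``segmentize`` applies the d-lambda rule (odd compartment counts per
section, segment length at most a fraction of the 1 kHz AC length
constant) and produces a flat compartment graph in Hines order.
``simulate`` integrates the full model (Crank-Nicolson, exponential-
Euler gating); ``input_resistance`` and ``calibrate_rm`` implement the
passive calibration of the specific membrane resistance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import _cable_core
from .morphology import REGION_SOMA, Morphology

__all__ = [
    "CableParams",
    "CompartmentGraph",
    "segmentize",
    "ac_length_constant",
    "simulate",
    "input_resistance",
    "calibrate_rm",
]


@dataclass(frozen=True)
class CableParams:
    """Biophysical parameters (published defaults).

    Units: Cm µF/cm²; Ra Ω·cm; Rm kΩ·cm²; reversals and v_shift mV;
    channel densities pS/µm²; border µm (path distance separating
    proximal from distal membrane resistance and Na density).
    """

    Cm: float = 0.9
    Ra: float = 170.0
    Rm_prox: float = 5.55
    Rm_dist: float = 55.5
    border: float = 120.0
    e_leak: float = -65.0
    e_K: float = -90.0
    e_Na: float = 55.0
    v_shift: float = -12.0
    gK_dend: float = 300.0
    gNa_dend_prox: float = 200.0
    gNa_dend_dist: float = 100.0
    gNa_soma: float = 2000.0
    #: somatic K density; the published table lists only the dendritic
    #: value, which is applied at the soma as well.
    gK_soma: float = 300.0

    def __post_init__(self) -> None:
        for name in ("Cm", "Ra", "Rm_prox", "Rm_dist", "border"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def with_overrides(self, **kwargs) -> "CableParams":
        return replace(self, **kwargs)

    def scale_rm(self, factor: float) -> "CableParams":
        """Scale both membrane resistances, preserving their ratio."""
        return replace(
            self, Rm_prox=self.Rm_prox * factor, Rm_dist=self.Rm_dist * factor
        )


def ac_length_constant(diam: float, params: CableParams, f: float = 1000.0) -> float:
    """AC length constant (µm) at frequency ``f`` for diameter ``diam`` µm."""
    # 0.5e5 * sqrt(d / (pi f Ra Cm)) with d in µm, Ra Ω·cm, Cm µF/cm²
    return 0.5e5 * np.sqrt(diam / (np.pi * f * params.Ra * params.Cm))


@dataclass
class CompartmentGraph:
    """Flat compartment arrays in Hines order (parent index < child).

    Conductances in nS, capacitances in pF, lengths/areas µm and µm².
    ``section_of``/``pos_of`` map compartments back to morphology
    coordinates; ``passive`` drops all active channels.
    """

    morph: Morphology
    params: CableParams
    parent: np.ndarray       # (n,)
    section_of: np.ndarray   # (n,)
    pos_of: np.ndarray       # (n,) normalized position of compartment center
    length: np.ndarray       # (n,) µm
    area: np.ndarray         # (n,) µm²
    path_dist: np.ndarray    # (n,) µm to soma
    g_axial: np.ndarray      # (n,) nS to parent
    C: np.ndarray            # (n,) pF
    g_leak: np.ndarray       # (n,) nS
    gNa: np.ndarray          # (n,) nS
    gK: np.ndarray           # (n,) nS
    nseg: np.ndarray         # (n_sections,) compartments per section

    @property
    def n_comp(self) -> int:
        return self.parent.size

    def locate(self, section: int, pos: float) -> int:
        """Index of the compartment containing (section, pos)."""
        mask = self.section_of == section
        idx = np.flatnonzero(mask)
        centers = self.pos_of[idx]
        return int(idx[np.argmin(np.abs(centers - pos))])

    def passive(self) -> "CompartmentGraph":
        """Copy with all active channel densities removed."""
        import copy

        out = copy.copy(self)
        out.gNa = np.zeros_like(self.gNa)
        out.gK = np.zeros_like(self.gK)
        return out


def segmentize(
    morph: Morphology,
    params: CableParams | None = None,
    d_lambda: float = 0.1,
    f: float = 1000.0,
) -> CompartmentGraph:
    """Discretize a morphology by the d-lambda rule.

    Per section the compartment count is the smallest odd integer giving
    segment lengths no longer than ``d_lambda`` times the AC length
    constant at ``f``.
    """
    params = params or CableParams()
    if not 0 < d_lambda <= 1:
        raise ValueError("d_lambda must lie in (0, 1]")

    nseg = np.empty(morph.n_sections, dtype=np.int64)
    for s in morph.sections:
        lam = ac_length_constant(s.diam, params, f)
        n = int(np.ceil(s.length / (d_lambda * lam)))
        if n % 2 == 0:
            n += 1
        nseg[s.index] = n

    parent, section_of, pos_of, length, area, g_axial = [], [], [], [], [], []
    last_comp_of_section: dict[int, int] = {}

    def axial_half(sec) -> float:
        """Axial resistance (GΩ-free; in Ω) of half a segment."""
        seg_len = sec.length / nseg[sec.index]
        r_ohm = (
            params.Ra * (seg_len / 2 * 1e-4)
            / (np.pi * (sec.diam / 2 * 1e-4) ** 2)
        )
        return r_ohm

    for s in morph.sections:
        n = nseg[s.index]
        seg_len = s.length / n
        for j in range(n):
            idx = len(parent)
            if j == 0:
                if s.parent < 0:
                    parent.append(-1)
                    g_axial.append(0.0)
                else:
                    p_sec = morph.sections[s.parent]
                    p_comp = last_comp_of_section[s.parent]
                    parent.append(p_comp)
                    r = axial_half(s) + axial_half(p_sec)
                    g_axial.append(1e9 / r)  # Ω -> nS
            else:
                parent.append(idx - 1)
                g_axial.append(1e9 / (2 * axial_half(s)))
            section_of.append(s.index)
            pos_of.append((j + 0.5) / n)
            length.append(seg_len)
            area.append(np.pi * s.diam * seg_len)
        last_comp_of_section[s.index] = len(parent) - 1

    section_of = np.asarray(section_of, dtype=np.int64)
    pos_of = np.asarray(pos_of)
    area = np.asarray(area)
    path_dist = np.array(
        [
            morph.path_distance(int(sec), float(p))
            for sec, p in zip(section_of, pos_of)
        ]
    )

    is_soma = np.array(
        [morph.sections[int(s)].region == REGION_SOMA for s in section_of]
    )
    is_distal = path_dist > params.border
    rm = np.where(is_distal, params.Rm_dist, params.Rm_prox)  # kΩ·cm²
    g_leak = area / rm * 1e-2  # nS
    C = params.Cm * area * 1e-2  # pF
    gNa_density = np.where(
        is_soma,
        params.gNa_soma,
        np.where(is_distal, params.gNa_dend_dist, params.gNa_dend_prox),
    )
    gK_density = np.where(is_soma, params.gK_soma, params.gK_dend)
    gNa = gNa_density * area * 1e-3  # pS/µm² * µm² -> nS
    gK = gK_density * area * 1e-3

    return CompartmentGraph(
        morph=morph,
        params=params,
        parent=np.asarray(parent, dtype=np.int64),
        section_of=section_of,
        pos_of=pos_of,
        length=np.asarray(length),
        area=area,
        path_dist=path_dist,
        g_axial=np.asarray(g_axial),
        C=C,
        g_leak=g_leak,
        gNa=gNa,
        gK=gK,
        nseg=nseg,
    )


def simulate(
    graph: CompartmentGraph,
    duration: float,
    dt: float = 0.025,
    synapses=None,            # list of (SynapseSpec, activation time ms)
    i_inj: tuple[int, float] | None = None,   # (compartment, pA)
    record: list[int] | None = None,           # compartment indices
    v_init: float | np.ndarray | None = None,
    mg: float = 1.3,
    rectify: bool = False,
    return_final: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the model; returns (times, voltages[record, time]).

    Somatic compartment 0 is always recorded first. Synaptic reversal is
    0 mV; NMDA conductances are multiplied by the Jahr-Stevens Mg-block
    factor at the compartment's pre-step voltage.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need duration >= dt > 0")
    n_steps = int(round(duration / dt))
    record = [0] + [r for r in (record or []) if r != 0]
    record_idx = np.asarray(record, dtype=np.int64)

    if synapses:
        syn_comp = np.array(
            [graph.locate(sp.section, sp.pos) for sp, _ in synapses],
            dtype=np.int64,
        )
        syn_ga = np.array([sp.g_ampa for sp, _ in synapses])
        syn_gn = np.array([sp.g_nmda for sp, _ in synapses])
        syn_t = np.array(
            [int(round(t / dt)) if t >= 0 else -1 for _, t in synapses],
            dtype=np.int64,
        )
        tau_a = np.array(
            [synapses[0][0].ampa_kinetics.tau1, synapses[0][0].ampa_kinetics.tau2]
        )
        tau_n = np.array(
            [synapses[0][0].nmda_kinetics.tau1, synapses[0][0].nmda_kinetics.tau2]
        )
    else:
        syn_comp = np.empty(0, dtype=np.int64)
        syn_ga = np.empty(0)
        syn_gn = np.empty(0)
        syn_t = np.empty(0, dtype=np.int64)
        tau_a = np.array([0.25, 0.77])
        tau_n = np.array([2.0, 60.0])

    inj_comp, inj_pa = (i_inj if i_inj is not None else (-1, 0.0))
    if v_init is None:
        v0 = np.full(graph.n_comp, graph.params.e_leak)
    elif np.isscalar(v_init):
        v0 = np.full(graph.n_comp, float(v_init))
    else:
        v0 = np.asarray(v_init, dtype=float).copy()
        if v0.shape != (graph.n_comp,):
            raise ValueError("v_init array must have one entry per compartment")

    v_rec, v_final, err = _cable_core.simulate_tree(
        graph.parent, graph.g_axial, graph.C, graph.g_leak,
        graph.params.e_leak, graph.gNa, graph.gK,
        graph.params.e_Na, graph.params.e_K, graph.params.v_shift,
        v0,
        syn_comp, syn_ga, syn_gn, syn_t, tau_a, tau_n, mg, rectify,
        inj_comp, inj_pa, record_idx, n_steps, dt,
    )
    if err >= 0:
        comp = int(record_idx[0])
        raise RuntimeError(
            f"non-finite voltage at t = {err * dt:.3f} ms "
            f"(first recorded compartment {comp})"
        )
    times = np.arange(n_steps + 1) * dt
    if return_final:
        return times, v_rec, v_final
    return times, v_rec


def resting_state(
    graph: CompartmentGraph,
    settle_ms: float = 400.0,
    dt: float = 0.05,
) -> np.ndarray:
    """Per-compartment resting potentials of the full model.

    Settles the model from ``e_leak`` with no input and returns the final
    voltages; used to initialize protocol simulations exactly at rest so
    slow relaxation does not contaminate baselines.
    """
    _, _, v_final = simulate(
        graph, duration=settle_ms, dt=dt, return_final=True
    )
    return v_final


def input_resistance(
    graph: CompartmentGraph,
    i_step: float = -10.0,
) -> float:
    """Somatic input resistance (MΩ) of the passive model.

    Solves the passive steady state directly: (G_leak + G_axial) V = b,
    with and without a small somatic current step, and returns dV/I.
    """
    n = graph.n_comp
    diag = graph.g_leak.astype(float).copy()
    b = graph.g_leak * graph.params.e_leak

    # assemble the symmetric axial Laplacian
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    rows, cols, vals = [], [], []
    for i in range(1, n):
        p = int(graph.parent[i])
        ga = graph.g_axial[i]
        diag[i] += ga
        diag[p] += ga
        rows += [i, p]
        cols += [p, i]
        vals += [-ga, -ga]
    A = sp.csc_matrix(
        (np.concatenate([diag, vals]),
         (np.concatenate([np.arange(n), rows]),
          np.concatenate([np.arange(n), cols]))),
        shape=(n, n),
    )
    solve = spla.factorized(A)
    v0 = solve(b)
    b2 = b.copy()
    b2[0] += i_step
    v1 = solve(b2)
    # mV / pA = GΩ -> MΩ
    return float((v1[0] - v0[0]) / i_step * 1e3)


def calibrate_rm(
    graph: CompartmentGraph,
    target_rin: float = 78.0,
    tol: float = 0.5,
    bracket: tuple[float, float] = (0.1, 10.0),
    max_iter: int = 60,
) -> CableParams:
    """Scale Rm (preserving the proximal/distal ratio) to hit a target Rin.

    Bisection on a single multiplier applied to both membrane
    resistances until the somatic input resistance is within ``tol`` MΩ
    of ``target_rin``. Returns the calibrated parameters.
    """
    from .cable import segmentize  # self-import for clarity

    def rin_at(mult: float) -> float:
        p = graph.params.scale_rm(mult)
        g = segmentize(graph.morph, p)
        return input_resistance(g)

    lo, hi = bracket
    r_lo, r_hi = rin_at(lo), rin_at(hi)
    if not (r_lo < target_rin < r_hi):
        raise RuntimeError(
            f"target {target_rin} MΩ not bracketed: "
            f"Rin({lo}x) = {r_lo:.1f}, Rin({hi}x) = {r_hi:.1f}"
        )
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        r_mid = rin_at(mid)
        if abs(r_mid - target_rin) < tol:
            return graph.params.scale_rm(mid)
        if r_mid < target_rin:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("Rm calibration did not converge within the bracket")
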