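"""In-silico uncaging protocol on the compartmental model.

At a chosen dendritic site, synapses are placed within a fixed path
distance, activated individually and then in increasing cumulative
numbers at a fixed inter-synapse interval, with the somatic voltage
recorded. The resulting TraceSet feeds the nonlinearity statistic
unchanged, mirroring the experimental quantification.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from ..nonlinearity_metrics import TraceSet
from ..synapse_kernels import AMPA_ONTO_PV, BiExpParams, NMDA_ONTO_PV
from .cable import CompartmentGraph, resting_state, simulate
from .morphology import REGION_RADIATUM

__all__ = [
    "SynapseSpec",
    "uncaging_protocol",
    "calibrate_synapse_weight",
    "place_synapses",
]

#: default NMDA/AMPA peak-conductance ratio (equal NMDAR conductance
#: across regions; the ratio manipulation halves it on radiatum-like
#: sections only)
DEFAULT_NMDA_AMPA_RATIO = 1.5
#: target somatic EPSP of a single synapse (mV), in the range of
#: spontaneous EPSPs; chosen so the AMPA-only compound response stays
#: clear of driving-force saturation
SINGLE_EPSP_TARGET_MV = 0.4

CONDITIONS = ("control", "no_nmda", "no_na", "radiatum_half_ratio")
PATTERNS = ("single", "across_dendrites")


@dataclass(frozen=True)
class SynapseSpec:
    """One dual-component synapse at (section, pos).

    ``g_ampa``/``g_nmda`` are peak conductances (nS); kinetics are the
    published network time constants absent compartment-specific values.
    """

    section: int
    pos: float
    g_ampa: float
    g_nmda: float
    ampa_kinetics: BiExpParams = AMPA_ONTO_PV
    nmda_kinetics: BiExpParams = NMDA_ONTO_PV
    mg: float = 1.3
    rectify: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.pos <= 1.0:
            raise ValueError("pos must lie in [0, 1]")
        if self.g_ampa < 0 or self.g_nmda < 0:
            raise ValueError("conductances must be non-negative")


def _compartment_distances(graph: CompartmentGraph, start: int) -> np.ndarray:
    """Path distance (µm) from compartment ``start`` to every compartment."""
    n = graph.n_comp
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(1, n):
        p = int(graph.parent[i])
        d = 0.5 * (graph.length[i] + graph.length[p])
        adj[i].append((p, d))
        adj[p].append((i, d))
    dist = np.full(n, np.inf)
    dist[start] = 0.0
    heap = [(0.0, start)]
    while heap:
        d, i = heapq.heappop(heap)
        if d > dist[i]:
            continue
        for j, w in adj[i]:
            nd = d + w
            if nd < dist[j]:
                dist[j] = nd
                heapq.heappush(heap, (nd, j))
    return dist


def place_synapses(
    graph: CompartmentGraph,
    site: tuple[int, float],
    n_syn: int = 15,
    spread: float = 30.0,
    pattern: str = "single",
) -> list[int]:
    """Compartments for ``n_syn`` synapses within ``spread`` µm of a site.

    ``single`` fills the nearest same-tree compartments (several synapses
    may share a compartment on coarse trees); ``across_dendrites``
    alternates placements between the site's branch and the nearest
    other dendritic branch, at matched distances where possible.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}")
    start = graph.locate(*site)
    dist = _compartment_distances(graph, start)
    dendritic = graph.section_of != 0
    order = np.argsort(dist)
    near = [int(i) for i in order if dendritic[i] and dist[i] <= spread]
    if not near:
        raise ValueError(f"no dendritic compartments within {spread} µm of site")

    if pattern == "single":
        # spread placements evenly over the available extent (uncaging
        # spots are spaced out along the dendrite, not piled at the site)
        if len(near) >= n_syn:
            picks = np.linspace(0, len(near) - 1, n_syn).round().astype(int)
            chosen = [near[int(k)] for k in picks]
        else:
            chosen = [near[k % len(near)] for k in range(n_syn)]
        return chosen

    # across_dendrites: half the synapses stay near the site, the other
    # half go to a different primary dendritic tree at matched somatic
    # path distances (activation spread over two dendrites)
    def tree_of(section: int) -> int:
        sec = graph.morph.sections[int(section)]
        while graph.morph.sections[sec.parent].parent != -1:
            sec = graph.morph.sections[sec.parent]
        return sec.index

    own_tree = tree_of(graph.section_of[start])
    site_dist = graph.path_dist[start]
    other = [
        int(i)
        for i in np.argsort(np.abs(graph.path_dist - site_dist))
        if dendritic[i]
        and tree_of(graph.section_of[i]) != own_tree
        and abs(graph.path_dist[i] - site_dist) <= spread
    ]
    if not other:
        raise ValueError("no second dendrite available for the across pattern")
    chosen = []
    for k in range(n_syn):
        pool = near if k % 2 == 0 else other
        chosen.append(pool[(k // 2) % len(pool)])
    return chosen


def _make_specs(
    graph: CompartmentGraph,
    comps: list[int],
    g_ampa: float,
    ratio: float,
    condition: str,
    rectify: bool,
) -> list[SynapseSpec]:
    specs = []
    for c in comps:
        sec = int(graph.section_of[c])
        pos = float(graph.pos_of[c])
        r = ratio
        if condition == "radiatum_half_ratio":
            if graph.morph.sections[sec].region == REGION_RADIATUM:
                r = ratio / 2.0
        g_nmda = 0.0 if condition == "no_nmda" else r * g_ampa
        specs.append(
            SynapseSpec(
                section=sec, pos=pos, g_ampa=g_ampa, g_nmda=g_nmda,
                rectify=rectify,
            )
        )
    return specs


def calibrate_synapse_weight(
    graph: CompartmentGraph,
    site: tuple[int, float],
    target_mv: float = SINGLE_EPSP_TARGET_MV,
    ratio: float = DEFAULT_NMDA_AMPA_RATIO,
    dt: float = 0.025,
    n_iter: int = 3,
) -> float:
    """AMPA peak conductance giving a ~``target_mv`` somatic EPSP.

    Runs a single-synapse simulation on the passive tree and rescales the
    weight by the amplitude ratio (the response is nearly linear in the
    weight, so a few iterations suffice).
    """
    passive = graph.passive()
    comp = graph.locate(*site)
    g = 1.0
    for _ in range(n_iter):
        spec = SynapseSpec(
            section=int(graph.section_of[comp]),
            pos=float(graph.pos_of[comp]),
            g_ampa=g, g_nmda=ratio * g,
        )
        t, v = simulate(passive, duration=60.0, dt=dt, synapses=[(spec, 10.0)])
        peak = float(np.max(v[0]) - v[0][0])
        if peak <= 0:
            raise RuntimeError("no somatic response during weight calibration")
        g *= target_mv / peak
    return g


def uncaging_protocol(
    graph: CompartmentGraph,
    site: tuple[int, float],
    n_syn: int = 15,
    spread: float = 30.0,
    interval: float = 1.0,
    condition: str = "control",
    pattern: str = "single",
    g_ampa: float | None = None,
    ratio: float = DEFAULT_NMDA_AMPA_RATIO,
    rectify: bool = False,
    dt: float = 0.025,
    t0: float = 10.0,
    window_after: float = 60.0,
    v_rest: np.ndarray | None = None,
) -> TraceSet:
    """Simulated uncaging experiment at one dendritic site.

    Every synapse is activated alone (individual traces), then in
    cumulative groups 1..n with ``interval`` ms between successive
    activations (compound traces), all somatically recorded. The
    condition toggles: ``no_nmda`` zeroes NMDA conductances, ``no_na``
    zeroes all Na+ densities, ``radiatum_half_ratio`` halves the
    NMDA/AMPA ratio on radiatum-like sections.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; one of {CONDITIONS}")
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")

    comps = place_synapses(graph, site, n_syn, spread, pattern)
    if g_ampa is None:
        g_ampa = calibrate_synapse_weight(graph, site, ratio=ratio, dt=dt)
    specs = _make_specs(graph, comps, g_ampa, ratio, condition, rectify)

    sim_graph = graph
    if condition == "no_na":
        import copy

        sim_graph = copy.copy(graph)
        sim_graph.gNa = np.zeros_like(graph.gNa)

    # start every run exactly at rest so slow settling cannot leak into
    # baselines (the arithmetic sum would otherwise accumulate the drift
    # n times while the measured compound contains it once); callers may
    # supply a precomputed rest, except for no_na whose rest differs
    if v_rest is None or condition == "no_na":
        v_rest = resting_state(sim_graph)

    duration = t0 + (n_syn - 1) * interval + window_after
    individual, compound = [], []
    for spec in specs:
        _, v = simulate(
            sim_graph, duration, dt, synapses=[(spec, t0)], rectify=rectify,
            v_init=v_rest,
        )
        individual.append(v[0] - v[0][0])
    for i in range(1, n_syn + 1):
        events = [(specs[k], t0 + k * interval) for k in range(i)]
        _, v = simulate(
            sim_graph, duration, dt, synapses=events, rectify=rectify,
            v_init=v_rest,
        )
        compound.append(v[0] - v[0][0])

    return TraceSet(
        dt=dt,
        individual=np.asarray(individual),
        compound=np.asarray(compound),
        t0=t0,
        inter_site_shift=interval,
    )
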