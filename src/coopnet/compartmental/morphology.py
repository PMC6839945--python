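"""Synthetic PV+ cell morphology and SWC round-trip.

The reconstruction used for the published model is not deposited, so a
stylized stand-in is generated: a cylindrical soma with several
dendritic trees, the oriens-like trees thinner and shorter than the
radiatum-like trees. Sections are straight cylinders of constant
diameter attached end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "MorphSpec",
    "make_synthetic_morphology",
    "site_selection",
]

REGION_SOMA = "soma"
REGION_ORIENS = "oriens"
REGION_RADIATUM = "radiatum"

# SWC type codes: 1 soma, 3 basal dendrite (oriens-like), 4 apical
# dendrite (radiatum-like)
_REGION_TO_SWC = {REGION_SOMA: 1, REGION_ORIENS: 3, REGION_RADIATUM: 4}
_SWC_TO_REGION = {v: k for k, v in _REGION_TO_SWC.items()}


@dataclass(frozen=True)
class Section:
    """A straight cylindrical section attached to its parent's distal end."""

    index: int
    parent: int          # -1 for the root (soma)
    length: float        # µm
    diam: float          # µm
    region: str
    # distal endpoint coordinates (µm); proximal end = parent's endpoint
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.diam <= 0:
            raise ValueError("section length and diameter must be positive")
        if self.region not in _REGION_TO_SWC:
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class Morphology:
    """A rooted tree of cylindrical sections; section 0 is the soma."""

    sections: list[Section]

    def __post_init__(self) -> None:
        if not self.sections or self.sections[0].parent != -1:
            raise ValueError("section 0 must be the root (parent -1)")
        if self.sections[0].region != REGION_SOMA:
            raise ValueError("root section must be the soma")
        for i, s in enumerate(self.sections):
            if s.index != i:
                raise ValueError("section indices must be consecutive")
            if i > 0 and not (0 <= s.parent < i):
                raise ValueError(
                    f"section {i} parent {s.parent} breaks tree ordering"
                )

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    def children(self, index: int) -> list[int]:
        return [s.index for s in self.sections if s.parent == index]

    def path_distance(self, index: int, pos: float = 0.5) -> float:
        """Path distance (µm) from a point on a section to the soma center.

        ``pos`` is the normalized position along the section (0 proximal).
        The soma itself is at distance 0.
        """
        if not 0.0 <= pos <= 1.0:
            raise ValueError("pos must lie in [0, 1]")
        s = self.sections[index]
        if s.region == REGION_SOMA:
            return 0.0
        d = pos * s.length
        p = s.parent
        while self.sections[p].region != REGION_SOMA:
            d += self.sections[p].length
            p = self.sections[p].parent
        return d

    def total_area(self) -> float:
        """Total lateral membrane area (µm^2)."""
        return float(sum(np.pi * s.diam * s.length for s in self.sections))

    # ---- SWC round trip --------------------------------------------
    def to_swc(self, path) -> None:
        """Write one SWC point per section (at its distal end)."""
        lines = ["# generated by coopnet.compartmental"]
        for s in self.sections:
            swc_type = _REGION_TO_SWC[s.region]
            parent = s.parent + 1 if s.parent >= 0 else -1
            lines.append(
                f"{s.index + 1} {swc_type} {s.x:.9g} {s.y:.9g} {s.z:.9g} "
                f"{s.diam / 2:.9g} {parent}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    @classmethod
    def from_swc(cls, path) -> "Morphology":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                pid, typ, x, y, z, r, parent = line.split()
                rows.append(
                    (int(pid), int(typ), float(x), float(y), float(z),
                     float(r), int(parent))
                )
        rows.sort(key=lambda r: r[0])
        coords = {pid: (x, y, z) for pid, _, x, y, z, _, _ in rows}
        sections = []
        for pid, typ, x, y, z, r, parent in rows:
            idx = pid - 1
            if parent == -1:
                # soma is stored as a sphere-equivalent point at the origin
                sections.append(
                    Section(idx, -1, 2 * r, 2 * r, _SWC_TO_REGION[typ],
                            x, y, z)
                )
            else:
                px, py, pz = coords[parent]
                length = float(
                    np.sqrt((x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2)
                )
                sections.append(
                    Section(idx, parent - 1, length, 2 * r,
                            _SWC_TO_REGION[typ], x, y, z)
                )
        return cls(sections)


@dataclass(frozen=True)
class MorphSpec:
    """Per-region generation parameters for the synthetic morphology.

    Lengths and diameters are (mean, jitter) pairs; each drawn value is
    mean * (1 + jitter * U(-1, 1)). Oriens-like trees default to thinner
    and shorter than radiatum-like ones.
    """

    soma_length: float = 15.0
    soma_diam: float = 15.0
    n_oriens_trees: int = 3
    n_radiatum_trees: int = 3
    branch_orders: int = 3
    #: (length mean µm, diameter mean µm) per branch order
    oriens_geometry: tuple = ((50.0, 1.2), (75.0, 0.8), (75.0, 0.55))
    radiatum_geometry: tuple = ((75.0, 2.0), (110.0, 1.2), (110.0, 0.75))
    jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.n_oriens_trees + self.n_radiatum_trees < 1:
            raise ValueError("need at least one dendritic tree")
        if len(self.oriens_geometry) < self.branch_orders or len(
            self.radiatum_geometry
        ) < self.branch_orders:
            raise ValueError("geometry must cover every branch order")


def make_synthetic_morphology(
    spec: MorphSpec | None = None,
    seed: int = 0,
) -> Morphology:
    """Generate a reproducible branching morphology.

    Each tree is a binary tree of ``branch_orders`` levels growing
    radially away from the soma, oriens-like trees into the lower
    half-space and radiatum-like into the upper.
    """
    spec = spec or MorphSpec()
    rng = np.random.default_rng(seed)
    # the soma sits at the origin so dendritic trees (which grow from the
    # parent's endpoint) radiate from the soma point; SWC stores it as a
    # sphere-equivalent single point
    sections = [
        Section(0, -1, spec.soma_length, spec.soma_diam, REGION_SOMA,
                0.0, 0.0, 0.0)
    ]

    def draw(mean: float) -> float:
        return mean * (1.0 + spec.jitter * rng.uniform(-1.0, 1.0))

    def grow(parent_idx, order, region, geometry, direction, origin):
        if order >= spec.branch_orders:
            return
        L = draw(geometry[order][0])
        d = draw(geometry[order][1])
        end = origin + L * direction
        idx = len(sections)
        sections.append(
            Section(idx, parent_idx, L, d, region, *end)
        )
        # two children fanning out from the current direction
        for sign in (-1.0, 1.0):
            angle = rng.uniform(0.25, 0.55) * sign
            c, s = np.cos(angle), np.sin(angle)
            child_dir = np.array(
                [direction[0] * c - direction[1] * s,
                 direction[0] * s + direction[1] * c,
                 direction[2]]
            )
            child_dir /= np.linalg.norm(child_dir)
            grow(idx, order + 1, region, geometry, child_dir, end)

    trees = [(REGION_ORIENS, spec.oriens_geometry, -1.0)] * spec.n_oriens_trees
    trees += [(REGION_RADIATUM, spec.radiatum_geometry, 1.0)] * spec.n_radiatum_trees
    for k, (region, geometry, updown) in enumerate(trees):
        phi = 2.0 * np.pi * k / len(trees) + rng.uniform(0, 0.3)
        direction = np.array(
            [np.cos(phi) * 0.6, np.sin(phi) * 0.6, updown * 0.8]
        )
        direction /= np.linalg.norm(direction)
        grow(0, 0, region, geometry, direction, np.zeros(3))
    return Morphology(sections)


def site_selection(
    morph: Morphology,
    min_dist: float = 40.0,
    max_dist: float = 190.0,
    region: str | None = None,
    spacing: float = 5.0,
) -> list[tuple[int, float]]:
    """Candidate uncaging sites with soma path distance in [min, max] µm.

    Returns (section index, normalized position) pairs sampled every
    ``spacing`` µm along each dendritic section, optionally restricted to
    one region. The distance interval is closed on both ends.
    """
    sites = []
    lo_seen, hi_seen = np.inf, -np.inf
    for s in morph.sections:
        if s.region == REGION_SOMA:
            continue
        if region is not None and s.region != region:
            continue
        n_pts = max(1, int(s.length / spacing))
        for j in range(n_pts):
            pos = (j + 0.5) / n_pts
            d = morph.path_distance(s.index, pos)
            lo_seen, hi_seen = min(lo_seen, d), max(hi_seen, d)
            if min_dist <= d <= max_dist:
                sites.append((s.index, pos))
    if not sites:
        raise ValueError(
            f"no sites in [{min_dist}, {max_dist}] µm; reachable range is "
            f"[{lo_seen:.1f}, {hi_seen:.1f}] µm"
        )
    return sites
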