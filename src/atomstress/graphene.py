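"""Native honeycomb-lattice builders: graphene ribbons and nanotubes.

Carbon atoms are parameterised as aromatic sp² carbon with embedded constants
from the published GAFF "ca" atom type (converted to kJ/mol, nm, rad; the
harmonic constants are doubled because this package writes bonds and angles
as ½k(x−x0)²), zero partial charge.  All values are overridable through
:class:`LatticeSpec` so tests never depend on external parameter files.

Bonded terms are enumerated from connectivity: one bond per nearest-neighbour
pair, one angle per neighbour pair at each atom, one proper torsion per
bond-adjacent path, and (optionally) one periodic improper per three-fold
site to resist out-of-plane pyramidalisation.  A nanotube wraps the sheet
periodically along its width, leaving no edge atoms in that direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .model_io import AtomRecord, BondedTerm, ForceFieldTopology
from .units import KCAL_TO_KJ

__all__ = ["LatticeSpec", "MiniMDState", "build_graphene", "BuilderError"]


class BuilderError(ValueError):
    pass


@dataclass
class LatticeSpec:
    """Geometry and aromatic-carbon force-field parameters for the builder."""

    edge_type: str = "armchair"       # orientation of the long (length) edges
    width: float = 4.0                # nm
    length: float = 4.0               # nm
    bond_length: float = 0.1387       # nm (aromatic C–C)
    k_bond: float = 2 * 478.40 * KCAL_TO_KJ * 100     # kJ/mol/nm²
    k_angle: float = 2 * 67.18 * KCAL_TO_KJ           # kJ/mol/rad²
    theta0: float = math.radians(119.97)
    k_dihedral: float = (14.50 / 4.0) * KCAL_TO_KJ    # kJ/mol, X-ca-ca-X, n=2
    dihedral_multiplicity: int = 2
    dihedral_phase: float = math.pi
    k_improper: float = 1.1 * KCAL_TO_KJ              # kJ/mol, n=2, phase π
    include_impropers: bool = True
    lj_sigma: float = 0.3816 / 2 ** (1 / 6)           # nm
    lj_epsilon: float = 0.0860 * KCAL_TO_KJ           # kJ/mol
    mass: float = 12.011
    coulomb14_scale: float = 1.0 / 1.2
    lj14_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.edge_type not in ("armchair", "zigzag"):
            raise BuilderError(f"edge_type must be armchair or zigzag, got {self.edge_type!r}")
        if self.width <= 0 or self.length <= 0:
            raise BuilderError("width and length must be positive")


@dataclass
class MiniMDState:
    """A ready-to-integrate system: topology, coordinates, velocities."""

    topology: ForceFieldTopology
    coordinates: np.ndarray
    velocities: np.ndarray
    restraint_reference: np.ndarray | None = None
    restraint_k: float = 0.0          # kJ/mol/nm²; excluded from stress terms

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        if self.coordinates.shape != (n, 3) or self.velocities.shape != (n, 3):
            raise BuilderError("coordinate/velocity arrays inconsistent with topology")


def _lattice_points(spec: LatticeSpec):
    """Honeycomb positions; x spans `length`, y spans `width`.

    With zigzag long edges the rectangular 4-atom cell is √3·d × 3·d; the
    armchair orientation swaps the two axes.
    """
    d = spec.bond_length
    zig = spec.edge_type == "zigzag"
    # cell with zigzag rows along x
    cell_x, cell_y = math.sqrt(3.0) * d, 3.0 * d
    basis = np.array([
        [0.0, 0.0], [cell_x / 2.0, d / 2.0],
        [cell_x / 2.0, 3.0 * d / 2.0], [0.0, 2.0 * d],
    ])
    lx, ly = (spec.length, spec.width) if zig else (spec.width, spec.length)
    nx = int(round(lx / cell_x))
    ny = int(round(ly / cell_y))
    if nx < 2 or ny < 2:
        raise BuilderError(
            f"dimensions {spec.width}×{spec.length} nm too small: need ≥2 cells each way"
        )
    pts = []
    for cx in range(nx):
        for cy in range(ny):
            for b in basis:
                pts.append([cx * cell_x + b[0], cy * cell_y + b[1]])
    pts = np.array(pts)
    if not zig:  # armchair long edges: rotate lattice 90°
        pts = pts[:, ::-1].copy()
    return pts, (nx * cell_x, ny * cell_y), zig


def _bond_pairs(xy: np.ndarray, d: float, wrap_y: float | None):
    """Nearest-neighbour pairs at distance d (min-image in y when wrapping)."""
    tol = 1e-6
    if wrap_y is None:
        tree = cKDTree(xy)
        pairs = tree.query_pairs(d + tol, output_type="ndarray")
        return pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
    delta = xy[:, None, :] - xy[None, :, :]
    delta[..., 1] -= wrap_y * np.round(delta[..., 1] / wrap_y)
    dist = np.linalg.norm(delta, axis=-1)
    ii, jj = np.nonzero((dist < d + tol) & (dist > tol))
    keep = ii < jj
    return np.stack([ii[keep], jj[keep]], axis=1)


def build_graphene(spec: LatticeSpec, nanotube: bool = False) -> MiniMDState:
    """Build a graphene ribbon, or a nanotube wrapping the width direction.

    Returns a state with zero velocities; atoms are ordered canonically by
    lattice cell so the output is deterministic.
    """
    xy, (span_x, span_y), zig = _lattice_points(spec)
    d = spec.bond_length
    if nanotube:
        # the width axis is always column 1 of `xy` (the armchair orientation
        # swap in _lattice_points already put it there); its span is the
        # exact lattice period, so wrapping is seamless
        circumference = span_y if zig else span_x
        pairs = _bond_pairs(xy, d, circumference)
        radius = circumference / (2.0 * math.pi)
        phi = 2.0 * math.pi * xy[:, 1] / circumference
        coords = np.stack(
            [xy[:, 0], radius * np.cos(phi), radius * np.sin(phi)], axis=1)
    else:
        pairs = _bond_pairs(xy, d, None)
        coords = np.concatenate([xy, np.zeros((len(xy), 1))], axis=1)
    coords = coords - coords.mean(axis=0)

    n = len(coords)
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        neighbors[int(i)].append(int(j))
        neighbors[int(j)].append(int(i))
    neighbors = [sorted(nb) for nb in neighbors]

    terms: list[BondedTerm] = []
    for i, j in pairs:
        terms.append(BondedTerm("bond", (int(i), int(j)),
                                {"k_b": spec.k_bond, "b0": spec.bond_length}))
    for c in range(n):
        nb = neighbors[c]
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                terms.append(BondedTerm("angle", (nb[a], c, nb[b]),
                                        {"k_theta": spec.k_angle, "theta0": spec.theta0}))
    for j, k in pairs:
        j, k = int(j), int(k)
        for i in neighbors[j]:
            if i == k:
                continue
            for l in neighbors[k]:
                if l == j or l == i:
                    continue
                terms.append(BondedTerm(
                    "dihedral", (i, j, k, l),
                    {"k_phi": spec.k_dihedral,
                     "multiplicity": spec.dihedral_multiplicity,
                     "phase": spec.dihedral_phase}))
    if spec.include_impropers:
        for c in range(n):
            if len(neighbors[c]) == 3:
                p, q, r = neighbors[c]
                terms.append(BondedTerm(
                    "dihedral", (p, q, c, r),
                    {"k_phi": spec.k_improper, "multiplicity": 2, "phase": math.pi}))

    exclusions, pairs14 = _exclusions_from_graph(neighbors, spec)
    atoms = [
        AtomRecord(i, "CA", i, "GRA", spec.mass, 0.0, spec.lj_sigma, spec.lj_epsilon)
        for i in range(n)
    ]
    topology = ForceFieldTopology(atoms, terms, exclusions, pairs14)
    return MiniMDState(topology, coords, np.zeros_like(coords))


def _exclusions_from_graph(neighbors: list[list[int]], spec: LatticeSpec):
    """1-2 and 1-3 pairs fully excluded; 1-4 pairs scaled."""
    exclusions: set[tuple[int, int]] = set()
    pairs14: dict[tuple[int, int], tuple[float, float]] = {}
    for i, nb1 in enumerate(neighbors):
        dist = {i: 0}
        frontier = [i]
        for depth in (1, 2, 3):
            nxt = []
            for a in frontier:
                for b in neighbors[a]:
                    if b not in dist:
                        dist[b] = depth
                        nxt.append(b)
            frontier = nxt
        for j, dd in dist.items():
            if j <= i:
                continue
            if dd <= 2:
                exclusions.add((i, j))
            elif dd == 3:
                pairs14[(i, j)] = (spec.coulomb14_scale, spec.lj14_scale)
    return exclusions, pairs14
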