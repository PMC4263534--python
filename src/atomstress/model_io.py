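"""Topology, trajectory, and index-group input for stress analysis.

The native inputs are plain-text, documented formats:

* **Portable topology** — a sectioned text file mirroring the physics content
  of a processed MD topology.  Sections ``[atoms]``, ``[bonds]``, ``[angles]``,
  ``[dihedrals]``, ``[pairs14]``, ``[exclusions]``, ``[gb]``; ``#`` starts a
  comment; columns are whitespace-separated; all atom indices are 0-based.
  Units: nm, kJ/mol, rad, amu, elementary charge.

  =============  =======================================================
  section        columns
  =============  =======================================================
  [atoms]        index name residue_id residue_name mass charge sigma eps
  [bonds]        i j k_b b0
  [angles]       i j k k_theta theta0
  [dihedrals]    i j k l k_phi multiplicity phase
  [pairs14]      i j coulomb_scale lj_scale
  [exclusions]   i j
  [gb]           index radius screen
  =============  =======================================================

* **Portable trajectory** — per-frame blocks: a ``t=<ps>`` line, an optional
  ``box bx by bz`` line (orthorhombic edges, nm), then one line per atom with
  ``x y z`` or ``x y z vx vy vz`` (nm, nm/ps).  Binary ``.trr``/``.xtc``
  trajectories are read through MDAnalysis when it is installed.

* **Index file** — GROMACS ``.ndx`` dialect: ``[ name ]`` headers followed by
  whitespace-separated 1-based atom indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "BondedTerm",
    "ForceFieldTopology",
    "TrajectoryFrame",
    "IndexGroup",
    "TopologyError",
    "TrajectoryError",
    "IndexError_",
    "read_topology",
    "write_topology",
    "read_trajectory",
    "write_trajectory",
    "read_index",
    "validate_system",
]


class TopologyError(ValueError):
    """Malformed or inconsistent topology input."""


class TrajectoryError(ValueError):
    """Malformed or inconsistent trajectory input."""


class IndexError_(ValueError):
    """Malformed index-group input."""


@dataclass
class AtomRecord:
    """One atom: identity, mass, charge, LJ and optional GB parameters."""

    index: int
    name: str
    residue_id: int
    residue_name: str
    mass: float                     # amu
    charge: float                   # e
    lj_sigma: float                 # nm
    lj_epsilon: float               # kJ/mol
    gb_radius: float | None = None  # nm, intrinsic Born radius
    gb_screen: float | None = None  # dimensionless HCT screening factor

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise TopologyError(f"atom {self.index}: mass must be > 0, got {self.mass}")
        if self.lj_sigma < 0 or self.lj_epsilon < 0:
            raise TopologyError(f"atom {self.index}: LJ parameters must be >= 0")


@dataclass
class BondedTerm:
    """A bond-stretch, angle-bend, or periodic torsion term instance.

    Parameter conventions: bond ``V = ½ k_b (b − b0)²``; angle
    ``V = ½ k_θ (θ − θ0)²``; dihedral ``V = k_φ (1 + cos(nφ − φ_s))`` with the
    phase recorded exactly as given.
    """

    kind: str  # bond | angle | dihedral
    atom_indices: tuple[int, ...]
    parameters: dict[str, float]

    _NATOMS = {"bond": 2, "angle": 3, "dihedral": 4}
    _PARAMS = {
        "bond": ("k_b", "b0"),
        "angle": ("k_theta", "theta0"),
        "dihedral": ("k_phi", "multiplicity", "phase"),
    }

    def __post_init__(self) -> None:
        if self.kind not in self._NATOMS:
            raise TopologyError(f"unknown bonded term kind {self.kind!r}")
        self.atom_indices = tuple(int(i) for i in self.atom_indices)
        if len(self.atom_indices) != self._NATOMS[self.kind]:
            raise TopologyError(
                f"{self.kind} term needs {self._NATOMS[self.kind]} atoms, "
                f"got {len(self.atom_indices)}"
            )
        if len(set(self.atom_indices)) != len(self.atom_indices):
            raise TopologyError(f"{self.kind} term has repeated atom indices {self.atom_indices}")
        missing = [p for p in self._PARAMS[self.kind] if p not in self.parameters]
        if missing:
            raise TopologyError(f"{self.kind} term missing parameters {missing}")
        if self.kind == "dihedral" and int(self.parameters["multiplicity"]) < 1:
            raise TopologyError("dihedral multiplicity must be >= 1")


def _pairkey(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class ForceFieldTopology:
    """Full parameterised system: atoms, bonded terms, nonbonded bookkeeping."""

    atoms: list[AtomRecord]
    bonded_terms: list[BondedTerm] = field(default_factory=list)
    exclusions: set[tuple[int, int]] = field(default_factory=set)
    pairs14: dict[tuple[int, int], tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        self.exclusions = {_pairkey(*p) for p in self.exclusions}
        self.pairs14 = {_pairkey(*p): tuple(s) for p, s in self.pairs14.items()}
        for term in self.bonded_terms:
            for i in term.atom_indices:
                if not 0 <= i < n:
                    raise TopologyError(
                        f"{term.kind} term references atom {i} of a {n}-atom system"
                    )
        for pair in list(self.exclusions) + list(self.pairs14):
            for i in pair:
                if not 0 <= i < n:
                    raise TopologyError(f"pair {pair} references atom {i} of a {n}-atom system")
        overlap = self.exclusions & set(self.pairs14)
        if overlap:
            raise TopologyError(f"pairs appear in both exclusions and pairs14: {sorted(overlap)}")
        self._arrays: dict[str, np.ndarray] = {}

    # -- convenience views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def _cached(self, key: str, build) -> np.ndarray:
        if key not in self._arrays:
            self._arrays[key] = build()
        return self._arrays[key]

    @property
    def masses(self) -> np.ndarray:
        return self._cached("mass", lambda: np.array([a.mass for a in self.atoms]))

    @property
    def charges(self) -> np.ndarray:
        return self._cached("charge", lambda: np.array([a.charge for a in self.atoms]))

    @property
    def lj_sigma(self) -> np.ndarray:
        return self._cached("sigma", lambda: np.array([a.lj_sigma for a in self.atoms]))

    @property
    def lj_epsilon(self) -> np.ndarray:
        return self._cached("eps", lambda: np.array([a.lj_epsilon for a in self.atoms]))

    @property
    def has_gb(self) -> bool:
        return all(a.gb_radius is not None and a.gb_screen is not None for a in self.atoms)

    @property
    def gb_radii(self) -> np.ndarray:
        if not self.has_gb:
            missing = [a.index for a in self.atoms if a.gb_radius is None]
            raise TopologyError(f"GB parameters missing for atoms {missing[:10]}")
        return self._cached("gbr", lambda: np.array([a.gb_radius for a in self.atoms]))

    @property
    def gb_screens(self) -> np.ndarray:
        if not self.has_gb:
            raise TopologyError("GB parameters incomplete")
        return self._cached("gbs", lambda: np.array([a.gb_screen for a in self.atoms]))

    @property
    def residue_map(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_id, []).append(a.index)
        return out

    @property
    def residue_ids(self) -> np.ndarray:
        return self._cached("resid", lambda: np.array([a.residue_id for a in self.atoms]))

    def terms_of_kind(self, kind: str) -> list[BondedTerm]:
        return [t for t in self.bonded_terms if t.kind == kind]


@dataclass
class TrajectoryFrame:
    """One snapshot: time, coordinates, optional velocities and box."""

    time: float                       # ps
    coordinates: np.ndarray           # (n, 3) nm
    velocities: np.ndarray | None = None  # (n, 3) nm/ps
    box: np.ndarray | None = None     # (3,) orthorhombic edges, nm

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TrajectoryError("coordinates must have shape (n, 3)")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coordinates.shape:
                raise TrajectoryError("velocities shape must match coordinates")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(self.box > 0):
                raise TrajectoryError(f"box edges must be positive, got {self.box}")


@dataclass
class IndexGroup:
    name: str
    atom_indices: np.ndarray  # sorted unique 0-based

    def __post_init__(self) -> None:
        self.atom_indices = np.unique(np.asarray(self.atom_indices, dtype=int))


# ---------------------------------------------------------------------------
# portable topology format
# ---------------------------------------------------------------------------

_SECTIONS = ("atoms", "bonds", "angles", "dihedrals", "pairs14", "exclusions", "gb")


def _parse_floats(fields: Sequence[str], lineno: int, path) -> list[float]:
    out = []
    for f in fields:
        try:
            out.append(float(f))
        except ValueError:
            raise TopologyError(f"{path}:{lineno}: non-numeric field {f!r}") from None
    return out


def read_topology(path) -> ForceFieldTopology:
    """Parse the portable sectioned text topology format."""
    path = Path(path)
    section = None
    rows: dict[str, list[tuple[int, list[str]]]] = {s: [] for s in _SECTIONS}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                name = line.strip("[] \t").lower()
                if name not in _SECTIONS:
                    raise TopologyError(f"{path}:{lineno}: unknown section [{name}]")
                section = name
                continue
            if section is None:
                raise TopologyError(f"{path}:{lineno}: data before any section header")
            rows[section].append((lineno, line.split()))

    if not rows["atoms"]:
        raise TopologyError(f"{path}: missing required [atoms] section")

    atoms: list[AtomRecord] = []
    for lineno, f in rows["atoms"]:
        if len(f) != 8:
            raise TopologyError(f"{path}:{lineno}: [atoms] rows need 8 columns, got {len(f)}")
        idx = int(f[0])
        if idx != len(atoms):
            raise TopologyError(f"{path}:{lineno}: atom indices must be 0..n-1 in order")
        mass, charge, sig, eps = _parse_floats(f[4:8], lineno, path)
        atoms.append(AtomRecord(idx, f[1], int(f[2]), f[3], mass, charge, sig, eps))
    n = len(atoms)

    def check_idx(i: int, lineno: int) -> int:
        if not 0 <= i < n:
            raise TopologyError(f"{path}:{lineno}: atom index {i} out of range for {n} atoms")
        return i

    terms: list[BondedTerm] = []
    for lineno, f in rows["bonds"]:
        if len(f) != 4:
            raise TopologyError(f"{path}:{lineno}: [bonds] rows need 4 columns")
        i, j = (check_idx(int(x), lineno) for x in f[:2])
        kb, b0 = _parse_floats(f[2:], lineno, path)
        terms.append(BondedTerm("bond", (i, j), {"k_b": kb, "b0": b0}))
    for lineno, f in rows["angles"]:
        if len(f) != 5:
            raise TopologyError(f"{path}:{lineno}: [angles] rows need 5 columns")
        i, j, k = (check_idx(int(x), lineno) for x in f[:3])
        kt, t0 = _parse_floats(f[3:], lineno, path)
        terms.append(BondedTerm("angle", (i, j, k), {"k_theta": kt, "theta0": t0}))
    for lineno, f in rows["dihedrals"]:
        if len(f) != 7:
            raise TopologyError(f"{path}:{lineno}: [dihedrals] rows need 7 columns")
        ijkl = tuple(check_idx(int(x), lineno) for x in f[:4])
        kp, mult, phase = _parse_floats(f[4:], lineno, path)
        terms.append(
            BondedTerm("dihedral", ijkl, {"k_phi": kp, "multiplicity": mult, "phase": phase})
        )

    pairs14: dict[tuple[int, int], tuple[float, float]] = {}
    for lineno, f in rows["pairs14"]:
        if len(f) != 4:
            raise TopologyError(f"{path}:{lineno}: [pairs14] rows need 4 columns")
        i, j = (check_idx(int(x), lineno) for x in f[:2])
        qs, ls = _parse_floats(f[2:], lineno, path)
        pairs14[_pairkey(i, j)] = (qs, ls)

    exclusions: set[tuple[int, int]] = set()
    for lineno, f in rows["exclusions"]:
        if len(f) != 2:
            raise TopologyError(f"{path}:{lineno}: [exclusions] rows need 2 columns")
        i, j = (check_idx(int(x), lineno) for x in f)
        exclusions.add(_pairkey(i, j))

    for lineno, f in rows["gb"]:
        if len(f) != 3:
            raise TopologyError(f"{path}:{lineno}: [gb] rows need 3 columns")
        i = check_idx(int(f[0]), lineno)
        radius, screen = _parse_floats(f[1:], lineno, path)
        atoms[i].gb_radius = radius
        atoms[i].gb_screen = screen

    return ForceFieldTopology(atoms, terms, exclusions, pairs14)


def write_topology(topology: ForceFieldTopology, path) -> None:
    """Write the portable topology format (full double precision)."""
    lines = ["# portable topology (0-based indices; nm, kJ/mol, rad, amu, e)"]
    lines.append("[atoms]")
    for a in topology.atoms:
        lines.append(
            f"{a.index} {a.name} {a.residue_id} {a.residue_name} "
            f"{a.mass!r} {a.charge!r} {a.lj_sigma!r} {a.lj_epsilon!r}"
        )
    by_kind = {k: topology.terms_of_kind(k) for k in ("bond", "angle", "dihedral")}
    if by_kind["bond"]:
        lines.append("[bonds]")
        for t in by_kind["bond"]:
            i, j = t.atom_indices
            lines.append(f"{i} {j} {t.parameters['k_b']!r} {t.parameters['b0']!r}")
    if by_kind["angle"]:
        lines.append("[angles]")
        for t in by_kind["angle"]:
            i, j, k = t.atom_indices
            lines.append(f"{i} {j} {k} {t.parameters['k_theta']!r} {t.parameters['theta0']!r}")
    if by_kind["dihedral"]:
        lines.append("[dihedrals]")
        for t in by_kind["dihedral"]:
            i, j, k, l = t.atom_indices
            p = t.parameters
            lines.append(
                f"{i} {j} {k} {l} {p['k_phi']!r} {int(p['multiplicity'])} {p['phase']!r}"
            )
    if topology.pairs14:
        lines.append("[pairs14]")
        for (i, j), (qs, ls) in sorted(topology.pairs14.items()):
            lines.append(f"{i} {j} {qs!r} {ls!r}")
    if topology.exclusions:
        lines.append("[exclusions]")
        for i, j in sorted(topology.exclusions):
            lines.append(f"{i} {j}")
    if topology.has_gb:
        lines.append("[gb]")
        for a in topology.atoms:
            lines.append(f"{a.index} {a.gb_radius!r} {a.gb_screen!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def read_trajectory(path, topology: ForceFieldTopology) -> list[TrajectoryFrame]:
    """Read a trajectory (portable text, or .trr/.xtc via MDAnalysis).

    Frames come back in file order with units converted to nm / nm·ps⁻¹.
    A truncated final frame in the portable format is dropped with a warning.
    """
    path = Path(path)
    if path.suffix.lower() in {".trr", ".xtc"}:
        return _read_binary_trajectory(path, topology)
    return _read_portable_trajectory(path, topology)


def _read_portable_trajectory(path: Path, topology: ForceFieldTopology) -> list[TrajectoryFrame]:
    n = topology.n_atoms
    frames: list[TrajectoryFrame] = []
    with open(path) as fh:
        lines = [ln.split("#", 1)[0].strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    pos = 0
    while pos < len(lines):
        header = lines[pos]
        if not header.startswith("t="):
            raise TrajectoryError(f"{path}: expected 't=<ps>' frame header, got {header!r}")
        time = float(header[2:])
        pos += 1
        box = None
        if pos < len(lines) and lines[pos].startswith("box"):
            box = np.array([float(x) for x in lines[pos].split()[1:4]])
            pos += 1
        block = lines[pos:pos + n]
        if len(block) < n or any(b.startswith("t=") for b in block):
            warnings.warn(f"{path}: truncated final frame at t={time} ps dropped")
            break
        coords = np.empty((n, 3))
        vels = None
        for a, ln in enumerate(block):
            vals = [float(x) for x in ln.split()]
            if len(vals) not in (3, 6):
                raise TrajectoryError(f"{path}: atom line needs 3 or 6 numbers, got {len(vals)}")
            coords[a] = vals[:3]
            if len(vals) == 6:
                if vels is None:
                    if a != 0:
                        raise TrajectoryError(f"{path}: mixed velocity presence within a frame")
                    vels = np.empty((n, 3))
                vels[a] = vals[3:]
            elif vels is not None:
                raise TrajectoryError(f"{path}: mixed velocity presence within a frame")
        frames.append(TrajectoryFrame(time, coords, vels, box))
        pos += n
    return frames


def _read_binary_trajectory(path: Path, topology: ForceFieldTopology) -> list[TrajectoryFrame]:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise TrajectoryError("MDAnalysis is required to read binary trajectories") from exc
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    u.load_new(str(path))
    frames = []
    for ts in u.trajectory:
        if ts.n_atoms != topology.n_atoms:
            raise TrajectoryError(
                f"{path}: frame has {ts.n_atoms} atoms, topology has {topology.n_atoms}"
            )
        coords = ts.positions / 10.0  # Å → nm
        vels = ts.velocities / 10.0 if ts.has_velocities else None
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            if not np.allclose(ts.dimensions[3:], 90.0):
                raise TrajectoryError(f"{path}: only orthorhombic boxes are supported")
            box = ts.dimensions[:3] / 10.0
        frames.append(TrajectoryFrame(float(ts.time), coords, vels, box))
    return frames


def write_trajectory(frames: Sequence[TrajectoryFrame], path) -> None:
    """Write frames in the portable text format, full precision."""
    out = []
    for fr in frames:
        out.append(f"t={fr.time!r}")
        if fr.box is not None:
            out.append("box " + " ".join(repr(float(b)) for b in fr.box))
        for a in range(fr.coordinates.shape[0]):
            row = [repr(float(x)) for x in fr.coordinates[a]]
            if fr.velocities is not None:
                row += [repr(float(v)) for v in fr.velocities[a]]
            out.append(" ".join(row))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# index groups
# ---------------------------------------------------------------------------

def read_index(path, n_atoms: int | None = None) -> list[IndexGroup]:
    """Parse a GROMACS-dialect .ndx file (1-based → 0-based indices)."""
    path = Path(path)
    groups: list[IndexGroup] = []
    name = None
    current: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            if line.startswith("["):
                if name is not None:
                    groups.append(IndexGroup(name, np.array(current, dtype=int)))
                name = line.strip("[] \t")
                current = []
                continue
            if name is None:
                raise IndexError_(f"{path}:{lineno}: indices before any group header")
            for tok in line.split():
                try:
                    one_based = int(tok)
                except ValueError:
                    raise IndexError_(f"{path}:{lineno}: non-integer index {tok!r}") from None
                if one_based <= 0 or (n_atoms is not None and one_based > n_atoms):
                    raise IndexError_(
                        f"{path}:{lineno}: index {one_based} out of range (1..{n_atoms})"
                    )
                current.append(one_based - 1)
    if name is not None:
        groups.append(IndexGroup(name, np.array(current, dtype=int)))
    return groups


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def validate_system(
    topology: ForceFieldTopology,
    frames: Sequence[TrajectoryFrame],
    gb_requested: bool = False,
) -> dict:
    """Consistency report for a topology + trajectory pair (report only)."""
    report: dict = {
        "n_atoms": topology.n_atoms,
        "n_frames": len(frames),
        "term_counts": {
            k: len(topology.terms_of_kind(k)) for k in ("bond", "angle", "dihedral")
        },
        "has_velocities": bool(frames) and all(f.velocities is not None for f in frames),
        "has_box": bool(frames) and all(f.box is not None for f in frames),
        "gb_complete": topology.has_gb,
        "problems": [],
        "notes": [],
    }
    for k, fr in enumerate(frames):
        if fr.coordinates.shape[0] != topology.n_atoms:
            report["problems"].append(
                f"frame {k}: {fr.coordinates.shape[0]} atoms, topology has {topology.n_atoms}"
            )
    if gb_requested and not topology.has_gb:
        report["problems"].append("GB stress requested but GB parameters are incomplete")
    if frames and not report["has_box"]:
        report["notes"].append("no box; per-atom carbon volume will be used")
    return report
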