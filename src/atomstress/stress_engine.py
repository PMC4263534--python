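"""Per-atom mean principal virial stress, assembled per frame and per term.

For each atom *i* the per-term mean principal stress (one-third of the trace
of the atomic virial stress tensor) is computed directly from dot products —
the full 3×3 tensor is never assembled:

    s_i(term) = −(1/(6·V_i)) · Σ_j  r_ij · f_ij

where f_ij is the pairwise force on *i* from *j* for that term (many-body
terms entering through their central pairwise decomposition), r_ij = r_i − r_j
and V_i is the atom's characteristic volume.  The optional kinetic term is

    s_i(kinetic) = −m_i·|v_i − v̄|² / (3·V_i)

(always compressive).  Sign convention: tension is positive stress; the
hydrostatic pressure is the negation, so stretched bonds show negative
hydrostatic pressure and an ideal gas positive.  Stresses are reported in
kbar (1 kJ·mol⁻¹·nm⁻³ = 16.6054 bar).

Characteristic volumes are uniform V_box/N when a box is present, else a
fixed per-atom carbon volume; the policy is decided from the first frame and
held constant over the trajectory.  The cutoff restricts only nonbonded
pairs; bonded-term pairs are always included.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import force_decomposition as fd
from .gb_solvation import GBParams, gb_pairwise_stress
from .model_io import ForceFieldTopology, IndexGroup, TrajectoryFrame
from .units import KBAR_PER_KJ_MOL_NM3

__all__ = [
    "StressOptions",
    "CharacteristicVolumes",
    "AtomStressRecord",
    "FrameStress",
    "TrajectoryStress",
    "characteristic_volumes",
    "enumerate_pairs",
    "frame_atom_stress",
    "kinetic_stress",
    "compute_trajectory_stress",
    "POTENTIAL_TERMS",
]

POTENTIAL_TERMS = ("bond", "angle", "dihedral", "coulomb", "vdw", "gb")
ALL_TERMS = POTENTIAL_TERMS + ("kinetic",)

# default per-atom volume without a box: 1.7 Å vdW carbon sphere, (4/3)π(0.17)³
DEFAULT_CARBON_VOLUME = 4.0 / 3.0 * np.pi * 0.17 ** 3  # ≈ 0.02058 nm³

_BRUTE_FORCE_LIMIT = 200


class ConfigurationError(ValueError):
    """Inconsistent stress-calculation configuration."""


@dataclass
class StressOptions:
    cutoff: float = 1.0                     # nm, nonbonded pairs only
    include_kinetic: bool = False
    include_gb: bool = True                 # used only if topology has GB params
    carbon_volume: float = DEFAULT_CARBON_VOLUME  # nm³
    split_terms: bool = False
    selection: IndexGroup | None = None     # None = all atoms
    remove_com_velocity: bool = False       # subtract selection COM velocity
    gb_params: GBParams = field(default_factory=GBParams)

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ConfigurationError("cutoff must be > 0")
        if not self.carbon_volume > 0:
            raise ConfigurationError("carbon_volume must be > 0")


@dataclass
class CharacteristicVolumes:
    volumes: np.ndarray  # per-atom, nm³
    policy: str          # box_uniform | carbon_default


@dataclass
class AtomStressRecord:
    atom_index: int
    frame_time: float
    total: float                 # kbar, tension positive
    per_term: dict[str, float]   # kbar
    hydrostatic_pressure: float  # kbar, = −total


@dataclass
class FrameStress:
    """Per-term per-atom mean principal stress for one frame (kbar)."""

    time: float
    terms: dict[str, np.ndarray]   # term → (n_selected,) kbar
    atom_indices: np.ndarray       # selected atoms the arrays refer to

    @property
    def total(self) -> np.ndarray:
        return sum(self.terms.values())

    @property
    def hydrostatic_pressure(self) -> np.ndarray:
        return -self.total

    def records(self) -> list[AtomStressRecord]:
        tot = self.total
        return [
            AtomStressRecord(
                int(a), self.time, float(tot[k]),
                {t: float(v[k]) for t, v in self.terms.items()}, float(-tot[k]),
            )
            for k, a in enumerate(self.atom_indices)
        ]


@dataclass
class TrajectoryStress:
    """Stacked per-frame stresses: term → (n_frames, n_selected) kbar."""

    times: np.ndarray
    atom_indices: np.ndarray
    terms: dict[str, np.ndarray]

    @property
    def total(self) -> np.ndarray:
        return sum(self.terms.values())


def characteristic_volumes(topology: ForceFieldTopology, frame: TrajectoryFrame,
                           options: StressOptions | None = None) -> CharacteristicVolumes:
    """Uniform V_box/N volumes, or the carbon-atom fallback without a box."""
    options = options or StressOptions()
    n = topology.n_atoms
    if frame.box is not None:
        vbox = float(np.prod(frame.box))
        if vbox <= 0:
            raise ConfigurationError("zero-volume box")
        return CharacteristicVolumes(np.full(n, vbox / n), "box_uniform")
    return CharacteristicVolumes(np.full(n, options.carbon_volume), "carbon_default")


# ---------------------------------------------------------------------------
# pair enumeration
# ---------------------------------------------------------------------------

@dataclass
class PairLists:
    """Nonbonded pair list (within cutoff, exclusions removed, 1-4 scaled)."""

    nb_i: np.ndarray
    nb_j: np.ndarray
    q_scale: np.ndarray
    lj_scale: np.ndarray


def _candidate_pairs(coords: np.ndarray, cutoff: float, box: np.ndarray | None):
    n = len(coords)
    if n <= _BRUTE_FORCE_LIMIT:
        ii, jj = np.triu_indices(n, k=1)
        rvec = fd.minimum_image(coords[ii] - coords[jj], box)
        r2 = np.einsum("ij,ij->i", rvec, rvec)
        keep = r2 <= cutoff * cutoff
        return ii[keep], jj[keep]
    if box is not None:
        wrapped = np.mod(coords, box)
        # guard against coordinates landing exactly on the upper box face
        wrapped = np.where(wrapped >= box, 0.0, wrapped)
        tree = cKDTree(wrapped, boxsize=box)
    else:
        tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        z = np.zeros(0, dtype=int)
        return z, z
    ii = np.minimum(pairs[:, 0], pairs[:, 1])
    jj = np.maximum(pairs[:, 0], pairs[:, 1])
    return ii, jj


def enumerate_pairs(frame: TrajectoryFrame, topology: ForceFieldTopology,
                    options: StressOptions) -> PairLists:
    """Nonbonded pairs within the cutoff (minimum image when periodic).

    Bonded-term pairs are taken directly from the topology by the per-term
    kernels and are not subject to the cutoff.
    """
    box = frame.box
    if box is not None and options.cutoff > 0.5 * float(np.min(box)):
        raise ConfigurationError(
            f"cutoff {options.cutoff} nm exceeds half the shortest box edge "
            f"{0.5 * float(np.min(box))} nm (minimum-image ambiguity)"
        )
    ii, jj = _candidate_pairs(frame.coordinates, options.cutoff, box)
    if len(ii) == 0:
        z = np.zeros(0)
        return PairLists(ii, jj, z, z)
    n = topology.n_atoms
    keys = ii.astype(np.int64) * n + jj
    excl_keys, p14_keys, p14_qs, p14_ls = _packed_pair_tables(topology)
    if len(excl_keys):
        keep = ~np.isin(keys, excl_keys)
        ii, jj, keys = ii[keep], jj[keep], keys[keep]
    qs = np.ones(len(ii))
    ls = np.ones(len(ii))
    if len(p14_keys):
        pos = np.searchsorted(p14_keys, keys)
        pos_c = np.minimum(pos, len(p14_keys) - 1)
        hit = p14_keys[pos_c] == keys
        qs[hit] = p14_qs[pos_c[hit]]
        ls[hit] = p14_ls[pos_c[hit]]
    return PairLists(ii, jj, qs, ls)


def _packed_pair_tables(topology: ForceFieldTopology):
    """Sorted packed-key (i*n+j, i<j) tables for exclusions and 1-4 pairs."""
    cache = getattr(topology, "_packed_pairs", None)
    if cache is not None:
        return cache
    n = topology.n_atoms
    excl = np.sort(np.array(
        [i * n + j for i, j in topology.exclusions], dtype=np.int64))
    items = sorted(topology.pairs14.items())
    p14_keys = np.array([i * n + j for (i, j), _ in items], dtype=np.int64)
    p14_qs = np.array([s[0] for _, s in items])
    p14_ls = np.array([s[1] for _, s in items])
    cache = (excl, p14_keys, p14_qs, p14_ls)
    topology._packed_pairs = cache
    return cache


# ---------------------------------------------------------------------------
# stress assembly
# ---------------------------------------------------------------------------

def _topology_term_arrays(topology: ForceFieldTopology):
    """Cache bonded-term index/parameter arrays on the topology object."""
    cache = getattr(topology, "_term_arrays", None)
    if cache is not None:
        return cache
    bonds = topology.terms_of_kind("bond")
    angles = topology.terms_of_kind("angle")
    dihedrals = topology.terms_of_kind("dihedral")
    cache = {
        "bond_idx": np.array([t.atom_indices for t in bonds], dtype=int).reshape(-1, 2),
        "bond_k": np.array([t.parameters["k_b"] for t in bonds]),
        "bond_b0": np.array([t.parameters["b0"] for t in bonds]),
        "angle_idx": np.array([t.atom_indices for t in angles], dtype=int).reshape(-1, 3),
        "angle_k": np.array([t.parameters["k_theta"] for t in angles]),
        "angle_t0": np.array([t.parameters["theta0"] for t in angles]),
        "dih_idx": np.array([t.atom_indices for t in dihedrals], dtype=int).reshape(-1, 4),
        "dih_k": np.array([t.parameters["k_phi"] for t in dihedrals]),
        "dih_n": np.array([int(t.parameters["multiplicity"]) for t in dihedrals]),
        "dih_phase": np.array([t.parameters["phase"] for t in dihedrals]),
    }
    topology._term_arrays = cache
    return cache


def pair_batches_for_frame(frame: TrajectoryFrame, topology: ForceFieldTopology,
                           options: StressOptions) -> list[fd.PairBatch]:
    """All pairwise-force batches (one per potential term) for one frame."""
    coords = frame.coordinates
    box = frame.box
    arrs = _topology_term_arrays(topology)
    batches = [
        fd.bond_forces_batch(coords, arrs["bond_idx"], arrs["bond_k"],
                             arrs["bond_b0"], box),
        fd.angle_forces_batch(coords, arrs["angle_idx"], arrs["angle_k"],
                              arrs["angle_t0"], box),
        fd.dihedral_forces_batch(coords, arrs["dih_idx"], arrs["dih_k"],
                                 arrs["dih_n"], arrs["dih_phase"], box),
    ]
    pl = enumerate_pairs(frame, topology, options)
    coul, vdw = fd.nonbonded_forces_batch(
        coords, pl.nb_i, pl.nb_j, topology.charges, topology.lj_sigma,
        topology.lj_epsilon, pl.q_scale, pl.lj_scale, box,
    )
    batches += [coul, vdw]
    if options.include_gb and topology.has_gb:
        gbp = replace(options.gb_params, cutoff=options.cutoff)
        batches.append(
            gb_pairwise_stress(coords, topology.charges, topology.gb_radii,
                               topology.gb_screens, gbp)
        )
    return batches


def frame_atom_stress(frame: TrajectoryFrame, topology: ForceFieldTopology,
                      options: StressOptions,
                      volumes: CharacteristicVolumes) -> FrameStress:
    """Per-term mean principal stress for every selected atom, kbar."""
    n = topology.n_atoms
    sel = (options.selection.atom_indices if options.selection is not None
           else np.arange(n))
    per_atom = {t: np.zeros(n) for t in POTENTIAL_TERMS}
    for batch in pair_batches_for_frame(frame, topology, options):
        if batch.n_pairs == 0:
            continue
        w = batch.virial_scalars()
        np.add.at(per_atom[batch.term], batch.atoms_i, w)
        np.add.at(per_atom[batch.term], batch.atoms_j, w)
    scale = -KBAR_PER_KJ_MOL_NM3 / (6.0 * volumes.volumes)
    terms = {t: (v * scale)[sel] for t, v in per_atom.items()}
    if options.include_kinetic:
        terms["kinetic"] = kinetic_stress(frame, topology, volumes, options)[sel]
    return FrameStress(frame.time, terms, sel)


def kinetic_stress(frame: TrajectoryFrame, topology: ForceFieldTopology,
                   volumes: CharacteristicVolumes,
                   options: StressOptions | None = None) -> np.ndarray:
    """Kinetic mean principal stress per atom, kbar (always ≤ 0)."""
    if frame.velocities is None:
        raise ConfigurationError(
            f"kinetic stress requested but frame at t={frame.time} ps has no velocities"
        )
    v = frame.velocities
    if options is not None and options.remove_com_velocity:
        sel = (options.selection.atom_indices if options.selection is not None
               else np.arange(topology.n_atoms))
        m = topology.masses[sel]
        vbar = np.sum(m[:, None] * v[sel], axis=0) / np.sum(m)
        v = v - vbar
    v2 = np.einsum("ij,ij->i", v, v)
    return -topology.masses * v2 / (3.0 * volumes.volumes) * KBAR_PER_KJ_MOL_NM3


def compute_trajectory_stress(topology: ForceFieldTopology,
                              frames,
                              options: StressOptions | None = None) -> TrajectoryStress:
    """Run the stress engine over a whole trajectory.

    The characteristic-volume policy is fixed from the first frame, per the
    constant-volume convention.
    """
    options = options or StressOptions()
    frames = list(frames)
    if not frames:
        raise ConfigurationError("empty trajectory")
    if options.include_kinetic and any(f.velocities is None for f in frames):
        raise ConfigurationError("kinetic term requested but trajectory lacks velocities")
    volumes = characteristic_volumes(topology, frames[0], options)
    frame_results = [frame_atom_stress(f, topology, options, volumes) for f in frames]
    times = np.array([f.time for f in frame_results])
    terms = {
        t: np.stack([fr.terms[t] for fr in frame_results])
        for t in frame_results[0].terms
    }
    return TrajectoryStress(times, frame_results[0].atom_indices, terms)
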