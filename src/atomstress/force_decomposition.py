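"""Pairwise decomposition of classical force-field terms into central forces.

Virial stress attribution requires every force contribution to act between an
atom *pair*, along the pair separation.  Two-body terms (bond, LJ, Coulomb)
are already central.  The many-body angle and torsion terms are made pairwise
by writing their energies as functions of the interatomic distances of the
triple/quadruple and differentiating through those distances: for an energy
``V(r_ab, ...)`` the force on atom ``a`` from pair ``(a, b)`` is
``−(∂V/∂r_ab)·ê_ab``, which is central by construction and whose per-atom sums
reproduce the exact analytic gradient.

For an angle i–j–k, ``cos θ`` is a function of the three distances
(law of cosines), giving three pairwise forces (i–j, k–j, i–k).  For a
periodic torsion i–j–k–l with phase 0 or π the energy depends on the dihedral
angle only through ``cos(nφ) = ±T_n(cos φ)`` (Chebyshev polynomial), and
``cos φ`` is a rational function of the six squared interatomic distances of
the quadruple; the sine-ratio singularity of general phases never arises.
Phases outside {0, π} raise :class:`UnsupportedPhaseError`.

Batch functions operate on index arrays and are the fast path used by the
stress engine and the mini-MD integrator; the scalar ``*_pair_force``
functions wrap them for single-term use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import COULOMB_CONSTANT

__all__ = [
    "PairForce",
    "PairGeometry",
    "PairBatch",
    "DegenerateGeometryError",
    "UnsupportedPhaseError",
    "bond_pair_force",
    "angle_pairwise_forces",
    "dihedral_pairwise_forces",
    "lj_pair_force",
    "coulomb_pair_force",
    "bond_forces_batch",
    "angle_forces_batch",
    "dihedral_forces_batch",
    "nonbonded_forces_batch",
    "bond_energy_batch",
    "angle_energy_batch",
    "dihedral_energy_batch",
    "nonbonded_energy_batch",
]

_SIN_TOL = 1e-8
_PLANE_TOL = 1e-24  # on squared-norm products, nm⁴


class DegenerateGeometryError(ValueError):
    """Geometry where a pairwise decomposition denominator vanishes."""


class UnsupportedPhaseError(ValueError):
    """Torsion phase outside {0, π}: the pairwise split is singular."""


@dataclass
class PairGeometry:
    """Separation r_ij = r_i − r_j (minimum-image applied upstream)."""

    r_ij: np.ndarray
    distance: float

    @classmethod
    def from_vector(cls, r_ij) -> "PairGeometry":
        r_ij = np.asarray(r_ij, dtype=float)
        d = float(np.linalg.norm(r_ij))
        if d <= 0:
            raise DegenerateGeometryError("coincident atoms: |r_ij| = 0")
        return cls(r_ij, d)


@dataclass
class PairForce:
    """Force on atom i due to atom j, attributed to one potential term."""

    i: int
    j: int
    force_on_i: np.ndarray  # kJ/mol/nm
    term: str


@dataclass
class PairBatch:
    """Vectorised pair forces: force_on_i[p] acts on atoms_i[p] from atoms_j[p].

    ``rvec[p] = r_i − r_j`` is the separation used, so the per-pair virial
    scalar is ``rvec · force_on_i`` (identical viewed from either atom).
    """

    atoms_i: np.ndarray
    atoms_j: np.ndarray
    rvec: np.ndarray
    force_on_i: np.ndarray
    term: str

    @property
    def n_pairs(self) -> int:
        return len(self.atoms_i)

    def virial_scalars(self) -> np.ndarray:
        """Per-pair r_ij · f_ij, kJ/mol."""
        return np.einsum("ij,ij->i", self.rvec, self.force_on_i)

    def accumulate_atom_forces(self, out: np.ndarray) -> None:
        np.add.at(out, self.atoms_i, self.force_on_i)
        np.add.at(out, self.atoms_j, -self.force_on_i)


def _empty_batch(term: str) -> PairBatch:
    z = np.zeros(0, dtype=int)
    return PairBatch(z, z, np.zeros((0, 3)), np.zeros((0, 3)), term)


def minimum_image(rvec: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Wrap displacement vectors into the primary orthorhombic image."""
    if box is None:
        return rvec
    return rvec - box * np.round(rvec / box)


# ---------------------------------------------------------------------------
# two-body terms
# ---------------------------------------------------------------------------

def bond_pair_force(geometry: PairGeometry, k_b: float, b0: float) -> PairForce:
    """Harmonic bond V = ½k_b(b−b0)²; force on i is −k_b(b−b0)·ê_ij."""
    b = geometry.distance
    if b <= 0:
        raise DegenerateGeometryError("bond between coincident atoms")
    f = -k_b * (b - b0) / b * geometry.r_ij
    return PairForce(0, 1, f, "bond")


def lj_pair_force(geometry: PairGeometry, sigma: float, epsilon: float,
                  scale: float = 1.0) -> PairForce:
    """Lennard-Jones V = 4ε[(σ/r)¹² − (σ/r)⁶] with optional 1-4 scaling."""
    r = geometry.distance
    if r <= 0:
        raise DegenerateGeometryError("LJ pair at zero separation")
    sr6 = (sigma / r) ** 6
    # dV/dr = -(24ε/r)(2 sr12 - sr6); force on i = -(dV/dr) ê_ij
    mag = scale * 24.0 * epsilon / r * (2.0 * sr6 * sr6 - sr6)
    return PairForce(0, 1, mag / r * geometry.r_ij, "vdw")


def coulomb_pair_force(geometry: PairGeometry, q_i: float, q_j: float,
                       scale: float = 1.0) -> PairForce:
    """Coulomb V = f·q_i·q_j/r; repulsive for like charges."""
    r = geometry.distance
    if r <= 0:
        raise DegenerateGeometryError("Coulomb pair at zero separation")
    mag = scale * COULOMB_CONSTANT * q_i * q_j / (r * r)
    return PairForce(0, 1, mag / r * geometry.r_ij, "coulomb")


# ---------------------------------------------------------------------------
# angle
# ---------------------------------------------------------------------------

def _angle_pair_scalars(coords: np.ndarray, idx: np.ndarray, k_theta: np.ndarray,
                        theta0: np.ndarray, box=None):
    """Per-angle scalars g_ab = ∂V/∂r_ab for pairs (i,j), (k,j), (i,k)."""
    ri, rj, rk = coords[idx[:, 0]], coords[idx[:, 1]], coords[idx[:, 2]]
    v_ij = minimum_image(ri - rj, box)
    v_kj = minimum_image(rk - rj, box)
    v_ik = minimum_image(ri - rk, box)
    b1 = np.linalg.norm(v_ij, axis=1)
    b2 = np.linalg.norm(v_kj, axis=1)
    c = np.linalg.norm(v_ik, axis=1)
    if np.any(b1 <= 0) or np.any(b2 <= 0):
        raise DegenerateGeometryError("angle term with coincident atoms")
    cos_t = (b1 * b1 + b2 * b2 - c * c) / (2.0 * b1 * b2)
    cos_t = np.clip(cos_t, -1.0, 1.0)
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    bad = sin_t < _SIN_TOL
    if np.any(bad):
        raise DegenerateGeometryError(
            f"collinear arms in angle terms {np.nonzero(bad)[0].tolist()}"
        )
    theta = np.arccos(cos_t)
    # dV/dcosθ = k(θ−θ0)·(−1/sinθ)
    dv_dcos = -k_theta * (theta - theta0) / sin_t
    s3 = c * c
    dcos_db1 = (b1 * b1 - b2 * b2 + s3) / (2.0 * b1 * b1 * b2)
    dcos_db2 = (b2 * b2 - b1 * b1 + s3) / (2.0 * b2 * b2 * b1)
    dcos_dc = -c / (b1 * b2)
    g_ij = dv_dcos * dcos_db1
    g_kj = dv_dcos * dcos_db2
    g_ik = dv_dcos * dcos_dc
    return (v_ij, b1, g_ij), (v_kj, b2, g_kj), (v_ik, c, g_ik), theta


def angle_pairwise_forces(coords, k_theta: float, theta0: float) -> list[PairForce]:
    """Decompose one angle i–j–k (coords rows i, j, k) into 3 central pairs."""
    coords = np.asarray(coords, dtype=float)
    idx = np.array([[0, 1, 2]])
    (vij, b1, gij), (vkj, b2, gkj), (vik, c, gik), _ = _angle_pair_scalars(
        coords, idx, np.array([k_theta]), np.array([theta0])
    )
    return [
        PairForce(0, 1, (-gij[0] / b1[0]) * vij[0], "angle"),
        PairForce(2, 1, (-gkj[0] / b2[0]) * vkj[0], "angle"),
        PairForce(0, 2, (-gik[0] / c[0]) * vik[0], "angle"),
    ]


def angle_forces_batch(coords: np.ndarray, idx: np.ndarray, k_theta: np.ndarray,
                       theta0: np.ndarray, box=None) -> PairBatch:
    """All angle terms at once; returns 3·n_angles central pair forces."""
    if len(idx) == 0:
        return _empty_batch("angle")
    (vij, b1, gij), (vkj, b2, gkj), (vik, c, gik), _ = _angle_pair_scalars(
        coords, idx, k_theta, theta0, box
    )
    ai = np.concatenate([idx[:, 0], idx[:, 2], idx[:, 0]])
    aj = np.concatenate([idx[:, 1], idx[:, 1], idx[:, 2]])
    rvec = np.concatenate([vij, vkj, vik])
    g = np.concatenate([gij, gkj, gik])
    d = np.concatenate([b1, b2, c])
    f = (-g / d)[:, None] * rvec
    return PairBatch(ai, aj, rvec, f, "angle")


# ---------------------------------------------------------------------------
# dihedral
# ---------------------------------------------------------------------------

def _chebyshev_U(n_minus_1: np.ndarray, x: np.ndarray) -> np.ndarray:
    """U_{n−1}(x) elementwise for small integer multiplicities."""
    out = np.empty_like(x)
    for n1 in np.unique(n_minus_1):
        m = n_minus_1 == n1
        u_prev, u = np.zeros(m.sum()), np.ones(m.sum())  # U_{-1}, U_0
        xm = x[m]
        for _ in range(int(n1)):
            u_prev, u = u, 2.0 * xm * u - u_prev
        out[m] = u
    return out


def _dihedral_pair_scalars(coords, idx, k_phi, mult, phase, box=None):
    """∂V/∂s_ab (s = squared distance) for the 6 pairs of each quadruple."""
    r = [coords[idx[:, a]] for a in range(4)]
    # pair displacement vectors r_a − r_b for the 6 pairs, minimum-imaged
    pairs = [(0, 1), (1, 2), (2, 3), (0, 2), (1, 3), (0, 3)]
    vecs = [minimum_image(r[a] - r[b], box) for a, b in pairs]
    s12, s23, s34, s13, s24, s14 = [np.einsum("ij,ij->i", v, v) for v in vecs]

    P, Q, R = s12, s23, s34
    A = 0.5 * (s13 - s12 - s23)
    B = 0.5 * (s24 - s23 - s34)
    C = 0.5 * (s14 + s23 - s13 - s24)

    D1 = P * Q - A * A      # |b1×b2|²
    D2 = Q * R - B * B      # |b2×b3|²
    bad = (D1 <= _PLANE_TOL) | (D2 <= _PLANE_TOL)
    if np.any(bad):
        raise DegenerateGeometryError(
            f"collinear consecutive atoms in dihedral terms {np.nonzero(bad)[0].tolist()}"
        )
    D = np.sqrt(D1 * D2)
    N = A * B - C * Q
    x = np.clip(N / D, -1.0, 1.0)

    phase = np.asarray(phase, dtype=float)
    cos_phase = np.cos(phase)
    if not np.allclose(np.abs(cos_phase), 1.0, atol=1e-9):
        off = np.nonzero(np.abs(np.abs(cos_phase) - 1.0) > 1e-9)[0]
        raise UnsupportedPhaseError(
            f"dihedral phase must be 0 or π; offending terms {off.tolist()}"
        )
    cos_phase = np.round(cos_phase)

    # V = k(1 + cosφ_s·T_n(x));  dV/dx = k·cosφ_s·n·U_{n−1}(x)
    n = np.asarray(mult, dtype=int)
    dv_dx = k_phi * cos_phase * n * _chebyshev_U(n - 1, x)

    h_P = -x * Q / (2.0 * D1)
    h_Q = -C / D - x * (P / (2.0 * D1) + R / (2.0 * D2))
    h_R = -x * Q / (2.0 * D2)
    h_A = B / D + x * A / D1
    h_B = A / D + x * B / D2
    h_C = -Q / D

    dx_ds = [
        h_P - 0.5 * h_A,                          # s12
        h_Q - 0.5 * h_A - 0.5 * h_B + 0.5 * h_C,  # s23
        h_R - 0.5 * h_B,                          # s34
        0.5 * h_A - 0.5 * h_C,                    # s13
        0.5 * h_B - 0.5 * h_C,                    # s24
        0.5 * h_C,                                # s14
    ]
    dv_ds = [dv_dx * d for d in dx_ds]
    return pairs, vecs, dv_ds, x


def dihedral_forces_batch(coords: np.ndarray, idx: np.ndarray, k_phi: np.ndarray,
                          mult: np.ndarray, phase: np.ndarray, box=None) -> PairBatch:
    """All torsion terms at once; 6·n_dihedrals central pair forces."""
    if len(idx) == 0:
        return _empty_batch("dihedral")
    pairs, vecs, dv_ds, _ = _dihedral_pair_scalars(coords, idx, k_phi, mult, phase, box)
    ai = np.concatenate([idx[:, a] for a, _ in pairs])
    aj = np.concatenate([idx[:, b] for _, b in pairs])
    rvec = np.concatenate(vecs)
    g = np.concatenate(dv_ds)
    # V depends on s_ab = r_ab²: force on a = −(∂V/∂s)·2·(r_a − r_b)
    f = (-2.0 * g)[:, None] * rvec
    return PairBatch(ai, aj, rvec, f, "dihedral")


def dihedral_pairwise_forces(coords, k_phi: float, multiplicity: int,
                             phase: float) -> list[PairForce]:
    """Decompose one torsion i–j–k–l (coords rows in order) into 6 pairs."""
    coords = np.asarray(coords, dtype=float)
    idx = np.array([[0, 1, 2, 3]])
    batch = dihedral_forces_batch(
        coords, idx, np.array([k_phi]), np.array([multiplicity]), np.array([phase])
    )
    return [
        PairForce(int(batch.atoms_i[p]), int(batch.atoms_j[p]),
                  batch.force_on_i[p], "dihedral")
        for p in range(batch.n_pairs)
    ]


# ---------------------------------------------------------------------------
# batch two-body paths
# ---------------------------------------------------------------------------

def bond_forces_batch(coords: np.ndarray, idx: np.ndarray, k_b: np.ndarray,
                      b0: np.ndarray, box=None) -> PairBatch:
    if len(idx) == 0:
        return _empty_batch("bond")
    rvec = minimum_image(coords[idx[:, 0]] - coords[idx[:, 1]], box)
    b = np.linalg.norm(rvec, axis=1)
    if np.any(b <= 0):
        raise DegenerateGeometryError("bond between coincident atoms")
    f = (-k_b * (b - b0) / b)[:, None] * rvec
    return PairBatch(idx[:, 0].copy(), idx[:, 1].copy(), rvec, f, "bond")


def nonbonded_forces_batch(coords: np.ndarray, pairs_i: np.ndarray, pairs_j: np.ndarray,
                           charges: np.ndarray, sigma: np.ndarray, epsilon: np.ndarray,
                           q_scale: np.ndarray, lj_scale: np.ndarray,
                           box=None) -> tuple[PairBatch, PairBatch]:
    """Coulomb and LJ batches over a precomputed pair list.

    Combination rules: Lorentz–Berthelot (σ arithmetic, ε geometric).
    """
    if len(pairs_i) == 0:
        return _empty_batch("coulomb"), _empty_batch("vdw")
    rvec = minimum_image(coords[pairs_i] - coords[pairs_j], box)
    r2 = np.einsum("ij,ij->i", rvec, rvec)
    if np.any(r2 <= 0):
        raise DegenerateGeometryError("nonbonded pair at zero separation")
    r = np.sqrt(r2)
    qmag = q_scale * COULOMB_CONSTANT * charges[pairs_i] * charges[pairs_j] / r2
    f_coul = (qmag / r)[:, None] * rvec
    sig = 0.5 * (sigma[pairs_i] + sigma[pairs_j])
    eps = np.sqrt(epsilon[pairs_i] * epsilon[pairs_j])
    sr6 = (sig * sig / r2) ** 3
    ljmag = lj_scale * 24.0 * eps / r * (2.0 * sr6 * sr6 - sr6)
    f_lj = (ljmag / r)[:, None] * rvec
    return (
        PairBatch(pairs_i, pairs_j, rvec, f_coul, "coulomb"),
        PairBatch(pairs_i, pairs_j, rvec, f_lj, "vdw"),
    )


# ---------------------------------------------------------------------------
# energies (same parameterisation; used by the integrator and diagnostics)
# ---------------------------------------------------------------------------

def bond_energy_batch(coords, idx, k_b, b0, box=None) -> float:
    if len(idx) == 0:
        return 0.0
    rvec = minimum_image(coords[idx[:, 0]] - coords[idx[:, 1]], box)
    b = np.linalg.norm(rvec, axis=1)
    return float(np.sum(0.5 * k_b * (b - b0) ** 2))


def angle_energy_batch(coords, idx, k_theta, theta0, box=None) -> float:
    if len(idx) == 0:
        return 0.0
    *_, theta = _angle_pair_scalars(coords, idx, k_theta, theta0, box)
    return float(np.sum(0.5 * k_theta * (theta - theta0) ** 2))


def dihedral_energy_batch(coords, idx, k_phi, mult, phase, box=None) -> float:
    if len(idx) == 0:
        return 0.0
    _, _, _, x = _dihedral_pair_scalars(coords, idx, k_phi, mult, phase, box)
    n = np.asarray(mult, dtype=int)
    # T_n(x) via cos(n·arccos x); x is clipped to [-1, 1] upstream
    tn = np.cos(n * np.arccos(x))
    return float(np.sum(k_phi * (1.0 + np.round(np.cos(phase)) * tn)))


def nonbonded_energy_batch(coords, pairs_i, pairs_j, charges, sigma, epsilon,
                           q_scale, lj_scale, box=None) -> tuple[float, float]:
    if len(pairs_i) == 0:
        return 0.0, 0.0
    rvec = minimum_image(coords[pairs_i] - coords[pairs_j], box)
    r2 = np.einsum("ij,ij->i", rvec, rvec)
    r = np.sqrt(r2)
    e_coul = float(np.sum(q_scale * COULOMB_CONSTANT * charges[pairs_i] * charges[pairs_j] / r))
    sig = 0.5 * (sigma[pairs_i] + sigma[pairs_j])
    eps = np.sqrt(epsilon[pairs_i] * epsilon[pairs_j])
    sr6 = (sig * sig / r2) ** 3
    e_lj = float(np.sum(lj_scale * 4.0 * eps * (sr6 * sr6 - sr6)))
    return e_coul, e_lj
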