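"""Minimal NVE molecular dynamics for stress-wave experiments.

A velocity-Verlet integrator over the package's own vectorised force kernels,
with a Verlet neighbour list (skin-based rebuild) for the nonbonded terms and
an optional weak harmonic position restraint.  The restraint holds the sheet
in place during pulse experiments but is never part of the stress terms.
Intended for the small, stiff, ultra-cold systems of the wave experiments —
not a general-purpose MD engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import force_decomposition as fd
from ._kernels import HAVE_NUMBA, bonded_forces_kernel, nonbonded_forces_kernel
from .graphene import MiniMDState
from .model_io import ForceFieldTopology, TrajectoryFrame
from .stress_engine import _packed_pair_tables, _topology_term_arrays
from .units import BOLTZMANN_KJ_MOL_K

__all__ = ["SystemForces", "nve_integrate", "maxwell_velocities",
           "apply_velocity_pulse", "IntegrationBlowupError"]


class IntegrationBlowupError(RuntimeError):
    pass


class SystemForces:
    """Per-atom forces and potential energy with a reusable neighbour list."""

    def __init__(self, topology: ForceFieldTopology, cutoff: float = 1.0,
                 skin: float = 0.2, include_nonbonded: bool = True,
                 use_compiled: bool | None = None):
        self.topology = topology
        self.cutoff = cutoff
        self.skin = skin
        self.include_nonbonded = include_nonbonded
        self.arrs = _topology_term_arrays(topology)
        self.use_compiled = HAVE_NUMBA if use_compiled is None else use_compiled
        self._dih_cosphase = np.round(np.cos(self.arrs["dih_phase"]))
        self._nb = None           # (pairs_i, pairs_j, qs, ls)
        self._nb_coords = None
        self.n_evaluations = 0

    def _neighbour_pairs(self, coords: np.ndarray):
        if (self._nb is not None and
                np.max(np.abs(coords - self._nb_coords)) < 0.5 * self.skin):
            return self._nb
        n = len(coords)
        reach = self.cutoff + self.skin
        if n <= 400:
            ii, jj = np.triu_indices(n, k=1)
            r2 = np.einsum("ij,ij->i", coords[ii] - coords[jj], coords[ii] - coords[jj])
            keep = r2 <= reach * reach
            ii, jj = ii[keep], jj[keep]
        else:
            pairs = cKDTree(coords).query_pairs(reach, output_type="ndarray")
            if len(pairs):
                ii = np.minimum(pairs[:, 0], pairs[:, 1])
                jj = np.maximum(pairs[:, 0], pairs[:, 1])
            else:
                ii = jj = np.zeros(0, dtype=int)
        keys = ii.astype(np.int64) * n + jj
        excl_keys, p14_keys, p14_qs, p14_ls = _packed_pair_tables(self.topology)
        if len(excl_keys):
            keep = ~np.isin(keys, excl_keys)
            ii, jj, keys = ii[keep], jj[keep], keys[keep]
        qs = np.ones(len(ii))
        ls = np.ones(len(ii))
        if len(p14_keys):
            pos = np.minimum(np.searchsorted(p14_keys, keys), len(p14_keys) - 1)
            hit = p14_keys[pos] == keys
            qs[hit] = p14_qs[pos[hit]]
            ls[hit] = p14_ls[pos[hit]]
        self._nb = (ii, jj, qs, ls)
        self._nb_coords = coords.copy()
        return self._nb

    def forces(self, coords: np.ndarray) -> np.ndarray:
        self.n_evaluations += 1
        a = self.arrs
        out = np.zeros_like(coords)
        if self.use_compiled:
            bonded_forces_kernel(
                coords, a["bond_idx"], a["bond_k"], a["bond_b0"],
                a["angle_idx"], a["angle_k"], a["angle_t0"],
                a["dih_idx"], a["dih_k"], a["dih_n"], self._dih_cosphase, out)
            if self.include_nonbonded:
                ii, jj, qs, ls = self._neighbour_pairs(coords)
                t = self.topology
                nonbonded_forces_kernel(
                    coords, ii, jj, qs, ls, t.charges, t.lj_sigma, t.lj_epsilon,
                    fd.COULOMB_CONSTANT, self.cutoff ** 2, out)
            return out
        for batch in (
            fd.bond_forces_batch(coords, a["bond_idx"], a["bond_k"], a["bond_b0"]),
            fd.angle_forces_batch(coords, a["angle_idx"], a["angle_k"], a["angle_t0"]),
            fd.dihedral_forces_batch(coords, a["dih_idx"], a["dih_k"], a["dih_n"],
                                     a["dih_phase"]),
        ):
            batch.accumulate_atom_forces(out)
        if self.include_nonbonded:
            ii, jj, qs, ls = self._neighbour_pairs(coords)
            if len(ii):
                rvec = coords[ii] - coords[jj]
                inside = np.einsum("ij,ij->i", rvec, rvec) <= self.cutoff ** 2
                t = self.topology
                coul, vdw = fd.nonbonded_forces_batch(
                    coords, ii[inside], jj[inside], t.charges, t.lj_sigma,
                    t.lj_epsilon, qs[inside], ls[inside])
                coul.accumulate_atom_forces(out)
                vdw.accumulate_atom_forces(out)
        return out

    def potential_energy(self, coords: np.ndarray) -> float:
        a = self.arrs
        e = (fd.bond_energy_batch(coords, a["bond_idx"], a["bond_k"], a["bond_b0"])
             + fd.angle_energy_batch(coords, a["angle_idx"], a["angle_k"], a["angle_t0"])
             + fd.dihedral_energy_batch(coords, a["dih_idx"], a["dih_k"], a["dih_n"],
                                        a["dih_phase"]))
        if self.include_nonbonded:
            ii, jj, qs, ls = self._neighbour_pairs(coords)
            if len(ii):
                rvec = coords[ii] - coords[jj]
                inside = np.einsum("ij,ij->i", rvec, rvec) <= self.cutoff ** 2
                t = self.topology
                ec, el = fd.nonbonded_energy_batch(
                    coords, ii[inside], jj[inside], t.charges, t.lj_sigma,
                    t.lj_epsilon, qs[inside], ls[inside])
                e += ec + el
        return e


def minimize_energy(state: MiniMDState, cutoff: float = 1.0,
                    include_nonbonded: bool = True, max_iterations: int = 500,
                    tol: float = 1e-8) -> MiniMDState:
    """Relax the structure with L-BFGS before pulse/heating experiments."""
    from scipy.optimize import minimize as _minimize

    ff = SystemForces(state.topology, cutoff=cutoff,
                      include_nonbonded=include_nonbonded)
    shape = state.coordinates.shape

    def fun(xflat):
        x = xflat.reshape(shape)
        return ff.potential_energy(x), -ff.forces(x).ravel()

    res = _minimize(fun, state.coordinates.ravel(), jac=True, method="L-BFGS-B",
                    tol=tol, options={"maxiter": max_iterations})
    return MiniMDState(state.topology, res.x.reshape(shape),
                       state.velocities.copy(),
                       state.restraint_reference, state.restraint_k)


def maxwell_velocities(masses: np.ndarray, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell–Boltzmann velocities at the given temperature, nm/ps."""
    sigma = np.sqrt(BOLTZMANN_KJ_MOL_K * temperature / np.asarray(masses))
    return rng.normal(size=(len(masses), 3)) * sigma[:, None]


def apply_velocity_pulse(state: MiniMDState, selection: np.ndarray,
                         velocity: np.ndarray | None = None,
                         radial_speed: float | None = None,
                         center: np.ndarray | None = None,
                         plane_normal: int = 2) -> MiniMDState:
    """Overwrite the velocities of selected atoms with a pulse.

    Either a fixed ``velocity`` vector (nm/ps; 1 km/s = 1 nm/ps) or a
    ``radial_speed`` directed outward in-plane from ``center``.  Atoms outside
    the selection are untouched.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty pulse selection")
    v = state.velocities.copy()
    if velocity is not None:
        v[selection] = np.asarray(velocity, dtype=float)
    elif radial_speed is not None:
        if center is None:
            center = state.coordinates[selection].mean(axis=0)
        radial = state.coordinates[selection] - center
        radial[:, plane_normal] = 0.0
        norms = np.linalg.norm(radial, axis=1)
        if np.any(norms <= 0):
            raise ValueError("pulse atom coincides with the radial center")
        v[selection] = radial / norms[:, None] * radial_speed
    else:
        raise ValueError("provide either velocity or radial_speed")
    return MiniMDState(state.topology, state.coordinates.copy(), v,
                       state.restraint_reference, state.restraint_k)


def nve_integrate(state: MiniMDState, dt: float, steps: int, stride: int,
                  cutoff: float = 1.0, include_nonbonded: bool = True,
                  record_energy: bool = False):
    """Velocity-Verlet NVE integration; snapshots every ``stride`` steps.

    Returns the list of frames (with velocities), and with
    ``record_energy=True`` also the total-energy series at snapshot times.
    The optional restraint force acts on the dynamics only.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ff = SystemForces(state.topology, cutoff=cutoff,
                      include_nonbonded=include_nonbonded)
    masses = state.topology.masses[:, None]
    x = state.coordinates.copy()
    v = state.velocities.copy()

    def total_force(xx):
        f = ff.forces(xx)
        if state.restraint_k > 0 and state.restraint_reference is not None:
            f = f - state.restraint_k * (xx - state.restraint_reference)
        return f

    def snapshot(t, xx, vv):
        frames.append(TrajectoryFrame(t, xx.copy(), vv.copy()))
        if record_energy:
            ke = 0.5 * float(np.sum(masses * vv * vv))
            energies.append(ke + ff.potential_energy(xx))

    f = total_force(x)
    if not np.all(np.isfinite(f)):
        raise IntegrationBlowupError("non-finite forces at step 0")
    frames: list[TrajectoryFrame] = []
    energies: list[float] = []
    snapshot(0.0, x, v)
    for step in range(1, steps + 1):
        v += 0.5 * dt * f / masses
        x += dt * v
        if not np.all(np.isfinite(x)):
            raise IntegrationBlowupError(f"non-finite coordinates at step {step}")
        f = total_force(x)
        v += 0.5 * dt * f / masses
        if step % stride == 0:
            snapshot(step * dt, x, v)
    if record_energy:
        return frames, np.array(energies)
    return frames
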