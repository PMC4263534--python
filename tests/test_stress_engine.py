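"""Stress assembly: volumes, pair enumeration, identities, sign convention."""

import numpy as np
import pytest

from atomstress.dynamics import maxwell_velocities
from atomstress.model_io import (AtomRecord, BondedTerm, ForceFieldTopology,
                                 TrajectoryFrame)
from atomstress.stress_engine import (ConfigurationError, StressOptions,
                                      characteristic_volumes,
                                      compute_trajectory_stress,
                                      enumerate_pairs, frame_atom_stress,
                                      kinetic_stress)
from atomstress.units import BOLTZMANN_KJ_MOL_K, KBAR_PER_KJ_MOL_NM3
from conftest import random_rotation


def _frame(entry, time=0.0, box=None, velocities=None):
    return TrajectoryFrame(time, entry.coordinates.copy(), velocities, box)


def _stress(entry, opts=None, frame=None):
    opts = opts or StressOptions(cutoff=100.0, carbon_volume=0.02)
    frame = frame or _frame(entry)
    vols = characteristic_volumes(entry.topology, frame, opts)
    return frame_atom_stress(frame, entry.topology, opts, vols)


# -- characteristic volumes -------------------------------------------------

def test_box_uniform_volumes():
    atoms = [AtomRecord(i, "X", 0, "R", 1.0, 0.0, 0.0, 0.0) for i in range(27)]
    top = ForceFieldTopology(atoms, [], set(), {})
    frame = TrajectoryFrame(0.0, np.zeros((27, 3)), box=np.array([3.0, 3.0, 3.0]))
    cv = characteristic_volumes(top, frame)
    assert cv.policy == "box_uniform"
    np.testing.assert_array_equal(cv.volumes, 1.0)
    assert cv.volumes.sum() == pytest.approx(27.0, rel=1e-15)


def test_no_box_carbon_fallback(catalog):
    entry = catalog["diatomic_stretched"]
    cv = characteristic_volumes(entry.topology, _frame(entry))
    assert cv.policy == "carbon_default"
    np.testing.assert_allclose(cv.volumes, 0.0206, atol=2e-4)


# -- pair enumeration -------------------------------------------------------

def test_cutoff_excludes_distant_nonbonded_but_not_bonds():
    atoms = [AtomRecord(i, "C", 0, "R", 12.0, 0.1, 0.3, 0.2) for i in range(2)]
    coords = np.array([[0.0, 0, 0], [1.2, 0, 0]])
    top_nb = ForceFieldTopology(atoms, [], set(), {})
    frame = TrajectoryFrame(0.0, coords)
    pl = enumerate_pairs(frame, top_nb, StressOptions(cutoff=1.0))
    assert len(pl.nb_i) == 0
    # with a bond term the bond pair is still evaluated (stress is nonzero)
    atoms = [AtomRecord(i, "C", 0, "R", 12.0, 0.0, 0.0, 0.0) for i in range(2)]
    top_b = ForceFieldTopology(
        atoms, [BondedTerm("bond", (0, 1), {"k_b": 1000.0, "b0": 0.1})],
        {(0, 1)}, {})
    vols = characteristic_volumes(top_b, frame, StressOptions())
    fs = frame_atom_stress(frame, top_b, StressOptions(cutoff=1.0), vols)
    assert np.all(np.abs(fs.terms["bond"]) > 0)


def test_pair_list_matches_brute_force_enumeration(rng):
    """KD-tree path (n > 200) equals the O(N²) reference, with and without box."""
    n = 300
    box = np.array([4.0, 4.0, 4.0])
    coords = rng.uniform(0, 4.0, size=(n, 3))
    atoms = [AtomRecord(i, "X", 0, "R", 1.0, 0.0, 0.1, 0.1) for i in range(n)]
    excl = {(0, 1), (5, 17)}
    p14 = {(2, 3): (0.8, 0.5)}
    top = ForceFieldTopology(atoms, [], excl, p14)
    for b in (box, None):
        frame = TrajectoryFrame(0.0, coords, box=b)
        pl = enumerate_pairs(frame, top, StressOptions(cutoff=1.0))
        got = set(zip(pl.nb_i.tolist(), pl.nb_j.tolist()))
        expected = set()
        for i in range(n):
            for j in range(i + 1, n):
                d = coords[i] - coords[j]
                if b is not None:
                    d = d - b * np.round(d / b)
                if np.dot(d, d) <= 1.0 and (i, j) not in excl:
                    expected.add((i, j))
        assert got == expected
        k = pl.nb_i.tolist().index(2) if (2, 3) in got else None
        if k is not None and pl.nb_j[k] == 3:
            assert (pl.q_scale[k], pl.lj_scale[k]) == (0.8, 0.5)


def test_cutoff_beyond_half_box_rejected():
    atoms = [AtomRecord(0, "X", 0, "R", 1.0, 0.0, 0.0, 0.0)]
    top = ForceFieldTopology(atoms, [], set(), {})
    frame = TrajectoryFrame(0.0, np.zeros((1, 3)), box=np.array([1.5, 3.0, 3.0]))
    with pytest.raises(ConfigurationError, match="half"):
        enumerate_pairs(frame, top, StressOptions(cutoff=1.0))


# -- worked example and sign convention ------------------------------------

def test_stretched_bond_worked_example(catalog):
    """(1/(6V))·r·f with V=0.02 nm³ → ±20 kJ/mol/nm³ = 0.3321 kbar tensile."""
    fs = _stress(catalog["diatomic_stretched"])
    np.testing.assert_allclose(fs.terms["bond"], 20.0 * KBAR_PER_KJ_MOL_NM3,
                               rtol=1e-12)
    np.testing.assert_allclose(fs.hydrostatic_pressure,
                               -20.0 * KBAR_PER_KJ_MOL_NM3, rtol=1e-12)
    assert np.allclose(fs.terms["bond"] * 1000, 332.10781, rtol=1e-6)


def test_sign_convention_stretch_vs_compress(catalog):
    stretched = _stress(catalog["diatomic_stretched"])
    assert np.all(stretched.hydrostatic_pressure < 0)  # tension
    entry = catalog["diatomic_stretched"]
    squeezed = TrajectoryFrame(0.0, np.array([[0.0, 0, 0], [0.08, 0, 0]]))
    fs = _stress(entry, frame=squeezed)
    assert np.all(fs.hydrostatic_pressure > 0)  # compression


def test_zero_stress_at_equilibria(catalog):
    for name in ("diatomic_equilibrium", "torsion_stationary", "lj_pair_minimum"):
        fs = _stress(catalog[name])
        assert np.abs(fs.total).max() < 1e-12, name


# -- identities -------------------------------------------------------------

def test_trace_additivity_and_pressure_identity(catalog):
    fs = _stress(catalog["five_atom_gb"])
    total = sum(fs.terms.values())
    np.testing.assert_allclose(fs.total, total, rtol=1e-15)
    np.testing.assert_array_equal(fs.hydrostatic_pressure, -fs.total)


def test_rotation_invariance(catalog, rng):
    entry = catalog["five_atom_gb"]
    fs0 = _stress(entry)
    R = random_rotation(rng)
    rotated = TrajectoryFrame(0.0, entry.coordinates @ R.T + [0.3, -1.0, 2.0])
    opts = StressOptions(cutoff=100.0, carbon_volume=0.02)
    vols = characteristic_volumes(entry.topology, rotated, opts)
    fs1 = frame_atom_stress(rotated, entry.topology, opts, vols)
    for term in fs0.terms:
        np.testing.assert_allclose(fs1.terms[term], fs0.terms[term], rtol=1e-9,
                                   atol=1e-12)


def test_volume_scaling_law(catalog):
    entry = catalog["five_atom_gb"]
    fs1 = _stress(entry, StressOptions(cutoff=100.0, carbon_volume=0.02))
    fs2 = _stress(entry, StressOptions(cutoff=100.0, carbon_volume=0.04))
    np.testing.assert_allclose(fs2.total, fs1.total / 2.0, rtol=1e-15)


def test_atom_order_permutation_invariance(catalog, rng):
    entry = catalog["five_atom_gb"]
    perm = rng.permutation(5)
    inv = np.argsort(perm)
    old = entry.topology
    atoms = []
    for new_i, old_i in enumerate(perm):
        a = old.atoms[old_i]
        atoms.append(AtomRecord(new_i, a.name, a.residue_id, a.residue_name,
                                a.mass, a.charge, a.lj_sigma, a.lj_epsilon,
                                a.gb_radius, a.gb_screen))
    terms = [BondedTerm(t.kind, tuple(int(inv[i]) for i in t.atom_indices),
                        dict(t.parameters)) for t in old.bonded_terms]
    excl = {(int(inv[i]), int(inv[j])) for i, j in old.exclusions}
    p14 = {(int(inv[i]), int(inv[j])): s for (i, j), s in old.pairs14.items()}
    permuted = ForceFieldTopology(atoms, terms, excl, p14)
    coords = entry.coordinates[perm]

    fs0 = _stress(entry)
    opts = StressOptions(cutoff=100.0, carbon_volume=0.02)
    frame = TrajectoryFrame(0.0, coords)
    vols = characteristic_volumes(permuted, frame, opts)
    fs1 = frame_atom_stress(frame, permuted, opts, vols)
    np.testing.assert_allclose(fs1.total, fs0.total[perm], rtol=1e-10, atol=1e-13)


# -- kinetic term -----------------------------------------------------------

def test_kinetic_stress_values_and_errors():
    atoms = [AtomRecord(0, "C", 0, "R", 12.0, 0.0, 0.0, 0.0)]
    top = ForceFieldTopology(atoms, [], set(), {})
    vols = characteristic_volumes(
        top, TrajectoryFrame(0.0, np.zeros((1, 3)), box=np.array([1.0, 1.0, 1.0])))
    still = TrajectoryFrame(0.0, np.zeros((1, 3)), np.zeros((1, 3)))
    assert kinetic_stress(still, top, vols)[0] == 0.0
    moving = TrajectoryFrame(0.0, np.zeros((1, 3)), np.array([[1.0, 0, 0]]))
    # −m v²/(3V) = −4 kJ/mol/nm³ → −4·16.6054 bar
    assert kinetic_stress(moving, top, vols)[0] == pytest.approx(
        -4.0 * KBAR_PER_KJ_MOL_NM3, rel=1e-12)
    no_vel = TrajectoryFrame(0.0, np.zeros((1, 3)))
    with pytest.raises(ConfigurationError, match="velocit"):
        kinetic_stress(no_vel, top, vols)


def _lj_gas(rng, n=100, L=5.0, eps=0.25, sigma=0.34, T=300.0):
    atoms = [AtomRecord(i, "Ar", i, "GAS", 39.948, 0.0, sigma, eps) for i in range(n)]
    top = ForceFieldTopology(atoms, [], set(), {})
    side = int(np.ceil(n ** (1 / 3)))
    grid = np.stack(np.meshgrid(*[np.arange(side)] * 3), -1).reshape(-1, 3)[:n]
    coords = (grid + 0.5) * (L / side) + rng.normal(scale=0.03, size=(n, 3))
    vel = maxwell_velocities(top.masses, T, rng)
    return top, TrajectoryFrame(0.0, coords, vel, np.array([L, L, L]))


def test_pressure_matches_independent_virial_formula(rng):
    """Mean atomic hydrostatic pressure ≡ the standard virial pressure."""
    top, frame = _lj_gas(rng)
    opts = StressOptions(cutoff=1.0, include_kinetic=True)
    vols = characteristic_volumes(top, frame, opts)
    fs = frame_atom_stress(frame, top, opts, vols)
    p_mean = float(fs.hydrostatic_pressure.mean())

    # independent virial evaluation written directly from the LJ formula
    n, L = top.n_atoms, 5.0
    coords, vel, box = frame.coordinates, frame.velocities, frame.box
    kin = np.sum(top.masses[:, None] * vel ** 2)
    virial = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            d = coords[i] - coords[j]
            d -= box * np.round(d / box)
            r2 = float(np.dot(d, d))
            if r2 > 1.0:
                continue
            sr6 = (0.34 ** 2 / r2) ** 3
            # r·f for the pair, with f the force on i
            virial += 24.0 * 0.25 * (2.0 * sr6 * sr6 - sr6)
    p_ref = (kin / 3.0 + virial / 3.0) / L ** 3 * KBAR_PER_KJ_MOL_NM3
    assert p_mean == pytest.approx(p_ref, rel=1e-6)


def test_ideal_gas_recovers_equation_of_state(rng):
    """Time-mean kinetic pressure of a noninteracting gas = N·k_B·T/V."""
    n, L, T, n_frames = 100, 5.0, 300.0, 400
    atoms = [AtomRecord(i, "Ar", i, "GAS", 39.948, 0.0, 0.0, 0.0) for i in range(n)]
    top = ForceFieldTopology(atoms, [], set(), {})
    frames = [
        TrajectoryFrame(float(k), rng.uniform(0, L, (n, 3)),
                        maxwell_velocities(top.masses, T, rng),
                        np.array([L, L, L]))
        for k in range(n_frames)
    ]
    ts = compute_trajectory_stress(top, frames, StressOptions(include_kinetic=True))
    p_frames = (-ts.total).mean(axis=1)
    p_expected = n * BOLTZMANN_KJ_MOL_K * T / L ** 3 * KBAR_PER_KJ_MOL_NM3
    sem = p_frames.std(ddof=1) / np.sqrt(n_frames)
    assert abs(p_frames.mean() - p_expected) < 3 * sem


def test_empty_trajectory_rejected(catalog):
    with pytest.raises(ConfigurationError):
        compute_trajectory_stress(catalog["five_atom_gb"].topology, [])
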