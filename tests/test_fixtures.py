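"""Fixture generators: catalog manifests, oracle, lattice builder, mini-MD."""

import math

import numpy as np
import pytest

from atomstress import fixtures as fx
from atomstress.dynamics import (IntegrationBlowupError, SystemForces,
                                 apply_velocity_pulse, maxwell_velocities,
                                 nve_integrate)
from atomstress.graphene import BuilderError, LatticeSpec, MiniMDState, build_graphene
from atomstress.model_io import TrajectoryFrame
from atomstress.stress_engine import (StressOptions, characteristic_volumes,
                                      frame_atom_stress)
from atomstress.waves import NoFrontError, measure_wavefront_speed


def test_catalog_is_deterministic(catalog):
    again = fx.build_test_structures()
    assert set(again) == set(catalog)
    for name in catalog:
        np.testing.assert_array_equal(again[name].coordinates,
                                      catalog[name].coordinates)


def test_catalog_manifests_predict_stress_terms(catalog):
    """Each entry's expected zero/nonzero stress terms hold in the engine."""
    opts = StressOptions(cutoff=100.0, carbon_volume=0.02)
    for name, entry in catalog.items():
        frame = TrajectoryFrame(0.0, entry.coordinates)
        vols = characteristic_volumes(entry.topology, frame, opts)
        fs = frame_atom_stress(frame, entry.topology, opts, vols)
        for term, arr in fs.terms.items():
            if term in entry.expect_nonzero:
                assert np.abs(arr).max() > 1e-10, (name, term)
            else:
                assert np.abs(arr).max() < 1e-9, (name, term)


def test_oracle_agrees_with_implementation_on_perturbed_catalog(catalog, rng):
    """Randomized perturbations of every entry: oracle vs analytic forces."""
    from atomstress.stress_engine import pair_batches_for_frame

    opts = StressOptions(cutoff=100.0)
    for name, entry in catalog.items():
        for _ in range(5):
            coords = entry.coordinates + rng.normal(scale=2e-3,
                                                    size=entry.coordinates.shape)
            oracle = fx.numerical_force_oracle(entry.topology, coords)
            impl = np.zeros_like(coords)
            frame = TrajectoryFrame(0.0, coords)
            for batch in pair_batches_for_frame(frame, entry.topology, opts):
                batch.accumulate_atom_forces(impl)
            atol = 2e-6 * np.abs(oracle).max() + 5e-8
            np.testing.assert_allclose(impl, oracle, rtol=0, atol=atol,
                                       err_msg=name)


def test_oracle_zero_interaction_system():
    from atomstress.model_io import AtomRecord, ForceFieldTopology

    top = ForceFieldTopology(
        [AtomRecord(i, "X", 0, "R", 1.0, 0.0, 0.0, 0.0) for i in range(3)], [],
        set(), {})
    f = fx.numerical_force_oracle(top, np.random.default_rng(0).normal(size=(3, 3)))
    np.testing.assert_array_equal(f, 0.0)


def test_oracle_stretched_diatomic_analytic(catalog):
    f = fx.numerical_force_oracle(catalog["diatomic_stretched"].topology,
                                  catalog["diatomic_stretched"].coordinates)
    np.testing.assert_allclose(f, [[20.0, 0, 0], [-20.0, 0, 0]], atol=1e-5)


# -- graphene builder -------------------------------------------------------

@pytest.mark.parametrize("edge", ["armchair", "zigzag"])
def test_ribbon_bond_lengths_and_coordination(edge):
    spec = LatticeSpec(edge_type=edge, width=2.5, length=3.0)
    st = build_graphene(spec)
    coords = st.coordinates
    bonds = st.topology.terms_of_kind("bond")
    for t in bonds:
        i, j = t.atom_indices
        assert np.linalg.norm(coords[i] - coords[j]) == pytest.approx(
            spec.bond_length, abs=1e-12)
    # interior atoms are 3-coordinated; angle count = Σ C(deg, 2)
    deg = np.zeros(st.topology.n_atoms, dtype=int)
    for t in bonds:
        deg[list(t.atom_indices)] += 1
    assert deg.max() == 3
    expected_angles = int(sum(d * (d - 1) // 2 for d in deg))
    assert len(st.topology.terms_of_kind("angle")) == expected_angles


def test_builder_deterministic():
    a = build_graphene(LatticeSpec(width=2.0, length=2.0))
    b = build_graphene(LatticeSpec(width=2.0, length=2.0))
    np.testing.assert_array_equal(a.coordinates, b.coordinates)
    assert [t.atom_indices for t in a.topology.bonded_terms] == \
        [t.atom_indices for t in b.topology.bonded_terms]


def test_nanotube_has_no_low_coordination_along_wrap():
    spec = LatticeSpec(edge_type="zigzag", width=2.5, length=3.0,
                       include_impropers=False)
    ribbon = build_graphene(spec)
    tube = build_graphene(spec, nanotube=True)

    def degrees(st):
        deg = np.zeros(st.topology.n_atoms, dtype=int)
        for t in st.topology.terms_of_kind("bond"):
            deg[list(t.atom_indices)] += 1
        return deg

    deg_t = degrees(tube)
    assert deg_t.min() >= 2  # only the open tube ends are under-coordinated
    # wrapped direction closes: strictly fewer under-coordinated atoms
    assert (deg_t < 3).sum() < (degrees(ribbon) < 3).sum()
    # tube is a proper cylinder: constant radius in the wrapped plane
    r = np.linalg.norm(tube.coordinates[:, 1:], axis=1)
    assert r.std() < 1e-9


def test_builder_rejects_tiny_sheets():
    with pytest.raises(BuilderError):
        build_graphene(LatticeSpec(width=0.3, length=3.0))


# -- velocity pulses --------------------------------------------------------

def test_velocity_pulse_units_and_radial_geometry():
    st = build_graphene(LatticeSpec(width=2.0, length=2.0))
    n = st.topology.n_atoms
    sel = np.arange(5)
    out = apply_velocity_pulse(st, sel, velocity=np.array([0.0, 0.0, 20.5]))
    np.testing.assert_array_equal(out.velocities[sel][:, 2], 20.5)  # km/s = nm/ps
    np.testing.assert_array_equal(out.velocities[5:], 0.0)  # untouched

    center = st.coordinates[sel].mean(axis=0)
    rad = apply_velocity_pulse(st, sel, radial_speed=10.0, center=center)
    for a in sel:
        v = rad.velocities[a]
        r = st.coordinates[a] - center
        r[2] = 0.0
        cross = np.cross(v, r)
        assert np.linalg.norm(cross) < 1e-9 * np.linalg.norm(r) * 10.0
        assert np.dot(v, r) > 0  # outward
        assert np.linalg.norm(v) == pytest.approx(10.0)

    with pytest.raises(ValueError, match="empty"):
        apply_velocity_pulse(st, np.array([], dtype=int), radial_speed=1.0)


# -- NVE integrator ---------------------------------------------------------

def _diatomic_state(catalog, stretch=0.12):
    entry = catalog["diatomic_stretched"]
    coords = np.array([[0.0, 0, 0], [stretch, 0, 0]])
    return MiniMDState(entry.topology, coords, np.zeros((2, 3)))


def test_harmonic_oscillator_period(catalog):
    """Period of a stretched diatomic matches 2π√(μ/k) within 0.1%."""
    state = _diatomic_state(catalog)
    mu = 12.011 / 2.0
    period = 2.0 * math.pi * math.sqrt(mu / 1000.0)
    dt = period / 2000.0
    frames = nve_integrate(state, dt, steps=int(10 * period / dt), stride=1,
                           include_nonbonded=False)
    sep = np.array([np.linalg.norm(f.coordinates[1] - f.coordinates[0])
                    for f in frames])
    # count maxima to measure the mean period
    peaks = [k for k in range(1, len(sep) - 1)
             if sep[k] >= sep[k - 1] and sep[k] > sep[k + 1]]
    times = np.array([frames[k].time for k in peaks])
    measured = np.diff(times).mean()
    assert measured == pytest.approx(period, rel=1e-3)


def test_energy_conservation(catalog):
    state = _diatomic_state(catalog)
    mu = 12.011 / 2.0
    period = 2.0 * math.pi * math.sqrt(mu / 1000.0)
    frames, energies = nve_integrate(state, period / 200.0, steps=10_000, stride=100,
                                     include_nonbonded=False, record_energy=True)
    drift = np.abs(energies - energies[0]).max() / abs(energies[0])
    assert drift < 1e-4


def test_static_at_energy_minimum(catalog):
    entry = catalog["diatomic_equilibrium"]
    state = MiniMDState(entry.topology, entry.coordinates.copy(), np.zeros((2, 3)))
    frames = nve_integrate(state, 1e-4, steps=100, stride=10,
                           include_nonbonded=False)
    for f in frames:
        np.testing.assert_allclose(f.coordinates, entry.coordinates, atol=1e-12)


def test_restraint_acts_on_dynamics_only(catalog):
    entry = catalog["diatomic_equilibrium"]
    shifted = entry.coordinates + np.array([0.05, 0.0, 0.0])
    state = MiniMDState(entry.topology, shifted.copy(), np.zeros((2, 3)),
                        restraint_reference=entry.coordinates.copy(),
                        restraint_k=100.0)
    frames = nve_integrate(state, 1e-3, steps=50, stride=50,
                           include_nonbonded=False)
    # restraint pulls the shifted copy back toward the reference
    d0 = np.linalg.norm(shifted - entry.coordinates)
    d1 = np.linalg.norm(frames[-1].coordinates - entry.coordinates)
    assert d1 < d0


def test_integration_blowup_detected(catalog):
    state = _diatomic_state(catalog)
    state.velocities[0] = [1e6, 0, 0]
    with pytest.raises((IntegrationBlowupError, FloatingPointError,
                        OverflowError)):
        nve_integrate(state, 10.0, steps=2000, stride=100, include_nonbonded=False)


def test_maxwell_velocities_temperature(rng):
    masses = np.full(2000, 12.0)
    v = maxwell_velocities(masses, 300.0, rng)
    from atomstress.units import BOLTZMANN_KJ_MOL_K
    ke = 0.5 * np.sum(masses[:, None] * v * v)
    expected = 1.5 * len(masses) * BOLTZMANN_KJ_MOL_K * 300.0
    assert ke == pytest.approx(expected, rel=0.1)


def test_compiled_and_numpy_forces_agree():
    st = build_graphene(LatticeSpec(width=2.0, length=2.0))
    rng = np.random.default_rng(3)
    coords = st.coordinates + rng.normal(scale=5e-3, size=st.coordinates.shape)
    f_np = SystemForces(st.topology, use_compiled=False).forces(coords)
    f_nb = SystemForces(st.topology, use_compiled=True).forces(coords)
    np.testing.assert_allclose(f_nb, f_np, rtol=0,
                               atol=1e-9 * max(1.0, np.abs(f_np).max()))


# -- wavefront measurement --------------------------------------------------

def _synthetic_front(speed=10.0, n_atoms=400, n_frames=12):
    rng = np.random.default_rng(6)
    coords = rng.uniform(-10, 10, size=(n_atoms, 3))
    coords[:, 2] = 0.0
    times = 0.05 * np.arange(n_frames)
    values = []
    r = np.linalg.norm(coords[:, :2], axis=1)
    for t in times:
        front = speed * t
        values.append(np.where(r <= front, 1.0, 0.0))
    return times, [coords] * n_frames, values


def test_synthetic_front_speed_exact():
    times, coords, values = _synthetic_front(speed=10.0)
    fit = measure_wavefront_speed(times, coords, values, np.zeros(3))
    assert fit.speed_km_s == pytest.approx(10.0, rel=0.05)
    assert fit.r_squared > 0.99


def test_threshold_robustness():
    times, coords, values = _synthetic_front(speed=10.0)
    s = [measure_wavefront_speed(times, coords, values, np.zeros(3),
                                 threshold_fraction=f).speed_km_s
         for f in (0.2, 0.3)]
    assert abs(s[0] - s[1]) / s[1] < 0.05


def test_static_field_has_no_front():
    times = np.arange(6.0)
    coords = [np.zeros((4, 3))] * 6
    values = [np.zeros(4)] * 6
    with pytest.raises(NoFrontError):
        measure_wavefront_speed(times, coords, values, np.zeros(3))
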