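"""End-to-end stress-wave experiments on graphene sheets.

Protocol, mirroring hypervelocity-impact simulations on ultra-cold graphene:
build an armchair sheet of aromatic carbon, energy-minimize it, draw 1 K
Maxwell–Boltzmann velocities (seeded), overwrite the velocities of a central
atom cluster with a hypervelocity pulse (radially outward in-plane for the
longitudinal experiment, out-of-plane for the transverse one), integrate NVE
at 0.05 fs steps with a weak position restraint (excluded from all stress
terms), and track the front of the baseline-subtracted tensile stress field,
or of the out-of-plane displacement field, versus time.

Front detection operates on the *change* of each field relative to the
initial minimized frame: a relaxed ribbon still carries static edge stress
that would otherwise capture the adaptive threshold once the pulse has
spread thin.  Frames whose front radius exceeds 90% of the sheet half-width
are excluded from the fit — after the front touches the boundary,
reflections break the linear radius–time model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import (apply_velocity_pulse, maxwell_velocities,
                       minimize_energy, nve_integrate)
from .graphene import LatticeSpec, MiniMDState, build_graphene
from .stress_engine import StressOptions, compute_trajectory_stress
from .units import KCAL_TO_KJ
from .waves import WavefrontFit, measure_wavefront_speed

__all__ = ["WaveExperimentResult", "graphene_wave_speeds"]

# weak positional restraint holding the sheet in place, 0.1 kcal/mol/Å²
RESTRAINT_K = 0.1 * KCAL_TO_KJ * 100  # kJ/mol/nm²


@dataclass
class WaveExperimentResult:
    longitudinal: WavefrontFit   # in-plane pulse, tensile stress front
    transverse: WavefrontFit     # out-of-plane pulse, displacement front
    n_atoms: int
    sheet_size: float            # nm


def _prepare_sheet(size: float, temperature: float, rng: np.random.Generator):
    spec = LatticeSpec(edge_type="armchair", width=size, length=size)
    state = build_graphene(spec)
    state = minimize_energy(state)
    ref = state.coordinates.copy()
    vel = maxwell_velocities(state.topology.masses, temperature, rng)
    return MiniMDState(state.topology, ref, vel, ref.copy(), RESTRAINT_K), ref


def graphene_wave_speeds(size: float = 8.0, pulse_speed: float = 20.5,
                         cluster_size: int = 10, dt: float = 5e-5,
                         longitudinal_time: float = 0.45,
                         transverse_time: float = 0.9,
                         snapshot_stride: int = 200,
                         temperature: float = 1.0,
                         threshold_fraction: float = 0.25,
                         seed: int = 1) -> WaveExperimentResult:
    """Run both pulse experiments and fit the two front speeds (km/s).

    Defaults are the study conditions: ~8×8 nm armchair sheet, 20.5 km/s
    pulse on the central ~10 atoms, 0.05 fs steps, snapshots every 10 fs,
    1 K pre-thermalization.
    """
    rng = np.random.default_rng(seed)
    state, ref = _prepare_sheet(size, temperature, rng)
    half = 0.5 * size
    cap = 0.9 * half
    dist = np.linalg.norm(ref[:, :2], axis=1)
    cluster = np.argsort(dist)[:cluster_size]
    center = ref[cluster].mean(axis=0)
    center[2] = 0.0
    options = StressOptions(cutoff=1.0)

    # longitudinal: radial in-plane pulse, tensile (positive Δstress) front
    pulsed = apply_velocity_pulse(state, cluster, radial_speed=pulse_speed,
                                  center=center)
    frames = nve_integrate(pulsed, dt, int(round(longitudinal_time / dt)),
                           snapshot_stride)
    stress = compute_trajectory_stress(state.topology, frames, options)
    tensile = [np.maximum(stress.total[k] - stress.total[0], 0.0)
               for k in range(len(frames))]
    fit_l = measure_wavefront_speed(
        stress.times, [f.coordinates for f in frames], tensile, center,
        threshold_fraction=threshold_fraction, max_radius=cap)

    # transverse: out-of-plane pulse, |z displacement| front
    pulsed = apply_velocity_pulse(
        state, cluster, velocity=np.array([0.0, 0.0, pulse_speed]))
    frames = nve_integrate(pulsed, dt, int(round(transverse_time / dt)),
                           snapshot_stride)
    displacement = [np.abs(f.coordinates[:, 2] - ref[:, 2]) for f in frames]
    times = np.array([f.time for f in frames])
    fit_t = measure_wavefront_speed(
        times, [f.coordinates for f in frames], displacement, center,
        threshold_fraction=threshold_fraction, max_radius=cap)

    return WaveExperimentResult(fit_l, fit_t, state.topology.n_atoms, size)
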