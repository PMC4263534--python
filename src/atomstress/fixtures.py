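"""Analytic micro-structures and an independent finite-difference force oracle.

The catalog of 1–5-atom systems exercises every potential term at geometries
where the expected stresses are known by hand (equilibria, stationary points,
simple stretched configurations).  The oracle evaluates total term energies
with plain scalar loops — deliberately sharing no code with the vectorised
pairwise-decomposition kernels — and differentiates them by central
differences, providing the reference the analytic forces are validated
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gb_solvation import GBParams
from .model_io import AtomRecord, BondedTerm, ForceFieldTopology
from .units import COULOMB_CONSTANT

__all__ = ["FixtureEntry", "build_test_structures", "oracle_energy",
           "numerical_force_oracle", "born_radii_oracle", "gb_energy_oracle",
           "OracleFailure"]

ALL_ORACLE_TERMS = ("bond", "angle", "dihedral", "coulomb", "vdw", "gb")


class OracleFailure(RuntimeError):
    """Energy became non-finite at a displaced oracle point."""


@dataclass
class FixtureEntry:
    name: str
    topology: ForceFieldTopology
    coordinates: np.ndarray
    velocities: np.ndarray | None = None
    # manifest of which stress terms are expected nonzero at this geometry
    expect_nonzero: set[str] = field(default_factory=set)
    notes: str = ""


def _atom(i, name="C", resid=0, resname="FIX", mass=12.011, charge=0.0,
          sigma=0.0, eps=0.0, gbr=None, gbs=None) -> AtomRecord:
    return AtomRecord(i, name, resid, resname, mass, charge, sigma, eps, gbr, gbs)


def build_test_structures() -> dict[str, FixtureEntry]:
    """Deterministic, seed-free catalog of validation structures."""
    cat: dict[str, FixtureEntry] = {}

    def add(entry: FixtureEntry) -> None:
        cat[entry.name] = entry

    bond = lambda i, j, k=1000.0, b0=0.1: BondedTerm("bond", (i, j), {"k_b": k, "b0": b0})

    # -- diatomics ---------------------------------------------------------
    top = ForceFieldTopology([_atom(0), _atom(1)], [bond(0, 1)], {(0, 1)}, {})
    add(FixtureEntry("diatomic_equilibrium", top,
                     np.array([[0.0, 0, 0], [0.1, 0, 0]]),
                     expect_nonzero=set(), notes="bond at b0: all stresses zero"))
    top = ForceFieldTopology([_atom(0), _atom(1)], [bond(0, 1)], {(0, 1)}, {})
    add(FixtureEntry("diatomic_stretched", top,
                     np.array([[0.0, 0, 0], [0.12, 0, 0]]),
                     expect_nonzero={"bond"},
                     notes="k=1000, b0=0.1, r=0.12: |f|=20 kJ/mol/nm, tensile"))

    # -- angle -------------------------------------------------------------
    th = math.radians(120.0)
    top = ForceFieldTopology(
        [_atom(0), _atom(1), _atom(2)],
        [BondedTerm("angle", (0, 1, 2),
                    {"k_theta": 400.0, "theta0": math.radians(104.5)})],
        {(0, 1), (1, 2), (0, 2)}, {},
    )
    add(FixtureEntry("triatomic_bent", top,
                     np.array([[0.1, 0, 0], [0.0, 0, 0],
                               [0.1 * math.cos(th), 0.1 * math.sin(th), 0]]),
                     expect_nonzero={"angle"},
                     notes="water-like angle off equilibrium"))

    # -- torsions ----------------------------------------------------------
    def torsion_coords(phi: float) -> np.ndarray:
        # i–j–k–l with unit-ish geometry; φ measured about the j–k axis
        return np.array([
            [0.1 * math.cos(phi), 0.1 * math.sin(phi), 0.1],
            [0.0, 0.0, 0.1],
            [0.0, 0.0, 0.0],
            [0.1, 0.0, 0.0],
        ])

    dihedral_term = lambda k, n, ph: BondedTerm(
        "dihedral", (0, 1, 2, 3), {"k_phi": k, "multiplicity": n, "phase": ph})
    excl4 = {(0, 1), (1, 2), (2, 3), (0, 2), (1, 3), (0, 3)}
    atoms4 = lambda: [_atom(i) for i in range(4)]
    top = ForceFieldTopology(atoms4(), [dihedral_term(5.0, 3, 0.0)], excl4, {})
    add(FixtureEntry("torsion_stationary", top, torsion_coords(math.radians(60.0)),
                     expect_nonzero=set(),
                     notes="n=3, φs=0, φ=60°: potential minimum, zero forces"))
    top = ForceFieldTopology(atoms4(), [dihedral_term(5.0, 2, math.pi)], excl4, {})
    add(FixtureEntry("torsion_generic", top, torsion_coords(math.radians(35.0)),
                     expect_nonzero={"dihedral"}))
    top = ForceFieldTopology(atoms4(), [dihedral_term(5.0, 2, math.pi)], excl4, {})
    add(FixtureEntry("torsion_planar", top, torsion_coords(0.0),
                     expect_nonzero=set(),
                     notes="φ=0 with n=2, φs=π: a stationary point; the contract "
                           "is finiteness (no sine-ratio blow-up), forces are zero"))

    # -- nonbonded pairs ---------------------------------------------------
    top = ForceFieldTopology([_atom(0, charge=1.0), _atom(1, charge=-1.0)], [], set(), {})
    add(FixtureEntry("charged_pair", top, np.array([[0.0, 0, 0], [0.3, 0, 0]]),
                     expect_nonzero={"coulomb"}))
    sig, eps = 0.34, 0.36
    rmin = 2.0 ** (1.0 / 6.0) * sig
    top = ForceFieldTopology([_atom(0, sigma=sig, eps=eps), _atom(1, sigma=sig, eps=eps)],
                             [], set(), {})
    add(FixtureEntry("lj_pair_minimum", top, np.array([[0.0, 0, 0], [rmin, 0, 0]]),
                     expect_nonzero=set(), notes="r = 2^(1/6)σ: zero LJ force"))
    top = ForceFieldTopology([_atom(0, sigma=sig, eps=eps), _atom(1, sigma=sig, eps=eps)],
                             [], set(), {})
    add(FixtureEntry("lj_pair_compressed", top, np.array([[0.0, 0, 0], [0.3, 0, 0]]),
                     expect_nonzero={"vdw"}))

    # -- 5-atom combined system with GB ------------------------------------
    atoms5 = [
        _atom(0, "N", 0, "GBX", 14.007, -0.4, 0.325, 0.71, 0.155, 0.79),
        _atom(1, "C", 0, "GBX", 12.011, 0.1, 0.34, 0.36, 0.17, 0.72),
        _atom(2, "O", 0, "GBX", 15.999, -0.5, 0.296, 0.88, 0.15, 0.85),
        _atom(3, "H", 1, "GBY", 1.008, 0.3, 0.107, 0.066, 0.12, 0.85),
        _atom(4, "C", 1, "GBY", 12.011, 0.5, 0.34, 0.36, 0.17, 0.72),
    ]
    terms5 = [
        BondedTerm("bond", (0, 1), {"k_b": 30000.0, "b0": 0.145}),
        BondedTerm("bond", (1, 2), {"k_b": 40000.0, "b0": 0.123}),
        BondedTerm("angle", (0, 1, 2), {"k_theta": 500.0, "theta0": math.radians(120.0)}),
        BondedTerm("dihedral", (3, 0, 1, 2),
                   {"k_phi": 8.0, "multiplicity": 2, "phase": math.pi}),
        BondedTerm("bond", (0, 3), {"k_b": 35000.0, "b0": 0.101}),
    ]
    excl5 = {(0, 1), (1, 2), (0, 2), (0, 3), (1, 3), (3, 2)}
    pairs5 = {(3, 4): (1.0 / 1.2, 0.5)}
    coords5 = np.array([
        [0.000, 0.000, 0.000],
        [0.150, 0.010, -0.020],
        [0.260, 0.110, 0.030],
        [-0.070, 0.080, 0.050],
        [0.120, -0.250, 0.160],
    ])
    top = ForceFieldTopology(atoms5, terms5, excl5, pairs5)
    add(FixtureEntry("five_atom_gb", top, coords5,
                     expect_nonzero={"bond", "angle", "dihedral", "coulomb", "vdw", "gb"},
                     notes="combined 5-atom validation structure with GB parameters"))
    return cat


# ---------------------------------------------------------------------------
# independent scalar-loop energy oracle
# ---------------------------------------------------------------------------

def _dist(coords, i, j) -> float:
    return math.sqrt(sum((coords[i][d] - coords[j][d]) ** 2 for d in range(3)))


def oracle_energy(topology: ForceFieldTopology, coords: np.ndarray,
                  terms=ALL_ORACLE_TERMS, gb_params: GBParams | None = None,
                  cutoff: float = math.inf) -> float:
    """Total energy of the selected term kinds, evaluated with scalar loops."""
    coords = np.asarray(coords, dtype=float)
    e = 0.0
    for t in topology.bonded_terms:
        if t.kind == "bond" and "bond" in terms:
            i, j = t.atom_indices
            b = _dist(coords, i, j)
            e += 0.5 * t.parameters["k_b"] * (b - t.parameters["b0"]) ** 2
        elif t.kind == "angle" and "angle" in terms:
            i, j, k = t.atom_indices
            v1 = coords[i] - coords[j]
            v2 = coords[k] - coords[j]
            ct = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            theta = math.acos(max(-1.0, min(1.0, ct)))
            e += 0.5 * t.parameters["k_theta"] * (theta - t.parameters["theta0"]) ** 2
        elif t.kind == "dihedral" and "dihedral" in terms:
            i, j, k, l = t.atom_indices
            b1 = coords[j] - coords[i]
            b2 = coords[k] - coords[j]
            b3 = coords[l] - coords[k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            cphi = float(np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
            phi = math.acos(max(-1.0, min(1.0, cphi)))
            n = int(t.parameters["multiplicity"])
            e += t.parameters["k_phi"] * (
                1.0 + math.cos(n * phi - t.parameters["phase"])
            )
    if "coulomb" in terms or "vdw" in terms:
        n = topology.n_atoms
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in topology.exclusions:
                    continue
                r = _dist(coords, i, j)
                if r > cutoff:
                    continue
                qs, ls = topology.pairs14.get((i, j), (1.0, 1.0))
                ai, aj = topology.atoms[i], topology.atoms[j]
                if "coulomb" in terms:
                    e += qs * COULOMB_CONSTANT * ai.charge * aj.charge / r
                if "vdw" in terms:
                    sig = 0.5 * (ai.lj_sigma + aj.lj_sigma)
                    epsi = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
                    sr6 = (sig / r) ** 6
                    e += ls * 4.0 * epsi * (sr6 * sr6 - sr6)
    if "gb" in terms and topology.has_gb and any(a.charge != 0 for a in topology.atoms):
        e += gb_energy_oracle(topology, coords, gb_params or GBParams())
    if not math.isfinite(e):
        raise OracleFailure("non-finite oracle energy")
    return e


def numerical_force_oracle(topology: ForceFieldTopology, coords: np.ndarray,
                           terms=ALL_ORACLE_TERMS, step: float = 1e-6,
                           gb_params: GBParams | None = None) -> np.ndarray:
    """Central-difference forces −∂E/∂r of the oracle energy, kJ/mol/nm."""
    coords = np.asarray(coords, dtype=float)
    forces = np.zeros_like(coords)
    for a in range(coords.shape[0]):
        for d in range(3):
            plus = coords.copy()
            minus = coords.copy()
            plus[a, d] += step
            minus[a, d] -= step
            ep = oracle_energy(topology, plus, terms, gb_params)
            em = oracle_energy(topology, minus, terms, gb_params)
            forces[a, d] = -(ep - em) / (2.0 * step)
    return forces


# ---------------------------------------------------------------------------
# brute-force GB oracle (direct summation, scalar loops, no neighbor lists)
# ---------------------------------------------------------------------------

def born_radii_oracle(topology: ForceFieldTopology, coords: np.ndarray,
                      params: GBParams | None = None) -> np.ndarray:
    """Direct-summation OBC Born radii."""
    params = params or GBParams()
    coords = np.asarray(coords, dtype=float)
    n = topology.n_atoms
    radii = [a.gb_radius for a in topology.atoms]
    screens = [a.gb_screen for a in topology.atoms]
    out = np.empty(n)
    for i in range(n):
        rho_i = radii[i] - params.offset
        integral = 0.0
        for j in range(n):
            if j == i:
                continue
            r = _dist(coords, i, j)
            if r > params.cutoff:
                continue
            sr = screens[j] * (radii[j] - params.offset)
            if rho_i >= r + sr:
                continue
            upper = r + sr
            lower = max(rho_i, abs(r - sr))
            term = (1.0 / lower - 1.0 / upper
                    + 0.25 * (r - sr * sr / r) * (1.0 / upper ** 2 - 1.0 / lower ** 2)
                    + 0.5 / r * math.log(lower / upper))
            if sr > r + rho_i:
                term += 2.0 * (1.0 / rho_i - 1.0 / lower)
            integral += 0.5 * term
        psi = integral * rho_i
        w = (params.obc_alpha * psi - params.obc_beta * psi ** 2
             + params.obc_gamma * psi ** 3)
        out[i] = 1.0 / (1.0 / rho_i - math.tanh(w) / radii[i])
    return out


def gb_energy_oracle(topology: ForceFieldTopology, coords: np.ndarray,
                     params: GBParams | None = None) -> float:
    """Direct-summation Still energy over the oracle Born radii."""
    params = params or GBParams()
    R = born_radii_oracle(topology, coords, params)
    q = [a.charge for a in topology.atoms]
    tau = 1.0 / params.dielectric_solute - 1.0 / params.dielectric_solvent
    e = 0.0
    n = topology.n_atoms
    for i in range(n):
        e += -COULOMB_CONSTANT * tau * 0.5 * q[i] * q[i] / R[i]
        for j in range(i + 1, n):
            r = _dist(coords, i, j)
            if r > params.cutoff:
                continue
            u = R[i] * R[j]
            fgb = math.sqrt(r * r + u * math.exp(-r * r / (4.0 * u)))
            e += -COULOMB_CONSTANT * tau * q[i] * q[j] / fgb
    return e
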