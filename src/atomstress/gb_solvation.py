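"""Generalized Born (OBC) implicit solvation: radii, energy, pairwise stress.

The model is the Onufriev–Bashford–Case variant of generalized Born theory.
Effective Born radii come from Hawkins–Cramer–Truhlar pairwise descreening
integrals rescaled through a tanh correction:

    ρ̃_i = ρ_i − offset
    Ψ_i  = ρ̃_i · Σ_j H(r_ij; ρ̃_i, S_j·ρ̃_j)
    R_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹ · tanh(αΨ_i − βΨ_i² + γΨ_i³)

with OBC-II coefficients α, β, γ = 1.0, 0.8, 4.85 and offset 0.009 nm by
default.  The polar solvation energy is the Still pairwise expression

    G = −f·(1/ε_in − 1/ε_solv)·[ Σ_{i<j} q_i q_j / f_GB + ½ Σ_i q_i²/R_i ]
    f_GB(r, R_i, R_j) = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j)))

so a single ion recovers the Born self-energy −f·(1/ε_in − 1/ε_solv)·q²/(2R).

For stress attribution the full gradient of G — including the chain-rule paths
through every Born radius — is folded into *central* pairwise forces: each
∂G/∂R_k·∂R_k/∂r_kl contribution is assigned to the pair (k, l) whose distance
appears in the descreening integral.  Per-atom sums of these pair forces equal
−∇G exactly (to numerical precision); per-pair values are one valid central
decomposition among several.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .force_decomposition import DegenerateGeometryError, PairBatch, _empty_batch
from .units import COULOMB_CONSTANT

__all__ = ["GBParams", "BornRadiiResult", "compute_born_radii", "gb_energy",
           "gb_pairwise_stress", "GBParameterError"]


class GBParameterError(ValueError):
    """Invalid or missing GB parameters."""


@dataclass
class GBParams:
    dielectric_solvent: float = 80.0
    dielectric_solute: float = 1.0
    offset: float = 0.009           # nm
    obc_alpha: float = 1.0
    obc_beta: float = 0.8
    obc_gamma: float = 4.85
    cutoff: float = np.inf          # nm, pair cutoff for descreening and energy

    def __post_init__(self) -> None:
        if not self.dielectric_solvent > self.dielectric_solute >= 1.0:
            raise GBParameterError(
                "require dielectric_solvent > dielectric_solute >= 1"
            )

    @property
    def tau(self) -> float:
        """1/ε_in − 1/ε_solv (polarity prefactor)."""
        return 1.0 / self.dielectric_solute - 1.0 / self.dielectric_solvent


@dataclass
class BornRadiiResult:
    born_radius: np.ndarray  # nm
    psi: np.ndarray          # dimensionless Ψ entering the tanh


# ---------------------------------------------------------------------------
# HCT descreening integral and its r-derivative
# ---------------------------------------------------------------------------

def _hct_terms(r: np.ndarray, rho: np.ndarray, sr: np.ndarray,
               want_derivative: bool = False):
    """HCT pair descreening H(r; ρ̃_i, S_j ρ̃_j) and optionally dH/dr.

    ``rho`` is the offset radius of the *descreened* atom i, ``sr`` the scaled
    offset radius of the descreening atom j.  Vectorised over pairs.
    """
    H = np.zeros_like(r)
    dH = np.zeros_like(r) if want_derivative else None

    active = r + sr > rho  # otherwise j is engulfed by i: no descreening
    if not np.any(active):
        return H, dH
    ra, rhoa, sra = r[active], rho[active], sr[active]

    U = ra + sra
    d = ra - sra
    absd = np.abs(d)
    use_rho = rhoa > absd
    L = np.where(use_rho, rhoa, absd)
    dL = np.where(use_rho, 0.0, np.sign(d))

    invL, invU = 1.0 / L, 1.0 / U
    term_r = ra - sra * sra / ra
    base = (invL - invU
            + 0.25 * term_r * (invU * invU - invL * invL)
            + 0.5 / ra * np.log(L / U))
    inside = sra > ra + rhoa  # atom i lies inside j's descreening sphere
    corr = np.where(inside, 2.0 * (1.0 / rhoa - invL), 0.0)
    H[active] = 0.5 * (base + corr)

    if want_derivative:
        dbase = (-dL * invL * invL + invU * invU
                 + 0.25 * (1.0 + sra * sra / (ra * ra)) * (invU * invU - invL * invL)
                 + 0.25 * term_r * (-2.0 * invU ** 3 + 2.0 * dL * invL ** 3)
                 - 0.5 / (ra * ra) * np.log(L / U)
                 + 0.5 / ra * (dL * invL - invU))
        dcorr = np.where(inside, 2.0 * dL * invL * invL, 0.0)
        dH[active] = 0.5 * (dbase + dcorr)
    return H, dH


def _pair_arrays(coords: np.ndarray, cutoff: float):
    """Upper-triangle pair list within cutoff; errors on coincident atoms."""
    n = len(coords)
    ii, jj = np.triu_indices(n, k=1)
    rvec = coords[ii] - coords[jj]
    r = np.linalg.norm(rvec, axis=1)
    if np.any(r <= 0):
        raise DegenerateGeometryError("overlapping identical coordinates in GB system")
    if np.isfinite(cutoff):
        keep = r <= cutoff
        ii, jj, rvec, r = ii[keep], jj[keep], rvec[keep], r[keep]
    return ii, jj, rvec, r


def compute_born_radii(coords: np.ndarray, gb_radii: np.ndarray,
                       gb_screens: np.ndarray, params: GBParams) -> BornRadiiResult:
    """OBC effective Born radii for all atoms."""
    coords = np.asarray(coords, dtype=float)
    gb_radii = np.asarray(gb_radii, dtype=float)
    if np.any(gb_radii <= params.offset):
        bad = np.nonzero(gb_radii <= params.offset)[0]
        raise GBParameterError(f"gb_radius <= offset for atoms {bad.tolist()}")
    rho = gb_radii - params.offset
    n = len(coords)
    I = np.zeros(n)
    if n > 1:
        ii, jj, _, r = _pair_arrays(coords, params.cutoff)
        # descreening acts both ways with each atom's own ρ̃ and the partner's S·ρ̃
        h_ij, _ = _hct_terms(r, rho[ii], gb_screens[jj] * rho[jj])
        h_ji, _ = _hct_terms(r, rho[jj], gb_screens[ii] * rho[ii])
        np.add.at(I, ii, h_ij)
        np.add.at(I, jj, h_ji)
    psi = I * rho
    w = params.obc_alpha * psi - params.obc_beta * psi ** 2 + params.obc_gamma * psi ** 3
    inv_R = 1.0 / rho - np.tanh(w) / gb_radii
    R = 1.0 / inv_R
    if not np.all(np.isfinite(R)) or np.any(R <= 0):
        raise GBParameterError("non-finite or non-positive Born radius")
    return BornRadiiResult(R, psi)


def _fgb(r2: np.ndarray, RiRj: np.ndarray):
    expo = np.exp(-r2 / (4.0 * RiRj))
    f = np.sqrt(r2 + RiRj * expo)
    return f, expo


def gb_energy(coords: np.ndarray, charges: np.ndarray,
              born_radii: np.ndarray, params: GBParams) -> float:
    """Still-type polar solvation energy, kJ/mol (self terms included)."""
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    R = np.asarray(born_radii, dtype=float)
    if not (len(coords) == len(charges) == len(R)):
        raise ValueError("coords, charges, born_radii must have equal lengths")
    pref = -COULOMB_CONSTANT * params.tau
    energy = pref * 0.5 * float(np.sum(charges * charges / R))
    if len(coords) > 1:
        ii, jj, _, r = _pair_arrays(coords, params.cutoff)
        f, _ = _fgb(r * r, R[ii] * R[jj])
        energy += pref * float(np.sum(charges[ii] * charges[jj] / f))
    return energy


def gb_pairwise_stress(coords: np.ndarray, charges: np.ndarray,
                       gb_radii: np.ndarray, gb_screens: np.ndarray,
                       params: GBParams) -> PairBatch:
    """Central pairwise GB forces whose per-atom sums equal −∇G.

    Combines the direct ∂G/∂r_ij term with all Born-radius chain-rule terms
    ∂G/∂R_k · ∂R_k/∂Ψ_k · ∂Ψ_k/∂r_kl, each attributed to the pair whose
    distance it differentiates.
    """
    coords = np.asarray(coords, dtype=float)
    charges = np.asarray(charges, dtype=float)
    n = len(coords)
    if np.all(charges == 0.0) or n < 2:
        return _empty_batch("gb")

    radii_res = compute_born_radii(coords, gb_radii, gb_screens, params)
    R, psi = radii_res.born_radius, radii_res.psi
    rho = np.asarray(gb_radii, dtype=float) - params.offset
    screens = np.asarray(gb_screens, dtype=float)
    pref = -COULOMB_CONSTANT * params.tau

    ii, jj, rvec, r = _pair_arrays(coords, params.cutoff)
    r2 = r * r
    RiRj = R[ii] * R[jj]
    f, expo = _fgb(r2, RiRj)
    qq = charges[ii] * charges[jj]

    # ∂G/∂R_k: pair terms + self terms
    dG_dR = np.zeros(n)
    dfgb_du = expo * (1.0 + r2 / (4.0 * RiRj)) / (2.0 * f)  # u = R_i R_j
    common = pref * qq * (-1.0 / (f * f)) * dfgb_du
    np.add.at(dG_dR, ii, common * R[jj])
    np.add.at(dG_dR, jj, common * R[ii])
    dG_dR += pref * 0.5 * charges * charges * (-1.0 / (R * R))

    # dR_k/dI_k through the tanh rescaling
    w = params.obc_alpha * psi - params.obc_beta * psi ** 2 + params.obc_gamma * psi ** 3
    dw_dpsi = params.obc_alpha - 2.0 * params.obc_beta * psi + 3.0 * params.obc_gamma * psi ** 2
    sech2 = 1.0 / np.cosh(w) ** 2
    dR_dI = (R * R) * sech2 * dw_dpsi * rho / np.asarray(gb_radii, dtype=float)

    # direct distance derivative of the pair energy
    dfgb_dr = (r / f) * (1.0 - 0.25 * expo)
    dE_dr = pref * qq * (-1.0 / (f * f)) * dfgb_dr

    # chain terms: dI_i/dr_ij and dI_j/dr_ij
    _, dh_ij = _hct_terms(r, rho[ii], screens[jj] * rho[jj], want_derivative=True)
    _, dh_ji = _hct_terms(r, rho[jj], screens[ii] * rho[ii], want_derivative=True)
    dE_dr = dE_dr + dG_dR[ii] * dR_dI[ii] * dh_ij + dG_dR[jj] * dR_dI[jj] * dh_ji

    force_on_i = (-dE_dr / r)[:, None] * rvec
    return PairBatch(ii, jj, rvec, force_on_i, "gb")
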