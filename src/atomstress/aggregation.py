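"""Residue averaging and time statistics for stress series.

Per snapshot, the residue-averaged stress is the arithmetic mean of the
residue's atomic stresses.  Over time, each series is summarised by its mean,
its mean square fluctuation (MSF, population-normalised 1/N_s), and the
standard error of the mean corrected for autocorrelation through the
statistical inefficiency g (sample variance, 1/(N_s−1), inside the SEM).
Between-condition difference maps combine the two SEMs in quadrature.

Caveat: residue-averaged stresses are reported in each residue's raw
(unshifted) frame; their sum does not reconstruct the system virial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .stress_engine import TrajectoryStress

__all__ = [
    "ResidueStressSeries",
    "StressSummary",
    "residue_average",
    "stress_msf",
    "statistical_inefficiency",
    "sem",
    "summarize_series",
    "difference_map",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    pass


@dataclass
class ResidueStressSeries:
    """Time series of residue-averaged stress (kbar), per term when split."""

    residue_id: int
    n_atoms: int
    times: np.ndarray
    series: np.ndarray                    # (n_frames,) total stress
    per_term: dict[str, np.ndarray] = field(default_factory=dict)


def residue_average(stress: TrajectoryStress, residue_map: dict[int, list[int]],
                    split: bool = False) -> list[ResidueStressSeries]:
    """Average atomic stresses over each residue's atoms, per snapshot."""
    sel = stress.atom_indices
    pos_of_atom = {int(a): k for k, a in enumerate(sel)}
    covered = set(pos_of_atom)
    mapped = {a for atoms in residue_map.values() for a in atoms}
    orphans = covered - mapped
    if orphans:
        raise ValueError(f"atoms with no residue assignment: {sorted(orphans)[:10]}")
    total = stress.total
    out = []
    for rid in sorted(residue_map):
        cols = [pos_of_atom[a] for a in residue_map[rid] if a in pos_of_atom]
        if not cols:
            continue
        series = total[:, cols].mean(axis=1)
        per_term = (
            {t: v[:, cols].mean(axis=1) for t, v in stress.terms.items()} if split else {}
        )
        out.append(ResidueStressSeries(rid, len(cols), stress.times, series, per_term))
    return out


def stress_msf(series: np.ndarray) -> float:
    """Mean square fluctuation, population-normalised: (1/N)Σ(s_t − s̄)²."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise InsufficientDataError("MSF needs at least 2 snapshots")
    return float(np.mean((series - series.mean()) ** 2))


def statistical_inefficiency(series: np.ndarray, min_samples: int = 10) -> float:
    """g = 1 + 2·Σ_τ (1 − τ/N)·ρ(τ), summed to the first zero crossing.

    ρ is the normalised autocorrelation function.  g is clamped to ≥ 1; a
    zero-variance series yields g = 1 with a warning.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < min_samples:
        raise InsufficientDataError(f"statistical inefficiency needs >= {min_samples} samples")
    dx = x - x.mean()
    var = np.dot(dx, dx) / n
    if var <= 0:
        warnings.warn("zero-variance series: statistical inefficiency defined as 1")
        return 1.0
    # full autocovariance via FFT, normalised to ρ(0)=1
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(dx, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    rho = acov / acov[0]
    g = 1.0
    for tau in range(1, n):
        if rho[tau] <= 0.0:
            break
        g += 2.0 * (1.0 - tau / n) * rho[tau]
    return max(g, 1.0)


def sem(series: np.ndarray) -> float:
    """Standard error of the mean with g-corrected sample variance."""
    x = np.asarray(series, dtype=float)
    g = statistical_inefficiency(x)
    var = float(np.var(x, ddof=1))
    return float(np.sqrt(var * g / x.size))


@dataclass
class StressSummary:
    """Per-key (atom or residue) time statistics of a stress series set."""

    keys: np.ndarray        # residue ids or atom indices
    mean: np.ndarray        # kbar
    msf: np.ndarray         # kbar²
    sem: np.ndarray         # kbar
    g: np.ndarray           # statistical inefficiency
    n_frames: int


def summarize_series(keyed_series: dict[int, np.ndarray]) -> StressSummary:
    """Summary statistics (mean, MSF, SEM, g) for each keyed time series."""
    keys = np.array(sorted(keyed_series))
    n = len(keyed_series[int(keys[0])]) if len(keys) else 0
    mean = np.empty(len(keys))
    msf = np.empty(len(keys))
    sem_ = np.empty(len(keys))
    g = np.empty(len(keys))
    for k, key in enumerate(keys):
        s = np.asarray(keyed_series[int(key)], dtype=float)
        mean[k] = s.mean()
        msf[k] = stress_msf(s)
        g[k] = statistical_inefficiency(s)
        sem_[k] = np.sqrt(np.var(s, ddof=1) * g[k] / s.size)
    return StressSummary(keys, mean, msf, sem_, g, n)


@dataclass
class DifferenceMap:
    keys: np.ndarray
    delta_mean: np.ndarray
    sem_delta: np.ndarray   # quadrature-combined
    delta_msf: np.ndarray


def difference_map(summary_a: StressSummary, summary_b: StressSummary) -> DifferenceMap:
    """Per-key a − b deltas with SEMs combined in quadrature."""
    if not np.array_equal(summary_a.keys, summary_b.keys):
        missing_a = set(summary_b.keys) - set(summary_a.keys)
        missing_b = set(summary_a.keys) - set(summary_b.keys)
        raise ValueError(
            f"key mismatch: missing in a {sorted(missing_a)}, in b {sorted(missing_b)}"
        )
    return DifferenceMap(
        summary_a.keys,
        summary_a.mean - summary_b.mean,
        np.sqrt(summary_a.sem ** 2 + summary_b.sem ** 2),
        summary_a.msf - summary_b.msf,
    )
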