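"""Wavefront tracking: front radius versus time and propagation speed.

After a localized pulse, the leading front of a field (tensile stress, or
out-of-plane displacement) is located per frame as the greatest distance from
the pulse origin among atoms whose field value exceeds an adaptive threshold
— a fraction of that frame's maximum.  The front speed is the least-squares
slope of radius versus time; in internal units nm/ps equals km/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WavefrontFit", "NoFrontError", "front_radii", "measure_wavefront_speed"]


class NoFrontError(RuntimeError):
    """No frame shows a detectable front above threshold."""


@dataclass
class WavefrontFit:
    speed_km_s: float
    intercept_nm: float
    r_squared: float
    times: np.ndarray          # frames used in the fit
    radii: np.ndarray
    residuals: np.ndarray


def front_radii(coords_frames, values_frames, origin,
                threshold_fraction: float = 0.25,
                in_plane_axes=(0, 1)) -> np.ndarray:
    """Per-frame front radius (nm); NaN where no atom exceeds threshold.

    ``values_frames`` holds one nonnegative scalar per atom per frame (e.g.
    tensile stress, or |out-of-plane displacement|); distances from ``origin``
    are measured in the in-plane axes.
    """
    origin = np.asarray(origin, dtype=float)
    axes = list(in_plane_axes)
    out = np.empty(len(values_frames))
    for k, (coords, vals) in enumerate(zip(coords_frames, values_frames)):
        vmax = np.max(vals) if len(vals) else 0.0
        if vmax <= 0:
            out[k] = np.nan
            continue
        mask = vals >= threshold_fraction * vmax
        dist = np.linalg.norm(coords[np.asarray(mask)][:, axes] - origin[axes], axis=1)
        out[k] = dist.max() if len(dist) else np.nan
    return out


def measure_wavefront_speed(times, coords_frames, values_frames, origin,
                            threshold_fraction: float = 0.25,
                            min_frames: int = 5,
                            max_radius: float | None = None) -> WavefrontFit:
    """Fit the front radius versus time; slope is the speed in km/s.

    ``max_radius`` excludes frames after the front reaches a confining
    boundary (reflections break the linear radius–time model).
    """
    times = np.asarray(times, dtype=float)
    radii = front_radii(coords_frames, values_frames, origin, threshold_fraction)
    use = np.isfinite(radii)
    if max_radius is not None:
        use &= radii < max_radius
    if use.sum() < min_frames:
        raise NoFrontError(
            f"only {int(use.sum())} frames with a detectable front (need {min_frames})"
        )
    t, r = times[use], radii[use]
    slope, intercept = np.polyfit(t, r, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((r - pred) ** 2))
    ss_tot = float(np.sum((r - r.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return WavefrontFit(float(slope), float(intercept), r2, t, r, r - pred)
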