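"""Compiled inner loops for the mini-MD integrator (numba, optional).

These kernels duplicate the arithmetic of the vectorised numpy batch
functions in :mod:`force_decomposition` — same pairwise decompositions, same
parameter conventions — as tight per-term loops that accumulate per-atom
forces in place.  Equivalence with the numpy path is enforced by test.  When
numba is unavailable the integrator silently falls back to numpy.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def bonded_forces_kernel(coords, bond_idx, bond_k, bond_b0,
                         angle_idx, angle_k, angle_t0,
                         dih_idx, dih_k, dih_n, dih_cosphase, out):
    for t in range(bond_idx.shape[0]):
        i, j = bond_idx[t, 0], bond_idx[t, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        b = math.sqrt(dx * dx + dy * dy + dz * dz)
        g = -bond_k[t] * (b - bond_b0[t]) / b
        out[i, 0] += g * dx
        out[i, 1] += g * dy
        out[i, 2] += g * dz
        out[j, 0] -= g * dx
        out[j, 1] -= g * dy
        out[j, 2] -= g * dz

    for t in range(angle_idx.shape[0]):
        i, j, k = angle_idx[t, 0], angle_idx[t, 1], angle_idx[t, 2]
        v1x = coords[i, 0] - coords[j, 0]
        v1y = coords[i, 1] - coords[j, 1]
        v1z = coords[i, 2] - coords[j, 2]
        v2x = coords[k, 0] - coords[j, 0]
        v2y = coords[k, 1] - coords[j, 1]
        v2z = coords[k, 2] - coords[j, 2]
        v3x = coords[i, 0] - coords[k, 0]
        v3y = coords[i, 1] - coords[k, 1]
        v3z = coords[i, 2] - coords[k, 2]
        b1 = math.sqrt(v1x * v1x + v1y * v1y + v1z * v1z)
        b2 = math.sqrt(v2x * v2x + v2y * v2y + v2z * v2z)
        c = math.sqrt(v3x * v3x + v3y * v3y + v3z * v3z)
        cos_t = (b1 * b1 + b2 * b2 - c * c) / (2.0 * b1 * b2)
        if cos_t > 1.0:
            cos_t = 1.0
        elif cos_t < -1.0:
            cos_t = -1.0
        sin_t = math.sqrt(1.0 - cos_t * cos_t)
        theta = math.acos(cos_t)
        dv_dcos = -angle_k[t] * (theta - angle_t0[t]) / sin_t
        s3 = c * c
        g1 = dv_dcos * (b1 * b1 - b2 * b2 + s3) / (2.0 * b1 * b1 * b2)
        g2 = dv_dcos * (b2 * b2 - b1 * b1 + s3) / (2.0 * b2 * b2 * b1)
        g3 = dv_dcos * (-c / (b1 * b2))
        f1 = -g1 / b1
        f2 = -g2 / b2
        f3 = -g3 / c
        out[i, 0] += f1 * v1x + f3 * v3x
        out[i, 1] += f1 * v1y + f3 * v3y
        out[i, 2] += f1 * v1z + f3 * v3z
        out[j, 0] -= f1 * v1x + f2 * v2x
        out[j, 1] -= f1 * v1y + f2 * v2y
        out[j, 2] -= f1 * v1z + f2 * v2z
        out[k, 0] += f2 * v2x - f3 * v3x
        out[k, 1] += f2 * v2y - f3 * v3y
        out[k, 2] += f2 * v2z - f3 * v3z

    for t in range(dih_idx.shape[0]):
        a0, a1, a2, a3 = dih_idx[t, 0], dih_idx[t, 1], dih_idx[t, 2], dih_idx[t, 3]
        # six pair displacement vectors r_a − r_b
        # order: (0,1) (1,2) (2,3) (0,2) (1,3) (0,3)
        vx = np.empty(6)
        vy = np.empty(6)
        vz = np.empty(6)
        pa = (a0, a1, a2, a0, a1, a0)
        pb = (a1, a2, a3, a2, a3, a3)
        for p in range(6):
            vx[p] = coords[pa[p], 0] - coords[pb[p], 0]
            vy[p] = coords[pa[p], 1] - coords[pb[p], 1]
            vz[p] = coords[pa[p], 2] - coords[pb[p], 2]
        s = np.empty(6)
        for p in range(6):
            s[p] = vx[p] * vx[p] + vy[p] * vy[p] + vz[p] * vz[p]
        P, Q, R = s[0], s[1], s[2]
        A = 0.5 * (s[3] - s[0] - s[1])
        B = 0.5 * (s[4] - s[1] - s[2])
        C = 0.5 * (s[5] + s[1] - s[3] - s[4])
        D1 = P * Q - A * A
        D2 = Q * R - B * B
        D = math.sqrt(D1 * D2)
        x = (A * B - C * Q) / D
        if x > 1.0:
            x = 1.0
        elif x < -1.0:
            x = -1.0
        # dV/dx = k·cosφ_s·n·U_{n−1}(x)
        n = dih_n[t]
        u_prev = 0.0
        u = 1.0
        for _ in range(n - 1):
            u_new = 2.0 * x * u - u_prev
            u_prev = u
            u = u_new
        dv_dx = dih_k[t] * dih_cosphase[t] * n * u
        h_P = -x * Q / (2.0 * D1)
        h_Q = -C / D - x * (P / (2.0 * D1) + R / (2.0 * D2))
        h_R = -x * Q / (2.0 * D2)
        h_A = B / D + x * A / D1
        h_B = A / D + x * B / D2
        h_C = -Q / D
        dxds0 = h_P - 0.5 * h_A
        dxds1 = h_Q - 0.5 * h_A - 0.5 * h_B + 0.5 * h_C
        dxds2 = h_R - 0.5 * h_B
        dxds3 = 0.5 * h_A - 0.5 * h_C
        dxds4 = 0.5 * h_B - 0.5 * h_C
        dxds5 = 0.5 * h_C
        dxds = (dxds0, dxds1, dxds2, dxds3, dxds4, dxds5)
        for p in range(6):
            g = -2.0 * dv_dx * dxds[p]
            out[pa[p], 0] += g * vx[p]
            out[pa[p], 1] += g * vy[p]
            out[pa[p], 2] += g * vz[p]
            out[pb[p], 0] -= g * vx[p]
            out[pb[p], 1] -= g * vy[p]
            out[pb[p], 2] -= g * vz[p]


@njit(cache=True)
def nonbonded_forces_kernel(coords, pairs_i, pairs_j, q_scale, lj_scale,
                            charges, sigma, epsilon, fcoul, cutoff2, out):
    for p in range(pairs_i.shape[0]):
        i, j = pairs_i[p], pairs_j[p]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > cutoff2:
            continue
        r = math.sqrt(r2)
        g = q_scale[p] * fcoul * charges[i] * charges[j] / (r2 * r)
        eps = math.sqrt(epsilon[i] * epsilon[j])
        if eps > 0.0:
            sig = 0.5 * (sigma[i] + sigma[j])
            sr6 = (sig * sig / r2) ** 3
            g += lj_scale[p] * 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        out[i, 0] += g * dx
        out[i, 1] += g * dy
        out[i, 2] += g * dz
        out[j, 0] -= g * dx
        out[j, 1] -= g * dy
        out[j, 2] -= g * dz
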