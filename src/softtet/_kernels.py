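"""Numba Gauss-Seidel kernels for the solver's inner projection loops.

These are numerically identical to the record-level reference functions in
:mod:`softtet.constraints`, written as sequential scalar loops so a substepped
simulation stays interactive on one CPU core.  Mode 0 is XPBD (compliance +
accumulated multiplier), mode 1 is legacy PBD (stiffness-scaled correction
toward the constraint's rest value, no multiplier).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MODE_XPBD = 0
MODE_PBD = 1

_SQRT3 = np.sqrt(3.0)


@njit(cache=True)
def project_distance_pass(pos, w, ids, rest, alpha_t, lam, mode, k_pbd):
    for c in range(ids.shape[0]):
        i = ids[c, 0]
        j = ids[c, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dist = np.sqrt(dx * dx + dy * dy + dz * dz)
        if dist < 1e-12:
            continue
        at = alpha_t[c]
        if not np.isfinite(at):
            continue
        C = dist - rest[c]
        wsum = w[i] + w[j]
        if mode == MODE_XPBD:
            denom = wsum + at
            if denom < 1e-12:
                continue
            dl = (-C - at * lam[c]) / denom
            lam[c] += dl
        else:
            if wsum < 1e-12:
                continue
            dl = -C / wsum * k_pbd
        nx = dx / dist
        ny = dy / dist
        nz = dz / dist
        pos[i, 0] += w[i] * nx * dl
        pos[i, 1] += w[i] * ny * dl
        pos[i, 2] += w[i] * nz * dl
        pos[j, 0] -= w[j] * nx * dl
        pos[j, 1] -= w[j] * ny * dl
        pos[j, 2] -= w[j] * nz * dl


@njit(cache=True)
def project_volume_pass(pos, w, ids, rest, alpha_t, lam, mode, k_pbd):
    for c in range(ids.shape[0]):
        a = ids[c, 0]
        b = ids[c, 1]
        d = ids[c, 2]
        e = ids[c, 3]
        e1x = pos[b, 0] - pos[a, 0]
        e1y = pos[b, 1] - pos[a, 1]
        e1z = pos[b, 2] - pos[a, 2]
        e2x = pos[d, 0] - pos[a, 0]
        e2y = pos[d, 1] - pos[a, 1]
        e2z = pos[d, 2] - pos[a, 2]
        e3x = pos[e, 0] - pos[a, 0]
        e3y = pos[e, 1] - pos[a, 1]
        e3z = pos[e, 2] - pos[a, 2]
        at = alpha_t[c]
        if not np.isfinite(at):
            continue
        # cross products for value and gradients
        c12x = e1y * e2z - e1z * e2y
        c12y = e1z * e2x - e1x * e2z
        c12z = e1x * e2y - e1y * e2x
        C = (c12x * e3x + c12y * e3y + c12z * e3z) / 6.0 - rest[c]
        g2x = (e2y * e3z - e2z * e3y) / 6.0
        g2y = (e2z * e3x - e2x * e3z) / 6.0
        g2z = (e2x * e3y - e2y * e3x) / 6.0
        g3x = (e3y * e1z - e3z * e1y) / 6.0
        g3y = (e3z * e1x - e3x * e1z) / 6.0
        g3z = (e3x * e1y - e3y * e1x) / 6.0
        g4x = c12x / 6.0
        g4y = c12y / 6.0
        g4z = c12z / 6.0
        g1x = -(g2x + g3x + g4x)
        g1y = -(g2y + g3y + g4y)
        g1z = -(g2z + g3z + g4z)
        denom = (
            w[a] * (g1x * g1x + g1y * g1y + g1z * g1z)
            + w[b] * (g2x * g2x + g2y * g2y + g2z * g2z)
            + w[d] * (g3x * g3x + g3y * g3y + g3z * g3z)
            + w[e] * (g4x * g4x + g4y * g4y + g4z * g4z)
        )
        if mode == MODE_XPBD:
            denom += at
            if denom < 1e-12:
                continue
            dl = (-C - at * lam[c]) / denom
            lam[c] += dl
        else:
            if denom < 1e-12:
                continue
            dl = -C / denom * k_pbd
        pos[a, 0] += w[a] * g1x * dl
        pos[a, 1] += w[a] * g1y * dl
        pos[a, 2] += w[a] * g1z * dl
        pos[b, 0] += w[b] * g2x * dl
        pos[b, 1] += w[b] * g2y * dl
        pos[b, 2] += w[b] * g2z * dl
        pos[d, 0] += w[d] * g3x * dl
        pos[d, 1] += w[d] * g3y * dl
        pos[d, 2] += w[d] * g3z * dl
        pos[e, 0] += w[e] * g4x * dl
        pos[e, 1] += w[e] * g4y * dl
        pos[e, 2] += w[e] * g4z * dl


@njit(cache=True)
def _apply_tet_update(pos, w, a, b, d, e, G, dl):
    # G columns are gradients at vertices 2..4; vertex-1 gradient is -sum.
    g1x = -(G[0, 0] + G[0, 1] + G[0, 2])
    g1y = -(G[1, 0] + G[1, 1] + G[1, 2])
    g1z = -(G[2, 0] + G[2, 1] + G[2, 2])
    pos[a, 0] += w[a] * g1x * dl
    pos[a, 1] += w[a] * g1y * dl
    pos[a, 2] += w[a] * g1z * dl
    pos[b, 0] += w[b] * G[0, 0] * dl
    pos[b, 1] += w[b] * G[1, 0] * dl
    pos[b, 2] += w[b] * G[2, 0] * dl
    pos[d, 0] += w[d] * G[0, 1] * dl
    pos[d, 1] += w[d] * G[1, 1] * dl
    pos[d, 2] += w[d] * G[2, 1] * dl
    pos[e, 0] += w[e] * G[0, 2] * dl
    pos[e, 1] += w[e] * G[1, 2] * dl
    pos[e, 2] += w[e] * G[2, 2] * dl


@njit(cache=True)
def _tet_denominator(w, a, b, d, e, G):
    g1x = -(G[0, 0] + G[0, 1] + G[0, 2])
    g1y = -(G[1, 0] + G[1, 1] + G[1, 2])
    g1z = -(G[2, 0] + G[2, 1] + G[2, 2])
    denom = w[a] * (g1x * g1x + g1y * g1y + g1z * g1z)
    denom += w[b] * (G[0, 0] ** 2 + G[1, 0] ** 2 + G[2, 0] ** 2)
    denom += w[d] * (G[0, 1] ** 2 + G[1, 1] ** 2 + G[2, 1] ** 2)
    denom += w[e] * (G[0, 2] ** 2 + G[1, 2] ** 2 + G[2, 2] ** 2)
    return denom


@njit(cache=True)
def project_neo_pass(
    pos, w, ids, inv_rest, offset, alpha_h_t, alpha_d_t, lam_h, lam_d, mode, k_h, k_d
):
    F = np.empty((3, 3))
    dCdF = np.empty((3, 3))
    G = np.empty((3, 3))
    for c in range(ids.shape[0]):
        a = ids[c, 0]
        b = ids[c, 1]
        d = ids[c, 2]
        e = ids[c, 3]
        B = inv_rest[c]

        # ---- hydrostatic: C_H = det(F) - 1 - offset ----
        for r in range(3):
            ds0 = pos[b, r] - pos[a, r]
            ds1 = pos[d, r] - pos[a, r]
            ds2 = pos[e, r] - pos[a, r]
            F[r, 0] = ds0 * B[0, 0] + ds1 * B[1, 0] + ds2 * B[2, 0]
            F[r, 1] = ds0 * B[0, 1] + ds1 * B[1, 1] + ds2 * B[2, 1]
            F[r, 2] = ds0 * B[0, 2] + ds1 * B[1, 2] + ds2 * B[2, 2]
        detF = (
            F[0, 0] * (F[1, 1] * F[2, 2] - F[1, 2] * F[2, 1])
            - F[0, 1] * (F[1, 0] * F[2, 2] - F[1, 2] * F[2, 0])
            + F[0, 2] * (F[1, 0] * F[2, 1] - F[1, 1] * F[2, 0])
        )
        at_h = alpha_h_t[c]
        if np.isfinite(at_h) and np.abs(detF) > 1e-8:
            C = detF - 1.0 - offset[c]
            # cofactor columns: f2 x f3, f3 x f1, f1 x f2
            dCdF[0, 0] = F[1, 1] * F[2, 2] - F[2, 1] * F[1, 2]
            dCdF[1, 0] = F[2, 1] * F[0, 2] - F[0, 1] * F[2, 2]
            dCdF[2, 0] = F[0, 1] * F[1, 2] - F[1, 1] * F[0, 2]
            dCdF[0, 1] = F[1, 2] * F[2, 0] - F[2, 2] * F[1, 0]
            dCdF[1, 1] = F[2, 2] * F[0, 0] - F[0, 2] * F[2, 0]
            dCdF[2, 1] = F[0, 2] * F[1, 0] - F[1, 2] * F[0, 0]
            dCdF[0, 2] = F[1, 0] * F[2, 1] - F[2, 0] * F[1, 1]
            dCdF[1, 2] = F[2, 0] * F[0, 1] - F[0, 0] * F[2, 1]
            dCdF[2, 2] = F[0, 0] * F[1, 1] - F[1, 0] * F[0, 1]
            for r in range(3):
                for q in range(3):
                    G[r, q] = (
                        dCdF[r, 0] * B[q, 0] + dCdF[r, 1] * B[q, 1] + dCdF[r, 2] * B[q, 2]
                    )
            denom = _tet_denominator(w, a, b, d, e, G)
            if mode == MODE_XPBD:
                denom += at_h
                if denom >= 1e-12:
                    dl = (-C - at_h * lam_h[c]) / denom
                    lam_h[c] += dl
                    _apply_tet_update(pos, w, a, b, d, e, G, dl)
            else:
                if denom >= 1e-12:
                    dl = -(C + offset[c]) / denom * k_h  # PBD target: rest value
                    _apply_tet_update(pos, w, a, b, d, e, G, dl)

        # ---- deviatoric: C_D = ||F||_F ----
        at_d = alpha_d_t[c]
        if not np.isfinite(at_d):
            continue
        for r in range(3):
            ds0 = pos[b, r] - pos[a, r]
            ds1 = pos[d, r] - pos[a, r]
            ds2 = pos[e, r] - pos[a, r]
            F[r, 0] = ds0 * B[0, 0] + ds1 * B[1, 0] + ds2 * B[2, 0]
            F[r, 1] = ds0 * B[0, 1] + ds1 * B[1, 1] + ds2 * B[2, 1]
            F[r, 2] = ds0 * B[0, 2] + ds1 * B[1, 2] + ds2 * B[2, 2]
        tr = 0.0
        for r in range(3):
            for q in range(3):
                tr += F[r, q] * F[r, q]
        Cd = np.sqrt(tr)
        if Cd < 1e-8:
            continue
        for r in range(3):
            for q in range(3):
                G[r, q] = (
                    F[r, 0] * B[q, 0] + F[r, 1] * B[q, 1] + F[r, 2] * B[q, 2]
                ) / Cd
        denom = _tet_denominator(w, a, b, d, e, G)
        if mode == MODE_XPBD:
            denom += at_d
            if denom < 1e-12:
                continue
            dl = (-Cd - at_d * lam_d[c]) / denom
            lam_d[c] += dl
        else:
            if denom < 1e-12:
                continue
            dl = -(Cd - _SQRT3) / denom * k_d  # PBD target: rest value sqrt(3)
        _apply_tet_update(pos, w, a, b, d, e, G, dl)
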