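"""Numba-compiled Gauss-Seidel constraint sweep.

The sweep processes constraints strictly in array (insertion) order, each
projection seeing the latest positions.  The arithmetic mirrors the
reference implementations in :mod:`softpbd.constraints`; the test suite
cross-checks the two paths on random systems.

Kinds handled here: distance (0), tet volume (1), overstretch (2),
sphere-sphere contact (3, a unilateral distance) and vertex-triangle
contact (4, barycentric-weighted normal gradients).  The single global
surface-volume constraint is projected between sweeps by
:func:`softpbd.constraints.project_surface_volume` (its gradient touches
every node, which does not fit the fixed-arity kernel layout).
"""

import math

import numpy as np
from numba import njit

__all__ = ["gauss_seidel_sweep", "accumulate_spring_forces"]


@njit(cache=True)
def accumulate_spring_forces(x, si, sj, l0, dlc, k1, k2, out):
    """Add nonlinear spring forces to ``out`` (restoring pairs).

    Same piecewise law as :func:`softpbd.forces.spring_scalar`: cubic
    below the per-spring crossover ``dlc``, linear with matched value and
    slope above.  Degenerate springs (length < 1e-9) are skipped.
    """
    for s in range(si.shape[0]):
        i = si[s]
        j = sj[s]
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        L = math.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if L < 1e-9:
            continue
        dl = L - l0[s]
        a = abs(dl)
        c = dlc[s]
        if a <= c:
            mag = k1 * dl + k2 * dl * dl * dl
        else:
            A = k1 * c + k2 * c * c * c
            B = k1 + 3.0 * k2 * c * c
            mag = (A + B * (a - c)) * (1.0 if dl > 0.0 else -1.0)
        f = -mag / L
        out[i, 0] += f * d0
        out[i, 1] += f * d1
        out[i, 2] += f * d2
        out[j, 0] -= f * d0
        out[j, 1] -= f * d1
        out[j, 2] -= f * d2


@njit(cache=True)
def gauss_seidel_sweep(x, w, kind, nodes, rest, aux, alpha_t, lam, unilateral):
    """One in-place Gauss-Seidel pass over all constraints.

    ``alpha_t`` holds the time-scaled compliances alpha/dt^2; ``lam`` the
    multipliers accumulated so far this timestep (updated in place).
    """
    m = kind.shape[0]
    for c in range(m):
        k = kind[c]
        at = alpha_t[c]
        if k == 0 or k == 3:  # distance / sphere-sphere contact
            i = nodes[c, 0]
            j = nodes[c, 1]
            d0 = x[j, 0] - x[i, 0]
            d1 = x[j, 1] - x[i, 1]
            d2 = x[j, 2] - x[i, 2]
            L = math.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
            if L < 1e-9:
                continue
            C = L - rest[c]
            if unilateral[c] and C >= 0.0:
                continue
            denom = w[i] + w[j] + at
            if denom <= 0.0:
                continue
            dl = -(C + at * lam[c]) / denom
            lam[c] += dl
            n0 = d0 / L
            n1 = d1 / L
            n2 = d2 / L
            x[i, 0] -= w[i] * n0 * dl
            x[i, 1] -= w[i] * n1 * dl
            x[i, 2] -= w[i] * n2 * dl
            x[j, 0] += w[j] * n0 * dl
            x[j, 1] += w[j] * n1 * dl
            x[j, 2] += w[j] * n2 * dl
        elif k == 1:  # tetrahedron volume
            i1 = nodes[c, 0]
            i2 = nodes[c, 1]
            i3 = nodes[c, 2]
            i4 = nodes[c, 3]
            u0 = x[i2, 0] - x[i1, 0]
            u1 = x[i2, 1] - x[i1, 1]
            u2 = x[i2, 2] - x[i1, 2]
            v0 = x[i3, 0] - x[i1, 0]
            v1 = x[i3, 1] - x[i1, 1]
            v2 = x[i3, 2] - x[i1, 2]
            t0 = x[i4, 0] - x[i1, 0]
            t1 = x[i4, 1] - x[i1, 1]
            t2 = x[i4, 2] - x[i1, 2]
            # g2 = (v x t)/6, g3 = (t x u)/6, g4 = (u x v)/6, g1 = -(g2+g3+g4)
            g2x = (v1 * t2 - v2 * t1) / 6.0
            g2y = (v2 * t0 - v0 * t2) / 6.0
            g2z = (v0 * t1 - v1 * t0) / 6.0
            g3x = (t1 * u2 - t2 * u1) / 6.0
            g3y = (t2 * u0 - t0 * u2) / 6.0
            g3z = (t0 * u1 - t1 * u0) / 6.0
            g4x = (u1 * v2 - u2 * v1) / 6.0
            g4y = (u2 * v0 - u0 * v2) / 6.0
            g4z = (u0 * v1 - u1 * v0) / 6.0
            g1x = -(g2x + g3x + g4x)
            g1y = -(g2y + g3y + g4y)
            g1z = -(g2z + g3z + g4z)
            C = g4x * t0 + g4y * t1 + g4z * t2 - rest[c]
            denom = (w[i1] * (g1x * g1x + g1y * g1y + g1z * g1z)
                     + w[i2] * (g2x * g2x + g2y * g2y + g2z * g2z)
                     + w[i3] * (g3x * g3x + g3y * g3y + g3z * g3z)
                     + w[i4] * (g4x * g4x + g4y * g4y + g4z * g4z) + at)
            if denom <= 0.0:
                continue
            dl = -(C + at * lam[c]) / denom
            lam[c] += dl
            x[i1, 0] += w[i1] * g1x * dl
            x[i1, 1] += w[i1] * g1y * dl
            x[i1, 2] += w[i1] * g1z * dl
            x[i2, 0] += w[i2] * g2x * dl
            x[i2, 1] += w[i2] * g2y * dl
            x[i2, 2] += w[i2] * g2z * dl
            x[i3, 0] += w[i3] * g3x * dl
            x[i3, 1] += w[i3] * g3y * dl
            x[i3, 2] += w[i3] * g3z * dl
            x[i4, 0] += w[i4] * g4x * dl
            x[i4, 1] += w[i4] * g4y * dl
            x[i4, 2] += w[i4] * g4z * dl
        elif k == 2:  # overstretch band limiter
            i = nodes[c, 0]
            j = nodes[c, 1]
            d0 = x[i, 0] - x[j, 0]
            d1 = x[i, 1] - x[j, 1]
            d2 = x[i, 2] - x[j, 2]
            L = math.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
            if L < 1e-9:
                continue
            dl_e = L - rest[c]
            band = aux[c]
            if dl_e * dl_e <= band * band:
                continue
            C = band * band - dl_e * dl_e
            s = -2.0 * dl_e / L
            g1x = s * d0
            g1y = s * d1
            g1z = s * d2
            denom = (w[i] + w[j]) * (g1x * g1x + g1y * g1y + g1z * g1z) + at
            if denom <= 0.0:
                continue
            dl = -(C + at * lam[c]) / denom
            lam[c] += dl
            x[i, 0] += w[i] * g1x * dl
            x[i, 1] += w[i] * g1y * dl
            x[i, 2] += w[i] * g1z * dl
            x[j, 0] -= w[j] * g1x * dl
            x[j, 1] -= w[j] * g1y * dl
            x[j, 2] -= w[j] * g1z * dl
        elif k == 4:  # vertex-triangle contact
            iq = nodes[c, 0]
            i1 = nodes[c, 1]
            i2 = nodes[c, 2]
            i3 = nodes[c, 3]
            e10 = x[i2, 0] - x[i1, 0]
            e11 = x[i2, 1] - x[i1, 1]
            e12 = x[i2, 2] - x[i1, 2]
            e20 = x[i3, 0] - x[i1, 0]
            e21 = x[i3, 1] - x[i1, 1]
            e22 = x[i3, 2] - x[i1, 2]
            n0 = e11 * e22 - e12 * e21
            n1 = e12 * e20 - e10 * e22
            n2 = e10 * e21 - e11 * e20
            nn = math.sqrt(n0 * n0 + n1 * n1 + n2 * n2)
            if nn < 1e-12:
                continue
            n0 /= nn
            n1 /= nn
            n2 /= nn
            d0 = x[iq, 0] - x[i1, 0]
            d1 = x[iq, 1] - x[i1, 1]
            d2 = x[iq, 2] - x[i1, 2]
            h = d0 * n0 + d1 * n1 + d2 * n2
            C = h - rest[c]
            if unilateral[c] and C >= 0.0:
                continue
            # barycentric weights of the in-plane projection of q
            t0 = d0 - h * n0
            t1 = d1 - h * n1
            t2 = d2 - h * n2
            a11 = e10 * e10 + e11 * e11 + e12 * e12
            a12 = e10 * e20 + e11 * e21 + e12 * e22
            a22 = e20 * e20 + e21 * e21 + e22 * e22
            det = a11 * a22 - a12 * a12
            if abs(det) < 1e-18:
                continue
            r1 = e10 * t0 + e11 * t1 + e12 * t2
            r2 = e20 * t0 + e21 * t1 + e22 * t2
            b2 = (a22 * r1 - a12 * r2) / det
            b3 = (a11 * r2 - a12 * r1) / det
            b1 = 1.0 - b2 - b3
            denom = (w[iq] + w[i1] * b1 * b1 + w[i2] * b2 * b2
                     + w[i3] * b3 * b3 + at)
            if denom <= 0.0:
                continue
            dl = -(C + at * lam[c]) / denom
            lam[c] += dl
            x[iq, 0] += w[iq] * n0 * dl
            x[iq, 1] += w[iq] * n1 * dl
            x[iq, 2] += w[iq] * n2 * dl
            x[i1, 0] -= w[i1] * b1 * n0 * dl
            x[i1, 1] -= w[i1] * b1 * n1 * dl
            x[i1, 2] -= w[i1] * b1 * n2 * dl
            x[i2, 0] -= w[i2] * b2 * n0 * dl
            x[i2, 1] -= w[i2] * b2 * n1 * dl
            x[i2, 2] -= w[i2] * b2 * n2 * dl
            x[i3, 0] -= w[i3] * b3 * n0 * dl
            x[i3, 1] -= w[i3] * b3 * n1 * dl
            x[i3, 2] -= w[i3] * b3 * n2 * dl
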