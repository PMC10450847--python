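"""Accelerated integration kernels (numba).

Same physics as the pure-NumPy reference engine in :mod:`cgidp.simulator`:
harmonic bonds, truncated-shifted Ashbaugh–Hatch, truncated-shifted
Debye–Hückel under minimum image, BAOAB Langevin splitting.  Trajectories
from the two backends agree distributionally (floating-point summation
order differs); each backend is bitwise-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _forces(x, box, bonds, kbond, r0, pi, pj, sigma, lam, dh_coef,
            eps, rc_n, rc_i, debye, f):
    n = x.shape[0]
    for a in range(n):
        f[a, 0] = 0.0
        f[a, 1] = 0.0
        f[a, 2] = 0.0
    rmin_seen = 1e30
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        d0 -= box[0] * np.rint(d0 / box[0])
        d1 -= box[1] * np.rint(d1 / box[1])
        d2 -= box[2] * np.rint(d2 / box[2])
        r = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
        if r < rmin_seen:
            rmin_seen = r
        mag = -kbond * (r - r0) / r
        f[i, 0] += mag * d0
        f[i, 1] += mag * d1
        f[i, 2] += mag * d2
        f[j, 0] -= mag * d0
        f[j, 1] -= mag * d1
        f[j, 2] -= mag * d2
    rmin_fac = 2.0 ** (1.0 / 6.0)
    for p in range(pi.shape[0]):
        i = pi[p]
        j = pj[p]
        d0 = x[i, 0] - x[j, 0]
        d1 = x[i, 1] - x[j, 1]
        d2 = x[i, 2] - x[j, 2]
        d0 -= box[0] * np.rint(d0 / box[0])
        d1 -= box[1] * np.rint(d1 / box[1])
        d2 -= box[2] * np.rint(d2 / box[2])
        r2 = d0 * d0 + d1 * d1 + d2 * d2
        r = np.sqrt(r2)
        if r < rmin_seen:
            rmin_seen = r
        dudr = 0.0
        if r <= rc_n:
            s = sigma[p] / r
            s6 = s * s * s * s * s * s
            uljp = -24.0 * eps * (2.0 * s6 * s6 - s6) / r
            if r <= rmin_fac * sigma[p]:
                dudr = uljp
            else:
                dudr = lam[p] * uljp
        c = dh_coef[p]
        if c != 0.0 and r <= rc_i:
            dudr += -c * np.exp(-r / debye) * (1.0 / r2 + 1.0 / (r * debye))
        if dudr != 0.0:
            mag = -dudr / r
            f[i, 0] += mag * d0
            f[i, 1] += mag * d1
            f[i, 2] += mag * d2
            f[j, 0] -= mag * d0
            f[j, 1] -= mag * d1
            f[j, 2] -= mag * d2
    return rmin_seen


@njit(cache=True)
def _baoab_chunk(x, v, f, masses, box, dt, c1, c2, noise,
                 bonds, kbond, r0, pi, pj, sigma, lam, dh_coef,
                 eps, rc_n, rc_i, debye,
                 step0, save_every, frames, kes, nsaved0):
    n = x.shape[0]
    nsaved = nsaved0
    rmin_global = 1e30
    for s in range(noise.shape[0]):
        for a in range(n):
            inv = 0.5 * dt / masses[a]
            for k in range(3):
                v[a, k] += inv * f[a, k]
                x[a, k] += 0.5 * dt * v[a, k]
        for a in range(n):
            amp = c2 / np.sqrt(masses[a])
            for k in range(3):
                v[a, k] = c1 * v[a, k] + amp * noise[s, a, k]
                x[a, k] += 0.5 * dt * v[a, k]
        rmin = _forces(x, box, bonds, kbond, r0, pi, pj, sigma, lam,
                       dh_coef, eps, rc_n, rc_i, debye, f)
        if rmin < rmin_global:
            rmin_global = rmin
        for a in range(n):
            inv = 0.5 * dt / masses[a]
            for k in range(3):
                v[a, k] += inv * f[a, k]
        if (step0 + s + 1) % save_every == 0:
            ke = 0.0
            for a in range(n):
                for k in range(3):
                    frames[nsaved, a, k] = x[a, k]
                    ke += 0.5 * masses[a] * v[a, k] * v[a, k]
            kes[nsaved] = ke
            nsaved += 1
    return nsaved, rmin_global
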