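"""Numba kernels for the per-day hot loops of batched population runs.

The reference implementations (numpy, histogram-explicit) live in
:mod:`radiobiology` and :mod:`oxygenation`; these fused kernels must agree
with them to floating-point tolerance and are cross-checked in the tests.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def survivors_lookup(viable, vf, cons, doses, vf_grid, cons_grid, table,
                     a_bins, b_bins, alpha_scale):
    """Expected survivors per voxel, fused histogram-interpolation + LQ kill.

    viable, vf, cons : (B, N); doses : (N,); table : (nv, nc, J) histogram
    weights; a_bins/b_bins : (J,) LQ exponents per bin at the reference
    alpha; alpha_scale : (B,) per-patient alpha / reference alpha.
    Returns (B, N) expected surviving cells.
    """
    B, N = viable.shape
    nv = vf_grid.shape[0]
    nc = cons_grid.shape[0]
    J = a_bins.shape[0]
    out = np.empty((B, N))
    for b in range(B):
        s = alpha_scale[b]
        for n in range(N):
            v = vf[b, n]
            if v < vf_grid[0]:
                v = vf_grid[0]
            elif v > vf_grid[nv - 1]:
                v = vf_grid[nv - 1]
            c = cons[b, n]
            if c < cons_grid[0]:
                c = cons_grid[0]
            elif c > cons_grid[nc - 1]:
                c = cons_grid[nc - 1]
            iv = np.searchsorted(vf_grid, v) - 1
            if iv < 0:
                iv = 0
            elif iv > nv - 2:
                iv = nv - 2
            ic = np.searchsorted(cons_grid, c) - 1
            if ic < 0:
                ic = 0
            elif ic > nc - 2:
                ic = nc - 2
            tv = (v - vf_grid[iv]) / (vf_grid[iv + 1] - vf_grid[iv])
            tc = (c - cons_grid[ic]) / (cons_grid[ic + 1] - cons_grid[ic])
            w00 = (1.0 - tv) * (1.0 - tc)
            w10 = tv * (1.0 - tc)
            w01 = (1.0 - tv) * tc
            w11 = tv * tc
            d = doses[n]
            acc = 0.0
            for j in range(J):
                wj = (w00 * table[iv, ic, j] + w10 * table[iv + 1, ic, j]
                      + w01 * table[iv, ic + 1, j] + w11 * table[iv + 1, ic + 1, j])
                if wj > 0.0:
                    acc += wj * np.exp(-(s * a_bins[j] + b_bins[j] * d) * d)
            out[b, n] = viable[b, n] * acc
    return out


@njit(cache=True)
def stochastic_survivors(viable, vf, cons, doses, vf_grid, cons_grid, table,
                         a_bins, b_bins, alpha_scale, seed):
    """Integerized survivors for small voxels (flat arrays).

    viable/vf/cons/doses/alpha_scale : (k,) per small voxel; the viable
    count is rounded to an integer, partitioned over the histogram bins
    (multinomial via a binomial chain) and killed binomially per bin with
    the oxygen-dependent survival fraction.  Seeded explicitly so a given
    call sequence is reproducible.
    """
    np.random.seed(seed)
    k = viable.shape[0]
    nv = vf_grid.shape[0]
    nc = cons_grid.shape[0]
    J = a_bins.shape[0]
    out = np.zeros(k)
    for i in range(k):
        n_int = int(np.rint(viable[i]))
        if n_int <= 0:
            continue
        v = min(max(vf[i], vf_grid[0]), vf_grid[nv - 1])
        c = min(max(cons[i], cons_grid[0]), cons_grid[nc - 1])
        iv = min(max(np.searchsorted(vf_grid, v) - 1, 0), nv - 2)
        ic = min(max(np.searchsorted(cons_grid, c) - 1, 0), nc - 2)
        tv = (v - vf_grid[iv]) / (vf_grid[iv + 1] - vf_grid[iv])
        tc = (c - cons_grid[ic]) / (cons_grid[ic + 1] - cons_grid[ic])
        w00 = (1.0 - tv) * (1.0 - tc)
        w10 = tv * (1.0 - tc)
        w01 = (1.0 - tv) * tc
        w11 = tv * tc
        d = doses[i]
        s = alpha_scale[i]
        remaining = n_int
        wsum = 1.0
        surv = 0
        for j in range(J):
            wj = (w00 * table[iv, ic, j] + w10 * table[iv + 1, ic, j]
                  + w01 * table[iv, ic + 1, j] + w11 * table[iv + 1, ic + 1, j])
            if remaining <= 0:
                break
            if wj <= 0.0 or wsum <= 0.0:
                continue
            p = wj / wsum
            if p >= 1.0:
                nj = remaining
            else:
                nj = np.random.binomial(remaining, p)
            remaining -= nj
            wsum -= wj
            if nj > 0:
                sf = np.exp(-(s * a_bins[j] + b_bins[j] * d) * d)
                surv += np.random.binomial(nj, sf)
        out[i] = surv
    return out


@njit(cache=True)
def diffusion_exchange(comps, cap, rate, overfill):
    """Occupancy-gradient diffusive exchange on a batched 3-D lattice.

    comps : (4, B, X, Y, Z) compartment stack, modified in place.
    Flow across each face goes from the fuller to the emptier voxel at
    ``rate/6 * cap`` per unit occupancy difference per day, limited by the
    receiver's headroom (up to ``overfill*cap``) and by the sender's
    content; composition moves proportionally.  Conserves each compartment.
    """
    nco, B, X, Y, Z = comps.shape
    orig = comps.copy()
    tracked = np.zeros((B, X, Y, Z))
    for k in range(nco):
        tracked += comps[k]
    r = rate / 6.0
    inflow = np.zeros((B, X, Y, Z))
    outflow = np.zeros((B, X, Y, Z))
    for b in range(B):
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    tc = tracked[b, x, y, z]
                    for axis in range(3):
                        for sgn in (-1, 1):
                            xx, yy, zz = x, y, z
                            if axis == 0:
                                xx += sgn
                            elif axis == 1:
                                yy += sgn
                            else:
                                zz += sgn
                            if xx < 0 or xx >= X or yy < 0 or yy >= Y or zz < 0 or zz >= Z:
                                continue
                            diff = tc - tracked[b, xx, yy, zz]
                            if diff > 0.0:
                                f = r * diff  # units of cells (diff/cap*cap)
                                outflow[b, x, y, z] += f
                                inflow[b, xx, yy, zz] += f
    # receiver acceptance and sender limits
    for b in range(B):
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    tc = tracked[b, x, y, z]
                    if outflow[b, x, y, z] <= 0.0:
                        continue
                    sent = 0.0
                    for axis in range(3):
                        for sgn in (-1, 1):
                            xx, yy, zz = x, y, z
                            if axis == 0:
                                xx += sgn
                            elif axis == 1:
                                yy += sgn
                            else:
                                zz += sgn
                            if xx < 0 or xx >= X or yy < 0 or yy >= Y or zz < 0 or zz >= Z:
                                continue
                            diff = tc - tracked[b, xx, yy, zz]
                            if diff <= 0.0:
                                continue
                            f = r * diff
                            head = overfill * cap - tracked[b, xx, yy, zz]
                            if head < 0.0:
                                head = 0.0
                            acc = 1.0
                            if inflow[b, xx, yy, zz] > head:
                                if inflow[b, xx, yy, zz] > 0.0:
                                    acc = head / inflow[b, xx, yy, zz]
                                else:
                                    acc = 0.0
                            f *= acc
                            sent += f
                    scale = 1.0
                    if sent > tc and sent > 0.0:
                        scale = tc / sent
                    if sent <= 0.0 or tc <= 0.0:
                        continue
                    # move composition-proportional amounts (source fractions
                    # are taken from the pre-exchange composition)
                    for axis in range(3):
                        for sgn in (-1, 1):
                            xx, yy, zz = x, y, z
                            if axis == 0:
                                xx += sgn
                            elif axis == 1:
                                yy += sgn
                            else:
                                zz += sgn
                            if xx < 0 or xx >= X or yy < 0 or yy >= Y or zz < 0 or zz >= Z:
                                continue
                            diff = tc - tracked[b, xx, yy, zz]
                            if diff <= 0.0:
                                continue
                            f = r * diff
                            head = overfill * cap - tracked[b, xx, yy, zz]
                            if head < 0.0:
                                head = 0.0
                            acc = 1.0
                            if inflow[b, xx, yy, zz] > head:
                                if inflow[b, xx, yy, zz] > 0.0:
                                    acc = head / inflow[b, xx, yy, zz]
                                else:
                                    acc = 0.0
                            f *= acc * scale
                            frac = f / tc
                            for k in range(nco):
                                amount = orig[k, b, x, y, z] * frac
                                comps[k, b, x, y, z] -= amount
                                comps[k, b, xx, yy, zz] += amount
    return comps
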