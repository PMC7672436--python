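"""Numba kernels for the overdamped Langevin sampler with ABF-like biasing.

The potential is selected by an integer archetype code so the whole
trajectory loop stays inside one jitted function.  Parameters are packed
into flat float arrays by :mod:`pairscape.synthetic_data`.
"""

import numpy as np
from numba import njit

KIND_QUADRATIC = 0
KIND_DOUBLE_WELL = 1
KIND_CANONICAL = 2
KIND_MISMATCH = 3


@njit(cache=False)
def _grad(kind, p, x, out):
    d = x.shape[0]
    if kind == KIND_QUADRATIC:
        # p = [k_0..k_{d-1}, x0_0..x0_{d-1}]
        for i in range(d):
            out[i] = p[i] * (x[i] - p[d + i])
    elif kind == KIND_DOUBLE_WELL:
        # p = [h, w, ky]; V = h((x/w)^2-1)^2 (+ 0.5 ky y^2 in 2D)
        h, w = p[0], p[1]
        r = x[0] / w
        out[0] = 4.0 * h * r * (r * r - 1.0) / w
        if d > 1:
            out[1] = p[2] * x[1]
    elif kind == KIND_CANONICAL:
        # p = [a, s, sig0, kS, S0, c, w]
        # V = a(exp(-u)+u-1) + c(sqrt(1+v^2)-1) + 0.5 kS (S-S0)^2
        # exponential wall toward the minor groove plus a stiff core with
        # asymptotically linear arms
        a, s = p[0], p[1]
        u = (x[0] - p[2]) / s
        v = (x[0] - p[2]) / p[6]
        out[0] = a * (1.0 - np.exp(-u)) / s \
            + p[5] * v / (p[6] * np.sqrt(1.0 + v * v))
        if d > 1:
            out[1] = p[3] * (x[1] - p[4])
    else:
        # mismatch: p = [a, s, sig0, kc, ridge, rw,  n_wells, (sig,S,dep,wsig,wS)*n]
        a, s = p[0], p[1]
        u = (x[0] - p[2]) / s
        out[0] = a * (1.0 - np.exp(-u)) / s
        out[1] = p[3] * x[1]
        # ridge across shear = 0
        e = np.exp(-0.5 * (x[1] / p[5]) ** 2)
        out[1] += p[4] * e * (-x[1] / (p[5] * p[5]))
        nw = int(p[6])
        for i in range(nw):
            o = 7 + 5 * i
            dx0 = (x[0] - p[o]) / p[o + 3]
            dx1 = (x[1] - p[o + 1]) / p[o + 4]
            g = p[o + 2] * np.exp(-0.5 * (dx0 * dx0 + dx1 * dx1))
            out[0] += g * dx0 / p[o + 3]
            out[1] += g * dx1 / p[o + 4]


@njit(cache=False)
def run_langevin(kind, p, x0, n_steps, dt, mobility, kT,
                 xi, force_noise,
                 mins, maxs, nbins, periodic,
                 bias_on, n_ramp,
                 bias_count, bias_sum,
                 values, forces):
    """Euler-Maruyama overdamped Langevin with optional ABF-like bias.

    ``bias_count``/``bias_sum`` are shared accumulators (multi-walker).
    Returns 0 on success, 1 on divergence (step index stored in values[-1,0]
    is not attempted; caller reports).
    """
    d = x0.shape[0]
    x = x0.copy()
    g = np.empty(d)
    sig = np.empty(d)
    span = np.empty(d)
    for i in range(d):
        sig[i] = np.sqrt(2.0 * kT * mobility[i] * dt)
        span[i] = maxs[i] - mins[i]
    for step in range(n_steps):
        _grad(kind, p, x, g)
        # instantaneous generalized force (recorded, unbiased)
        for i in range(d):
            forces[step, i] = -g[i] + force_noise[step, i]
            values[step, i] = x[i]
        # locate bin
        idx = 0
        ok = True
        for i in range(d):
            b = int((x[i] - mins[i]) / span[i] * nbins[i])
            if b < 0:
                b = 0
            if b >= nbins[i]:
                b = nbins[i] - 1
            idx = idx * nbins[i] + b
        if not ok:
            return 1
        # accumulate running mean of the instantaneous force
        bias_count[idx] += 1
        for i in range(d):
            bias_sum[idx * d + i] += forces[step, i]
        # total deterministic force
        ramp = 0.0
        if bias_on == 1:
            c = bias_count[idx]
            ramp = c / n_ramp
            if ramp > 1.0:
                ramp = 1.0
        for i in range(d):
            f = -g[i]
            if bias_on == 1 and bias_count[idx] > 0:
                f -= ramp * (bias_sum[idx * d + i] / bias_count[idx])
            x[i] += mobility[i] * f * dt + sig[i] * xi[step, i]
        # boundaries
        for i in range(d):
            if periodic[i] == 1:
                while x[i] >= maxs[i]:
                    x[i] -= span[i]
                while x[i] < mins[i]:
                    x[i] += span[i]
            else:
                # reflective walls
                if x[i] > maxs[i]:
                    x[i] = 2.0 * maxs[i] - x[i]
                if x[i] < mins[i]:
                    x[i] = 2.0 * mins[i] - x[i]
                if x[i] > maxs[i] or x[i] < mins[i]:
                    return 1        # diverged beyond a full span in one step
    return 0


@njit(cache=False)
def welford_accumulate(flat_idx, values, forces, count, value_mean, mean, m2):
    """Per-bin Welford update for force samples and position centroids."""
    n, d = forces.shape
    for s in range(n):
        b = flat_idx[s]
        if b < 0:
            continue
        count[b] += 1
        c = count[b]
        for i in range(d):
            value_mean[i, b] += (values[s, i] - value_mean[i, b]) / c
            delta = forces[s, i] - mean[i, b]
            mean[i, b] += delta / c
            m2[i, b] += delta * (forces[s, i] - mean[i, b])
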