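"""Independent brute-force oracles used only by the tests.

The integrator here is a deliberately simple pure-Python fixed-step RK4
method of steps with linear interpolation of the delayed glucose history
— sharing no code with the package's integrators — so that agreement
between the two is evidence, not tautology.
"""

import math

import numpy as np

MGDL_PER_MM = 18.016


def reference_rk4(params, schedule, anchor, y0, t_end=240.0, dt=0.05):
    """Pure-Python method-of-steps RK4; returns (ts, Y[3, n])."""
    h_rise = params.h if params.h is not None else params.h1
    h_fall = params.h if params.h is not None else params.h2
    if params.h is not None:
        C1 = params.psi_scale
    else:
        r1 = (anchor.G_hyst / params.K) ** params.h1
        r2 = (anchor.G_hyst / params.K) ** params.h2
        C1 = params.psi_scale * (r1 / (1 + r1)) * ((1 + r2) / r2)
    yshift = math.exp(-params.k1 * anchor.G_hyst)
    rates = schedule.rates_mg_per_kg_min()
    block = schedule.block_min
    rate_end = schedule.t_end

    n = int(round(t_end / dt))
    ts = np.arange(n + 1) * dt
    G = np.empty(n + 1)
    I = np.empty(n + 1)
    A = np.empty(n + 1)
    G[0], I[0], A[0] = y0

    def g_hist(s, k):
        # linear interpolation over already-computed nodes
        if s <= 0:
            return y0[0]
        i = min(int(s / dt), k - 1)
        w = (s - ts[i]) / dt
        return G[i] * (1 - w) + G[i + 1] * w

    def f(t, g, i_, a, k):
        gd1 = (g_hist(t - params.tau1, k) if params.tau1 > 0 else g) / MGDL_PER_MM
        gd2 = (g_hist(t - params.tau2, k) if params.tau2 > 0 else g) / MGDL_PER_MM
        if t < anchor.t_hyst:
            r = (gd1 / params.K) ** h_rise
            psi = params.psi_scale * r / (1 + r)
            phi = math.exp(-params.k1 * gd2)
        else:
            r = (gd1 / params.K) ** h_fall
            psi = C1 * r / (1 + r)
            phi = math.exp(-params.k2 * gd2) + yshift
        tr = t - params.tau
        R = rates[min(int(tr / block), rates.size - 1)] \
            if 0 <= tr < rate_end else 0.0
        return (-(params.SG + params.a1 * i_) * g + params.a2 * a
                + R / params.V,
                -params.n1 * i_ + params.gamma1 * psi,
                -params.n2 * a + params.gamma2 * phi)

    for k in range(1, n + 1):
        t = ts[k - 1]
        g, i_, a = G[k - 1], I[k - 1], A[k - 1]
        d1 = f(t, g, i_, a, k)
        d2 = f(t + dt / 2, g + dt / 2 * d1[0], i_ + dt / 2 * d1[1],
               a + dt / 2 * d1[2], k)
        d3 = f(t + dt / 2, g + dt / 2 * d2[0], i_ + dt / 2 * d2[1],
               a + dt / 2 * d2[2], k)
        d4 = f(t + dt, g + dt * d3[0], i_ + dt * d3[1], a + dt * d3[2], k)
        G[k] = g + dt / 6 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
        I[k] = i_ + dt / 6 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
        A[k] = a + dt / 6 * (d1[2] + 2 * d2[2] + 2 * d3[2] + d4[2])
    return ts, np.vstack([G, I, A])


def brute_mann_whitney(x, y):
    """U by direct pair counting and exact two-sided p by enumerating
    every labeling of the pooled sample."""
    import itertools

    x = list(map(float, x))
    y = list(map(float, y))

    def u_of(a, b):
        u = 0.0
        for xi in a:
            for yj in b:
                if xi > yj:
                    u += 1.0
                elif xi == yj:
                    u += 0.5
        return u

    u_obs = u_of(x, y)
    pooled = x + y
    n = len(x)
    le = ge = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_of(a, b)
        total += 1
        if u <= u_obs + 1e-9:
            le += 1
        if u >= u_obs - 1e-9:
            ge += 1
    return u_obs, min(1.0, 2.0 * min(le / total, ge / total))
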