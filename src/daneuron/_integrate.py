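"""Compiled adaptive Runge–Kutta integration of the two neuron models.

A Dormand–Prince 5(4) stepper with proportional step control is compiled
with numba once per process and specialised for each model's right-hand
side.  Output is sampled on a fixed grid (cubic Hermite interpolation
between accepted steps) so that downstream threshold-crossing detection
never misses an oscillation.

The relaxation character of both models (fast voltage jumps between slow
branches) makes step sizes span several orders of magnitude within one
period; the adaptive controller handles this without a stiff solver.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 5(4) tableau
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    71.0 / 57600.0,
    -71.0 / 16695.0,
    71.0 / 1920.0,
    -17253.0 / 339200.0,
    22.0 / 525.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def _rhs_minimal(v, w, p, out):
    c = p[0]
    f = p[2] * (v * v * v + p[3] * v * v + p[4] * v + p[5])
    w4 = w * w * w * w
    k4 = p[8] * p[8] * p[8] * p[8]
    jk = p[6] * (p[7] - v) * w4 / (w4 + k4)
    gn = p[14] / (1.0 + p[10] * np.exp(-6.0 * v))
    js = gn * (p[11] - v) + p[13] * (p[12] - v)
    if w >= 0.0:
        g = v - p[9]
    else:
        g = 0.01 * (v - p[9]) - w
    out[0] = (f + jk + js) / c
    out[1] = p[1] * g / c


@njit(cache=True)
def _rhs_bio(v, ca, n, p, out):
    c_m = p[0]
    x = v + 50.0
    if abs(x) < 1e-9:
        alpha = 0.0032 * 5.0
    else:
        alpha = 0.0032 * x / (1.0 - np.exp(-x / 5.0))
    beta = 0.05 * np.exp(-(v + 55.0) / 40.0)
    rat = alpha / (alpha + beta)
    gca = p[1] * rat * rat * rat * rat
    i_ca = gca * (p[2] - v)
    ca4 = ca * ca * ca * ca
    k4 = p[4] * p[4] * p[4] * p[4]
    gkca = p[3] * ca4 / (ca4 + k4)
    n4 = n * n * n * n
    gk = p[6] / (1.0 + np.exp(-(v + 10.0) / 7.0))
    gnmda = p[12] / (1.0 + 0.1 * p[14] * np.exp(-0.062 * v))
    dv = (
        i_ca
        + (gkca + p[5] * n4 + gk) * (p[7] - v)
        + p[8] * (p[9] - v)
        + p[10] * (p[11] - v)
        + gnmda * (p[13] - v)
    ) / c_m
    dca = p[15] * i_ca - p[16] * ca
    ninf = 1.0 / (1.0 + np.exp(-(v - p[17]) / p[18]))
    s1 = 1.0 / (1.0 + np.exp((v - p[21]) / p[18]))
    s2 = 1.0 / (1.0 + np.exp((v - p[22]) / p[18]))
    tau = p[19] + p[20] * (s1 - s2)
    out[0] = dv
    out[1] = dca
    out[2] = (ninf - n) / tau
    # keep n in [0, 1]: the kinetics already do, but clip drift at the edges
    if n <= 0.0 and out[2] < 0.0 and ninf <= 0.0:
        out[2] = 0.0


def _build_integrator(rhs, dim):
    """Compile a DP5(4) integrator specialised for ``rhs`` (dim 2 or 3)."""

    @njit(cache=False)
    def integrate(p, y0, t0, t1, dt_out, rtol, atol, max_step):
        n_out = int(np.floor((t1 - t0) / dt_out + 1e-9)) + 1
        ts = np.empty(n_out)
        ys = np.empty((n_out, dim))
        for i in range(n_out):
            ts[i] = t0 + i * dt_out

        y = y0.copy()
        t = t0
        k1 = np.empty(dim)
        k2 = np.empty(dim)
        k3 = np.empty(dim)
        k4 = np.empty(dim)
        k5 = np.empty(dim)
        k6 = np.empty(dim)
        k7 = np.empty(dim)
        ytmp = np.empty(dim)
        ynew = np.empty(dim)

        if dim == 2:
            rhs(y[0], y[1], p, k1)
        else:
            rhs(y[0], y[1], y[2], p, k1)

        ys[0, :] = y
        i_out = 1

        h = dt_out * 0.1
        if h > max_step:
            h = max_step
        h_min = (t1 - t0) * 1e-14

        while t < t1 and i_out < n_out:
            if h > max_step:
                h = max_step
            if t + h > t1:
                h = t1 - t

            # stages
            for i in range(dim):
                ytmp[i] = y[i] + h * _A21 * k1[i]
            if dim == 2:
                rhs(ytmp[0], ytmp[1], p, k2)
            else:
                rhs(ytmp[0], ytmp[1], ytmp[2], p, k2)
            for i in range(dim):
                ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
            if dim == 2:
                rhs(ytmp[0], ytmp[1], p, k3)
            else:
                rhs(ytmp[0], ytmp[1], ytmp[2], p, k3)
            for i in range(dim):
                ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
            if dim == 2:
                rhs(ytmp[0], ytmp[1], p, k4)
            else:
                rhs(ytmp[0], ytmp[1], ytmp[2], p, k4)
            for i in range(dim):
                ytmp[i] = y[i] + h * (
                    _A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i]
                )
            if dim == 2:
                rhs(ytmp[0], ytmp[1], p, k5)
            else:
                rhs(ytmp[0], ytmp[1], ytmp[2], p, k5)
            for i in range(dim):
                ytmp[i] = y[i] + h * (
                    _A61 * k1[i]
                    + _A62 * k2[i]
                    + _A63 * k3[i]
                    + _A64 * k4[i]
                    + _A65 * k5[i]
                )
            if dim == 2:
                rhs(ytmp[0], ytmp[1], p, k6)
            else:
                rhs(ytmp[0], ytmp[1], ytmp[2], p, k6)
            for i in range(dim):
                ynew[i] = y[i] + h * (
                    _B1 * k1[i]
                    + _B3 * k3[i]
                    + _B4 * k4[i]
                    + _B5 * k5[i]
                    + _B6 * k6[i]
                )
            if dim == 2:
                rhs(ynew[0], ynew[1], p, k7)
            else:
                rhs(ynew[0], ynew[1], ynew[2], p, k7)

            # error estimate
            err = 0.0
            for i in range(dim):
                e = h * (
                    _E1 * k1[i]
                    + _E3 * k3[i]
                    + _E4 * k4[i]
                    + _E5 * k5[i]
                    + _E6 * k6[i]
                    + _E7 * k7[i]
                )
                sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
                err += (e / sc) ** 2
            err = np.sqrt(err / dim)

            finite = True
            for i in range(dim):
                if not np.isfinite(ynew[i]):
                    finite = False
            if not finite:
                return ts[:i_out], ys[:i_out], False, t

            if err <= 1.0:
                t_new = t + h
                # dense output: cubic Hermite on [t, t_new]
                while i_out < n_out and ts[i_out] <= t_new + 1e-30:
                    s = (ts[i_out] - t) / h
                    h00 = (1.0 + 2.0 * s) * (1.0 - s) * (1.0 - s)
                    h10 = s * (1.0 - s) * (1.0 - s)
                    h01 = s * s * (3.0 - 2.0 * s)
                    h11 = s * s * (s - 1.0)
                    for i in range(dim):
                        ys[i_out, i] = (
                            h00 * y[i]
                            + h10 * h * k1[i]
                            + h01 * ynew[i]
                            + h11 * h * k7[i]
                        )
                    i_out += 1
                t = t_new
                for i in range(dim):
                    y[i] = ynew[i]
                    k1[i] = k7[i]  # FSAL
                fac = 0.9 * err ** -0.2 if err > 1e-10 else 5.0
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                fac = 0.9 * err ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h *= fac
                if h < h_min:
                    return ts[:i_out], ys[:i_out], False, t

        return ts[:i_out], ys[:i_out], i_out == n_out, t

    return integrate


integrate_minimal = _build_integrator(_rhs_minimal, 2)
integrate_bio = _build_integrator(_rhs_bio, 3)
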