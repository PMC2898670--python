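"""Numba-compiled numerical kernels.

Everything here works on a flat parameter vector so that the same compiled
code serves all six model families:

    p = [alpha, beta, gamma, sigma, sigma_prime, delta, n, m]

and an integer design code (see models.Design).  The deterministic kernel is
a Dormand-Prince 5(4) adaptive step integrator with cubic-Hermite sampling on
a uniform output grid; the stochastic kernel is an exact Gillespie direct-
method simulation of the four birth/death channels realising each design.
The hand-written integrator exists purely for throughput: parameter sweeps
evaluate tens of thousands of trajectories, and per-call overhead of a
generic ODE driver dominates at that scale.  scipy.integrate remains the
cross-check in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# design codes (must match models.Design.code)
DESIGN_I = 0
DESIGN_II = 1
DESIGN_III = 2
SMOLEN = 3


@njit(cache=True)
def rhs(code, x, y, p):
    """Vector field (dx/dtau, dy/dtau) of one design at one state."""
    a, b, g, s, sp, d, n, m = p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7]
    xn = x ** n
    base = 1.0 + xn
    num = 1.0 + a * xn
    if code == DESIGN_I:
        fx = b * num / (base + s * y ** m)
        loss = x
    elif code == DESIGN_II:
        fx = b * num / base
        loss = x * (1.0 + sp * y)
    elif code == DESIGN_III:
        fx = b * (num / base) / (1.0 + s * y ** m)
        loss = x
    else:  # SMOLEN: both genes read the same competitively regulated promoter
        fx = b * num / (base + s * y ** m)
        loss = x
    dx = d * (fx - loss)
    if code == SMOLEN:
        py = d * g * num / (base + s * y ** m)
    else:
        py = d * g * num / base
    return dx, py - y


@njit(cache=True)
def jacobian(code, x, y, p):
    """Analytic 2x2 Jacobian of ``rhs`` (closed-form partial derivatives)."""
    a, b, g, s, sp, d, n, m = p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7]
    xn = x ** n
    base = 1.0 + xn
    num = 1.0 + a * xn
    # d(x^n)/dx, written to stay finite at x=0 for n>=1
    if n == 1.0:
        dxn = 1.0
    else:
        dxn = n * x ** (n - 1.0)
    if m == 1.0:
        dym = 1.0
    else:
        dym = m * y ** (m - 1.0)
    J = np.empty((2, 2))
    if code == DESIGN_I or code == SMOLEN:
        den = base + s * y ** m
        dfx_dx = b * dxn * (a * den - num) / (den * den)
        dfx_dy = -b * num * s * dym / (den * den)
        J[0, 0] = d * (dfx_dx - 1.0)
        J[0, 1] = d * dfx_dy
    elif code == DESIGN_II:
        dP = (a - 1.0) * dxn / (base * base)
        J[0, 0] = d * (b * dP - (1.0 + sp * y))
        J[0, 1] = -d * sp * x
    else:  # DESIGN_III
        rep = 1.0 + s * y ** m
        dP = (a - 1.0) * dxn / (base * base)
        J[0, 0] = d * (b * dP / rep - 1.0)
        J[0, 1] = -d * b * (num / base) * s * dym / (rep * rep)
    if code == SMOLEN:
        den = base + s * y ** m
        J[1, 0] = d * g * dxn * (a * den - num) / (den * den)
        J[1, 1] = -d * g * num * s * dym / (den * den) - 1.0
    else:
        dP = (a - 1.0) * dxn / (base * base)
        J[1, 0] = d * g * dP
        J[1, 1] = -1.0
    return J


@njit(cache=True)
def rhs_x_array(code, p, xs, ys):
    """dx/dtau along paired (x, y) arrays (1-D fixed-point reduction)."""
    out = np.empty(xs.size)
    for i in range(xs.size):
        dx, _ = rhs(code, xs[i], ys[i], p)
        out[i] = dx
    return out


# Dormand-Prince 5(4) coefficients
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0,
                                49.0 / 176.0, -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E1, _E3, _E4, _E5, _E6, _E7 = (71.0 / 57600.0, -71.0 / 16695.0, 71.0 / 1920.0,
                                -17253.0 / 339200.0, 22.0 / 525.0, -1.0 / 40.0)


@njit(cache=True)
def integrate(code, p, x0, y0, t_end, dt_out, rtol, atol):
    """Adaptive DP45 integration sampled on a uniform grid.

    Returns (t, x, y) with t = 0, dt_out, 2*dt_out, ... <= t_end.  Sample
    values inside an accepted step come from cubic Hermite interpolation
    using the step-end derivatives, so the sampling error is O(h^4) and
    does not limit period measurement.
    """
    n_out = int(t_end / dt_out) + 1
    ts = np.empty(n_out)
    xs = np.empty(n_out)
    ys = np.empty(n_out)
    ts[0] = 0.0
    xs[0] = x0
    ys[0] = y0
    t = 0.0
    x = x0
    y = y0
    k1x, k1y = rhs(code, x, y, p)
    h = 1e-4
    i_out = 1
    safety = 0.9
    max_steps = 100_000_000
    for _ in range(max_steps):
        if i_out >= n_out:
            break
        if t + h > t_end:
            h = t_end - t + 1e-15
        k2x, k2y = rhs(code, x + h * _A21 * k1x, y + h * _A21 * k1y, p)
        k3x, k3y = rhs(code, x + h * (_A31 * k1x + _A32 * k2x),
                       y + h * (_A31 * k1y + _A32 * k2y), p)
        k4x, k4y = rhs(code, x + h * (_A41 * k1x + _A42 * k2x + _A43 * k3x),
                       y + h * (_A41 * k1y + _A42 * k2y + _A43 * k3y), p)
        k5x, k5y = rhs(code, x + h * (_A51 * k1x + _A52 * k2x + _A53 * k3x + _A54 * k4x),
                       y + h * (_A51 * k1y + _A52 * k2y + _A53 * k3y + _A54 * k4y), p)
        k6x, k6y = rhs(code, x + h * (_A61 * k1x + _A62 * k2x + _A63 * k3x + _A64 * k4x + _A65 * k5x),
                       y + h * (_A61 * k1y + _A62 * k2y + _A63 * k3y + _A64 * k4y + _A65 * k5y), p)
        xn = x + h * (_B1 * k1x + _B3 * k3x + _B4 * k4x + _B5 * k5x + _B6 * k6x)
        yn = y + h * (_B1 * k1y + _B3 * k3y + _B4 * k4y + _B5 * k5y + _B6 * k6y)
        k7x, k7y = rhs(code, xn, yn, p)
        ex = h * (_E1 * k1x + _E3 * k3x + _E4 * k4x + _E5 * k5x + _E6 * k6x + _E7 * k7x)
        ey = h * (_E1 * k1y + _E3 * k3y + _E4 * k4y + _E5 * k5y + _E6 * k6y + _E7 * k7y)
        sx = atol + rtol * max(abs(x), abs(xn))
        sy = atol + rtol * max(abs(y), abs(yn))
        err = np.sqrt(0.5 * ((ex / sx) ** 2 + (ey / sy) ** 2))
        if err <= 1.0:
            t_new = t + h
            # emit all output points inside (t, t_new]
            while i_out < n_out and i_out * dt_out <= t_new + 1e-12:
                to = i_out * dt_out
                th = (to - t) / h if h > 0 else 0.0
                h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
                h10 = th * (1.0 - th) ** 2
                h01 = th * th * (3.0 - 2.0 * th)
                h11 = th * th * (th - 1.0)
                xo = h00 * x + h10 * h * k1x + h01 * xn + h11 * h * k7x
                yo = h00 * y + h10 * h * k1y + h01 * yn + h11 * h * k7y
                ts[i_out] = to
                xs[i_out] = xo if xo > 0.0 else 0.0
                ys[i_out] = yo if yo > 0.0 else 0.0
                i_out += 1
            t = t_new
            x = xn if xn > 0.0 else 0.0
            y = yn if yn > 0.0 else 0.0
            k1x, k1y = rhs(code, x, y, p)
            if t >= t_end:
                break
        fac = safety * err ** -0.2 if err > 1e-10 else 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-12:
            break
    return ts[:i_out], xs[:i_out], ys[:i_out]


@njit(cache=True)
def ssa(code, p, omega, x_counts0, y_counts0, t_end, dt_out, seed):
    """Gillespie direct-method sample of the design's jump process.

    Four channels: activator production (rate Omega*Delta*f(x,y)), activator
    loss (Delta*X*loss-factor), repressor production (Omega*Delta*gamma*g(x)),
    repressor loss (Y).  Concentrations are counts/Omega; time is in 1/delta_R
    units, matching the deterministic model in the Omega->inf limit.
    Returns counts sampled on a uniform grid; bit-reproducible given seed.
    """
    np.random.seed(seed)
    a, b, g, s, sp, d, n, m = p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7]
    n_out = int(t_end / dt_out) + 1
    xs = np.empty(n_out, dtype=np.int64)
    ys = np.empty(n_out, dtype=np.int64)
    X = x_counts0
    Y = y_counts0
    t = 0.0
    i_out = 0
    while True:
        x = X / omega
        y = Y / omega
        xn = x ** n
        base = 1.0 + xn
        num = 1.0 + a * xn
        if code == DESIGN_I or code == SMOLEN:
            fx = b * num / (base + s * y ** m)
        elif code == DESIGN_II:
            fx = b * num / base
        else:
            fx = b * (num / base) / (1.0 + s * y ** m)
        a1 = omega * d * fx
        if code == DESIGN_II:
            a2 = d * X * (1.0 + sp * y)
        else:
            a2 = d * X
        if code == SMOLEN:
            a3 = omega * d * g * num / (base + s * y ** m)
        else:
            a3 = omega * d * g * num / base
        a4 = float(Y)
        a0 = a1 + a2 + a3 + a4
        if a0 <= 0.0:
            # absorbing: fill remaining samples with the frozen state
            while i_out < n_out:
                xs[i_out] = X
                ys[i_out] = Y
                i_out += 1
            break
        dt = -np.log(np.random.random()) / a0
        t_next = t + dt
        while i_out < n_out and i_out * dt_out <= t_next:
            xs[i_out] = X
            ys[i_out] = Y
            i_out += 1
        if i_out >= n_out:
            break
        r = np.random.random() * a0
        if r < a1:
            X += 1
        elif r < a1 + a2:
            X -= 1
        elif r < a1 + a2 + a3:
            Y += 1
        else:
            Y -= 1
        t = t_next
    return xs, ys
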