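"""Compiled Dormand-Prince RK45 kernel for the time-varying linear CME.

The truncated generator is split as A(t) = A0 + g(t) * E, where A0
collects every reaction except the single signal-modulated switching
edge and E is that edge's generator at unit rate.  g(t) is the
instantaneous edge rate driven by the two-exponential signal.  Both
matrices are passed as CSR triplets so the right-hand side is two sparse
matvecs inside one jitted loop; the per-step Python overhead of generic
ODE drivers dominates at these dimensions, which is why the integrator
lives here.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# signal-edge modes
MODE_ENHANCE = 0
MODE_SUPPRESS_SAT = 1
MODE_SUPPRESS_LIN = 2


@njit(cache=False)
def _edge_rate(t, mode, k, b, r1, r2):
    s = np.exp(-r1 * t) * (1.0 - np.exp(-r2 * t))
    if mode == MODE_ENHANCE:
        return k + b * s
    if mode == MODE_SUPPRESS_SAT:
        return k / (1.0 + b * s)
    g = 1.0 - b * s
    return k * g if g > 0.0 else 0.0


@njit(cache=False)
def _rhs(t, p, out, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2):
    g = _edge_rate(t, mode, k, b, r1, r2)
    n = p.shape[0]
    for i in range(n):
        acc = 0.0
        for jj in range(A0p[i], A0p[i + 1]):
            acc += A0d[jj] * p[A0i[jj]]
        for jj in range(Ep[i], Ep[i + 1]):
            acc += g * Ed[jj] * p[Ei[jj]]
        out[i] = acc


@njit(cache=False)
def integrate_linear(A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2,
                     p0, t_eval, rtol, atol):
    """Integrate dp/dt = (A0 + g(t) E) p over ``t_eval`` (adaptive RK45).

    Returns (solution array of shape (len(t_eval), n), status) with
    status 0 on success, 1 if the step size underflowed.
    """
    n = p0.shape[0]
    m = t_eval.shape[0]
    out = np.empty((m, n))
    p = p0.copy()
    out[0] = p

    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n)
    k4 = np.empty(n); k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    y2 = np.empty(n)
    err = np.empty(n)

    t = t_eval[0]
    _rhs(t, p, k1, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2)
    h = 1.0
    status = 0

    for seg in range(1, m):
        tend = t_eval[seg]
        while t < tend:
            if h < 1e-10 * (1.0 + t):
                status = 1
                h = 1e-10 * (1.0 + t)
            hu = h if t + h <= tend else tend - t

            for i in range(n):
                y2[i] = p[i] + hu * (0.2 * k1[i])
            _rhs(t + 0.2 * hu, y2, k2, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2)
            for i in range(n):
                y2[i] = p[i] + hu * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
            _rhs(t + 0.3 * hu, y2, k3, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2)
            for i in range(n):
                y2[i] = p[i] + hu * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i]
                                     + 32.0 / 9.0 * k3[i])
            _rhs(t + 0.8 * hu, y2, k4, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2)
            for i in range(n):
                y2[i] = p[i] + hu * (19372.0 / 6561.0 * k1[i] - 25360.0 / 2187.0 * k2[i]
                                     + 64448.0 / 6561.0 * k3[i] - 212.0 / 729.0 * k4[i])
            _rhs(t + 8.0 / 9.0 * hu, y2, k5, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2)
            for i in range(n):
                y2[i] = p[i] + hu * (9017.0 / 3168.0 * k1[i] - 355.0 / 33.0 * k2[i]
                                     + 46732.0 / 5247.0 * k3[i] + 49.0 / 176.0 * k4[i]
                                     - 5103.0 / 18656.0 * k5[i])
            _rhs(t + hu, y2, k6, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2)
            # 5th-order solution (FSAL)
            for i in range(n):
                y2[i] = p[i] + hu * (35.0 / 384.0 * k1[i] + 500.0 / 1113.0 * k3[i]
                                     + 125.0 / 192.0 * k4[i] - 2187.0 / 6784.0 * k5[i]
                                     + 11.0 / 84.0 * k6[i])
            _rhs(t + hu, y2, k7, A0d, A0i, A0p, Ed, Ei, Ep, mode, k, b, r1, r2)

            # embedded error estimate
            nrm = 0.0
            for i in range(n):
                e = hu * (71.0 / 57600.0 * k1[i] - 71.0 / 16695.0 * k3[i]
                          + 71.0 / 1920.0 * k4[i] - 17253.0 / 339200.0 * k5[i]
                          + 22.0 / 525.0 * k6[i] - 1.0 / 40.0 * k7[i])
                ay = abs(p[i])
                ay2 = abs(y2[i])
                sc = atol + rtol * (ay if ay > ay2 else ay2)
                q = e / sc
                nrm += q * q
            nrm = np.sqrt(nrm / n)

            if nrm <= 1.0 or status == 1:
                t = t + hu
                for i in range(n):
                    p[i] = y2[i]
                    k1[i] = k7[i]
                if nrm > 1e-30:
                    fac = 0.9 * nrm ** (-0.2)
                else:
                    fac = 5.0
                if fac > 5.0:
                    fac = 5.0
                if fac < 0.2:
                    fac = 0.2
                h = hu * fac
            else:
                fac = 0.9 * nrm ** (-0.2)
                if fac < 0.1:
                    fac = 0.1
                h = hu * fac
        out[seg] = p
    return out, status
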