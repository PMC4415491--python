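"""Compiled fixed-step RK4 kernel for the nonlinear PD model.

The model is packed into flat arrays so one jitted kernel serves every
condition (knockouts, conductance scalings) without recompilation. Column
layout of the per-channel parameter matrix P (one row per channel):

  0 gbar, 1 reversal, 2 r, 3 q, 4 calcium_coupled, 5 ca_half,
  6..11 activation  (half, slope, tau_base, tau_amp, tau_half, tau_slope),
  12..17 inactivation (same order; unused when q == 0),
  18 drives_calcium (1.0 for the CaT/CaS currents feeding the [Ca] pool).

State vector: [V, gating (activation then inactivation per channel), Ca].
Stimulus samples are taken literally at the step endpoints and averaged at
the half-step (linear interpolation on the shared uniform grid).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .model import PDModelParams, gating_names

__all__ = ["pack_params", "rk4_run", "rhs_packed"]


def pack_params(params: PDModelParams):
    n = len(params.channels)
    P = np.zeros((n, 19))
    m_idx = np.zeros(n, dtype=np.int64)
    h_idx = np.full(n, -1, dtype=np.int64)
    j = 1  # state index 0 is V
    for i, c in enumerate(params.channels):
        a = c.activation
        P[i, 0] = c.gbar
        P[i, 1] = params.reversal_of(c)
        P[i, 2] = c.activation_exponent
        P[i, 3] = c.inactivation_exponent
        P[i, 4] = 1.0 if c.calcium_coupled else 0.0
        P[i, 5] = c.ca_half
        P[i, 6:12] = (
            a.half_voltage,
            a.slope,
            a.tau_base,
            a.tau_amplitude,
            a.tau_half_voltage,
            a.tau_slope,
        )
        P[i, 18] = 1.0 if c.reversal is None else 0.0
        m_idx[i] = j
        j += 1
        if c.inactivation is not None:
            b = c.inactivation
            P[i, 12:18] = (
                b.half_voltage,
                b.slope,
                b.tau_base,
                b.tau_amplitude,
                b.tau_half_voltage,
                b.tau_slope,
            )
            h_idx[i] = j
            j += 1
    cal = params.calcium
    scal = np.array([params.C, params.g_leak, params.E_leak, cal.F, cal.tau_Ca, cal.C0])
    nvar = 2 + len(gating_names(params))
    return P, m_idx, h_idx, scal, nvar


@njit(cache=False)
def _sig(x):
    if x >= 0.0:
        z = np.exp(-x)
        return z / (1.0 + z)
    return 1.0 / (1.0 + np.exp(x))


@njit(cache=False)
def rhs_packed(y, I_inp, P, m_idx, h_idx, scal):
    C, gL, EL, F, tauCa, C0 = scal[0], scal[1], scal[2], scal[3], scal[4], scal[5]
    V = y[0]
    Ca = y[y.shape[0] - 1]
    dy = np.zeros_like(y)
    I_total = gL * (V - EL)
    I_ca = 0.0
    for i in range(P.shape[0]):
        gbar, E = P[i, 0], P[i, 1]
        r = int(P[i, 2])
        q = int(P[i, 3])
        m = y[m_idx[i]]
        g = gbar
        for _ in range(r):
            g *= m
        if q == 1:
            g *= y[h_idx[i]]
        I = g * (V - E)
        I_total += I
        if P[i, 18] == 1.0:
            I_ca += I
        m_inf = _sig((V - P[i, 6]) / P[i, 7])
        if P[i, 4] == 1.0:
            m_inf *= Ca / (Ca + P[i, 5])
        tau_m = P[i, 8] + P[i, 9] * _sig((V - P[i, 10]) / P[i, 11])
        dy[m_idx[i]] = (m_inf - m) / tau_m
        if q == 1:
            h_inf = _sig((V - P[i, 12]) / P[i, 13])
            tau_h = P[i, 14] + P[i, 15] * _sig((V - P[i, 16]) / P[i, 17])
            dy[h_idx[i]] = (h_inf - y[h_idx[i]]) / tau_h
    dy[0] = (-I_total + I_inp) / C
    dy[y.shape[0] - 1] = (-F * I_ca - Ca + C0) / tauCa
    return dy


@njit(cache=False)
def rk4_run(y0, I, dt, P, m_idx, h_idx, scal):
    n = I.shape[0]
    nv = y0.shape[0]
    Y = np.empty((n, nv))
    y = y0.copy()
    for k in range(n):
        for j in range(nv):
            Y[k, j] = y[j]
        Ia = I[k]
        if k == n - 1:
            Ib = Ia
            Ic = Ia
        else:
            Ic = I[k + 1]
            Ib = 0.5 * (Ia + Ic)
        k1 = rhs_packed(y, Ia, P, m_idx, h_idx, scal)
        k2 = rhs_packed(y + 0.5 * dt * k1, Ib, P, m_idx, h_idx, scal)
        k3 = rhs_packed(y + 0.5 * dt * k2, Ib, P, m_idx, h_idx, scal)
        k4 = rhs_packed(y + dt * k3, Ic, P, m_idx, h_idx, scal)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if not np.isfinite(y[0]):
            return Y[: k + 1]
    return Y
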