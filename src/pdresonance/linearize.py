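"""Quasi-active linearization: the equivalent RLC circuit of the PD model.

Around an equilibrium (V*, x*, [Ca]*), each first-order gating variable
contributes an admittance term of the form a/(p + b) (p the differential
operator), which is electrically a series resistor–inductor branch with
L = 1/a and R = b/a, in parallel with the channel's instantaneous
conductance gbar·m*^r·h*^q. For a gating variable x with time constant
tau_x and steady-state slope dx_inf/dV,

    a = gbar · (d g/d x)|_* · (V* - E) · (1/tau_x) · dx_inf/dV,   b = 1/tau_x.

The KCa channel couples to the calcium pool: a perturbation of the calcium
currents perturbs [Ca] through the buffered-pool transfer
delta[Ca] = -F·(1/tau_Ca)/(p + 1/tau_Ca) · delta(I_CaT + I_CaS), which then
moves the KCa activation. Composing this path with the CaT/CaS admittances
yields a rational admittance with five simple poles — 1/tau_mKCa, 1/tau_Ca,
and the three calcium-channel gating rates — whose partial-fraction residues
define the five KCa branches (labels KCa1..KCa5, ordered as in the published
component table: voltage pole, calcium pole, CaS activation, CaT
inactivation, CaT activation).

Because the linearization is the exact Jacobian of the nonlinear model, the
circuit's DC input conductance equals the slope of the steady-state I–V
curve, and its impedance matches the small-signal chirp response.

Internal units: conductance µS, resistance MΩ, time ms, so inductance is
MΩ·ms. The published component table prints values 10^6 larger than these
(its resistances are gigaohms and its inductances gigahenries in absolute
per-cell units); ``printed_scale`` converts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .integrator import EquilibriumState, find_equilibrium
from .model import ChannelSpec, GatingKinetics, PDModelParams

__all__ = [
    "RLBranch",
    "LinearCircuit",
    "linearize_channel",
    "assemble_linear_circuit",
    "analytic_impedance",
    "simulate_linear",
    "classify_branch",
    "printed_scale",
    "component_table",
]


class LinearizationError(ValueError):
    pass


class SingularityError(ZeroDivisionError):
    pass


@dataclass(frozen=True)
class RLBranch:
    """A series R–L branch: admittance 1/(R + pL) = a/(p + b) with
    a = 1/L, b = R/L. Negative (R, L) pairs mark amplifying (positive
    feedback) pathways."""

    label: str
    R: float  # MΩ
    L: float  # MΩ·ms

    @property
    def slope(self) -> float:
        """Admittance slope a = 1/L (µS/ms)."""
        return 1.0 / self.L

    @property
    def pole(self) -> float:
        """Pole rate b = R/L (1/ms)."""
        return self.R / self.L

    @property
    def dc_conductance(self) -> float:
        return 1.0 / self.R

    def admittance(self, p: complex) -> complex:
        return 1.0 / (self.R + p * self.L)


@dataclass
class LinearCircuit:
    """Membrane capacitance in parallel with instantaneous conductances
    (leak plus each channel's gbar·m*^r·h*^q) and series-RL branches."""

    C: float  # nF
    conductances: list[tuple[str, float]]  # (label, µS)
    branches: list[RLBranch]
    V_star: float = float("nan")  # equilibrium the circuit was derived at

    @property
    def g_instantaneous(self) -> float:
        return sum(g for _, g in self.conductances)

    def dc_conductance(self) -> float:
        """Input conductance at DC: inductors are shorts, so each branch
        contributes 1/R."""
        return self.g_instantaneous + sum(b.dc_conductance for b in self.branches)

    def branch(self, label: str) -> RLBranch:
        for b in self.branches:
            if b.label == label:
                return b
        raise KeyError(label)

    def system_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """State-space (A, B) for x = [v, I_1..I_n]:
        C dv/dt = -g v - sum I_y + I_inp;  L_y dI_y/dt = v - R_y I_y."""
        n = len(self.branches)
        A = np.zeros((n + 1, n + 1))
        B = np.zeros(n + 1)
        A[0, 0] = -self.g_instantaneous / self.C
        A[0, 1:] = -1.0 / self.C
        B[0] = 1.0 / self.C
        for i, b in enumerate(self.branches, start=1):
            A[i, 0] = 1.0 / b.L
            A[i, i] = -b.R / b.L
        return A, B


def _dsigmoid_dV(k: GatingKinetics, V: float) -> float:
    s = k.steady_state(V)
    return -s * (1.0 - s) / k.slope


def _check_consistent(eq: EquilibriumState, params: PDModelParams) -> None:
    ref = find_equilibrium(params, eq.V_star)
    if abs(ref.Ca_star - eq.Ca_star) > 1e-9 * max(1.0, abs(ref.Ca_star)):
        raise LinearizationError("equilibrium inconsistent with parameters (Ca*)")
    for k, v in ref.gating_star.items():
        if k not in eq.gating_star or abs(eq.gating_star[k] - v) > 1e-9:
            raise LinearizationError(f"equilibrium inconsistent with parameters ({k})")


def _voltage_branches(
    channel: ChannelSpec, eq: EquilibriumState, params: PDModelParams
) -> tuple[float, list[RLBranch]]:
    """Instantaneous conductance and gating branches of a purely
    voltage-gated channel (also the voltage pathway of KCa)."""
    V = eq.V_star
    E = params.reversal_of(channel)
    r, q = channel.activation_exponent, channel.inactivation_exponent
    m = eq.gating_star[f"m_{channel.name}"]
    h = eq.gating_star.get(f"h_{channel.name}", 1.0)
    g_inst = channel.gbar * m**r * (h if q else 1.0)
    branches: list[RLBranch] = []

    tau_m = channel.activation.time_constant(V)
    if channel.calcium_coupled:
        caf = eq.Ca_star / (eq.Ca_star + channel.ca_half)
        dm_dV = caf * _dsigmoid_dV(channel.activation, V)
    else:
        dm_dV = _dsigmoid_dV(channel.activation, V)
    a_m = channel.gbar * r * m ** (r - 1) * (h if q else 1.0) * (V - E) * dm_dV / tau_m
    label = "KCa1" if channel.calcium_coupled else f"m_{channel.name}"
    if a_m != 0.0:
        branches.append(RLBranch(label, R=(1.0 / tau_m) / a_m, L=1.0 / a_m))

    if channel.inactivation is not None:
        tau_h = channel.inactivation.time_constant(V)
        dh_dV = _dsigmoid_dV(channel.inactivation, V)
        a_h = channel.gbar * m**r * (V - E) * dh_dV / tau_h
        if a_h != 0.0:
            branches.append(
                RLBranch(f"h_{channel.name}", R=(1.0 / tau_h) / a_h, L=1.0 / a_h)
            )
    return g_inst, branches


def _calcium_gating_terms(
    params: PDModelParams, eq: EquilibriumState
) -> tuple[float, list[tuple[str, float, float]]]:
    """DC conductance and (label, a, b) admittance terms of delta(I_Ca)/delta(V).

    Ordered as the published KCa branch numbering expects: channels without
    inactivation first (CaS), then inactivation before activation (h_CaT,
    m_CaT).
    """
    g0 = 0.0
    terms: list[tuple[str, float, float]] = []
    ca_channels = [c for c in params.channels if c.reversal is None and c.gbar > 0]
    for c in ca_channels:
        g_inst, brs = _voltage_branches(c, eq, params)
        g0 += g_inst
        for b in brs:
            terms.append((b.label, b.slope, b.pole))
    order = {"m_CaS": 0, "h_CaT": 1, "m_CaT": 2}
    terms.sort(key=lambda t: order.get(t[0], 99))
    return g0, terms


def _kca_branches(
    channel: ChannelSpec, eq: EquilibriumState, params: PDModelParams
) -> tuple[float, list[RLBranch]]:
    """Instantaneous conductance and the five branches of the KCa channel.

    KCa1 is the direct voltage pathway (pole 1/tau_mKCa); KCa2..KCa5 come
    from the calcium-feedback path, whose admittance is

      Y_fb(p) = -K0 / ((p+alpha)(p+gamma)) * [gCa0 + sum_x a_x/(p+b_x)],
      K0 = gbar_K·4·mK*³·(V*-E_K)·alpha·(dmK_inf/dCa)·F·gamma,

    expanded in partial fractions over the simple poles alpha = 1/tau_mKCa,
    gamma = 1/tau_Ca and the calcium-channel gating poles b_x. Residues at
    alpha add to the KCa1 branch.
    """
    V = eq.V_star
    E = params.reversal_of(channel)
    cal = params.calcium
    g_inst, v_branches = _voltage_branches(channel, eq, params)
    mK = eq.gating_star[f"m_{channel.name}"]
    alpha = 1.0 / channel.activation.time_constant(V)
    gamma = 1.0 / cal.tau_Ca
    if abs(alpha - gamma) < 1e-12 * max(alpha, gamma):
        raise LinearizationError("coincident poles tau_mKCa and tau_Ca")
    dmK_dCa = (
        channel.ca_half
        / (eq.Ca_star + channel.ca_half) ** 2
        * channel.activation.steady_state(V)
    )
    W = channel.gbar * channel.activation_exponent * mK ** (
        channel.activation_exponent - 1
    ) * (V - E)
    K0 = W * alpha * dmK_dCa * cal.F * gamma

    g0_ca, gating_terms = _calcium_gating_terms(params, eq)

    res_alpha = -K0 * g0_ca / (gamma - alpha)
    res_gamma = -K0 * g0_ca / (alpha - gamma)
    tail: list[tuple[float, float]] = []  # (residue, pole)
    for _, a_x, b_x in gating_terms:
        for b_other in (alpha, gamma):
            if abs(b_x - b_other) < 1e-12 * max(b_x, b_other):
                raise LinearizationError("coincident gating and feedback poles")
        res_alpha += -K0 * a_x / ((gamma - alpha) * (b_x - alpha))
        res_gamma += -K0 * a_x / ((alpha - gamma) * (b_x - gamma))
        tail.append((-K0 * a_x / ((alpha - b_x) * (gamma - b_x)), b_x))

    # fold the feedback residue at alpha into the voltage branch KCa1
    a1 = (v_branches[0].slope if v_branches else 0.0) + res_alpha
    branches: list[RLBranch] = []
    if a1 != 0.0:
        branches.append(RLBranch("KCa1", R=alpha / a1, L=1.0 / a1))
    if res_gamma != 0.0:
        branches.append(RLBranch("KCa2", R=gamma / res_gamma, L=1.0 / res_gamma))
    for i, (res, pole) in enumerate(tail, start=3):
        if res != 0.0:
            branches.append(RLBranch(f"KCa{i}", R=pole / res, L=1.0 / res))
    return g_inst, branches


def linearize_channel(
    channel: ChannelSpec, eq: EquilibriumState, params: PDModelParams
) -> tuple[float, list[RLBranch]]:
    """Linearize one channel at an equilibrium.

    Returns the instantaneous conductance gbar·m*^r·h*^q (µS) and the
    series-RL branches of the gating pathways.
    """
    _check_consistent(eq, params)
    if channel.calcium_coupled:
        return _kca_branches(channel, eq, params)
    return _voltage_branches(channel, eq, params)


def assemble_linear_circuit(
    params: PDModelParams, eq: EquilibriumState
) -> LinearCircuit:
    """Parallel combination of C, leak, all instantaneous conductances and
    all RL branches (nine branches for the full control model)."""
    _check_consistent(eq, params)
    conds: list[tuple[str, float]] = [("leak", params.g_leak)]
    branches: list[RLBranch] = []
    for c in params.channels:
        if c.gbar == 0:
            continue
        g_inst, brs = linearize_channel(c, eq, params)
        conds.append((c.name, g_inst))
        branches.extend(brs)
    return LinearCircuit(
        C=params.C, conductances=conds, branches=branches, V_star=eq.V_star
    )


def analytic_impedance(circuit: LinearCircuit, f) -> complex | np.ndarray:
    """Closed-form impedance Z(f) in MΩ at frequency f in Hz (scalar or
    array): Z = 1/(j 2πf C + Σg + Σ 1/(R_y + j 2πf L_y))."""
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr < 0):
        raise ValueError("frequency must be non-negative")
    p = 1j * 2.0 * np.pi * f_arr * 1e-3  # rad/ms
    Y = p * circuit.C + circuit.g_instantaneous
    for b in circuit.branches:
        Y = Y + 1.0 / (b.R + p * b.L)
    if np.any(Y == 0):
        raise SingularityError("impedance pole at requested frequency")
    Z = 1.0 / Y
    return complex(Z) if np.isscalar(f) else Z


_RK4_TOL = 1e-9


def rk4_stable(circuit: LinearCircuit, dt: float) -> bool:
    """Check that every eigenvalue of the circuit's system matrix lies in
    the RK4 absolute-stability region at step dt."""
    A, _ = circuit.system_matrices()
    z = np.linalg.eigvals(A) * dt
    growth = 1 + z + z**2 / 2 + z**3 / 6 + z**4 / 24
    return bool(np.all(np.abs(growth) <= 1 + _RK4_TOL))


def simulate_linear(
    circuit: LinearCircuit, t: np.ndarray, I_inp: np.ndarray
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """RK4 integration of the circuit from rest.

    Returns (t, v, branch_currents) where v is the voltage deviation from
    the equilibrium (mV) and branch currents are in nA. Raises if the step
    is outside the RK4 stability region (possible with negative elements).
    """
    t = np.asarray(t, dtype=float)
    I_inp = np.asarray(I_inp, dtype=float)
    if t.shape != I_inp.shape:
        raise ValueError("time grid and stimulus must have equal length")
    dts = np.diff(t)
    if len(dts) == 0 or not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        raise ValueError("stimulus grid must be uniform")
    dt = float(dts[0])
    if not rk4_stable(circuit, dt):
        raise RuntimeError(
            "linear circuit unstable under RK4 at this step; reduce dt"
        )
    A, B = circuit.system_matrices()
    n = len(t)
    nv = A.shape[0]
    X = np.empty((n, nv))
    x = np.zeros(nv)
    for k in range(n):
        X[k] = x
        Ia = I_inp[k]
        Ic = I_inp[k + 1] if k < n - 1 else Ia
        Ib = 0.5 * (Ia + Ic)
        k1 = A @ x + B * Ia
        k2 = A @ (x + 0.5 * dt * k1) + B * Ib
        k3 = A @ (x + 0.5 * dt * k2) + B * Ib
        k4 = A @ (x + dt * k3) + B * Ic
        x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    currents = {b.label: X[:, i + 1] for i, b in enumerate(circuit.branches)}
    return t, X[:, 0], currents


def classify_branch(branch: RLBranch) -> str:
    """Resonator (negative feedback, inductive) vs amplifier (positive
    feedback, capacitor-like); mixed-sign elements are unclassified."""
    if not (math.isfinite(branch.R) and math.isfinite(branch.L)):
        raise ValueError("branch elements must be finite")
    if branch.R > 0 and branch.L >= 0:
        return "resonator"
    if branch.R < 0 and branch.L < 0:
        return "amplifier"
    return "unclassified"


def printed_scale(value: float, kind: str) -> float:
    """Convert internal units to the published component-table scale.

    kind='R': MΩ -> GΩ (numerically the table's 'MΩ' column);
    kind='L': MΩ·ms -> GΩ·s = GH (numerically the table's 'H' column).
    """
    if kind == "R":
        return value / 1e3
    if kind == "L":
        return value / 1e6
    raise ValueError(kind)


def component_table(circuit: LinearCircuit):
    """Component table mirroring the published layout, one row per element,
    values on the published scale (resistances GΩ, inductances GH)."""
    import pandas as pd

    rows = []
    for label, g in circuit.conductances:
        if label == "leak":
            rows.append(("leak", "R_leak", printed_scale(1.0 / g, "R"), "GOhm"))
        else:
            rows.append((label, f"R_{label}0", printed_scale(1.0 / g, "R"), "GOhm"))
    for b in circuit.branches:
        chan = b.label.split("_")[-1] if "_" in b.label else "KCa"
        rows.append((chan, f"R_{b.label}", printed_scale(b.R, "R"), "GOhm"))
        rows.append((chan, f"L_{b.label}", printed_scale(b.L, "L"), "GH"))
    return pd.DataFrame(rows, columns=["channel", "component", "value", "units"])
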