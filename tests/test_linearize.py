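import math

import numpy as np
import pytest

from pdresonance import (
    RLBranch,
    analytic_impedance,
    assemble_linear_circuit,
    chirp_current,
    classify_branch,
    find_equilibrium,
    linearize_channel,
    simulate_linear,
)
from pdresonance.linearize import (
    LinearizationError,
    component_table,
    printed_scale,
    rk4_stable,
)
from pdresonance.model import steady_state_current
from pdresonance.stimuli import ChirpSpec

FULL_LABELS = {
    "m_h", "m_CaT", "h_CaT", "m_CaS",
    "KCa1", "KCa2", "KCa3", "KCa4", "KCa5",
}


def direct_admittance(params, V, p):
    """Independent oracle: the small-signal membrane admittance assembled
    directly from transfer-function products (no partial fractions)."""
    sig = lambda x: 1.0 / (1.0 + math.exp(x))

    def kin(k, V):
        x = sig((V - k.half_voltage) / k.slope)
        tau = k.tau_base + k.tau_amplitude * sig((V - k.tau_half_voltage) / k.tau_slope)
        dx = -x * (1 - x) / k.slope
        return x, tau, dx

    cal = params.calcium
    # calcium fixed point, recomputed here
    I_ca = 0.0
    for c in params.channels:
        if c.reversal is not None:
            continue
        m, tm, dm = kin(c.activation, V)
        g = c.gbar * m**c.activation_exponent
        if c.inactivation is not None:
            h, _, _ = kin(c.inactivation, V)
            g *= h
        I_ca += g * (V - params.E_Ca)
    Ca = cal.C0 - cal.F * I_ca

    def Y_channel(c):
        E = params.E_Ca if c.reversal is None else c.reversal
        r, q = c.activation_exponent, c.inactivation_exponent
        m, tm, dm = kin(c.activation, V)
        if c.calcium_coupled:
            caf = Ca / (Ca + c.ca_half)
            m, dm = caf * m, caf * dm
        h = 1.0
        if c.inactivation is not None:
            h, th, dh = kin(c.inactivation, V)
        Y = c.gbar * m**r * h  # instantaneous
        Y += c.gbar * r * m ** (r - 1) * h * (V - E) * dm / tm / (p + 1 / tm)
        if c.inactivation is not None:
            Y += c.gbar * m**r * (V - E) * dh / th / (p + 1 / th)
        return Y

    Y = params.g_leak + p * params.C
    for c in params.channels:
        if c.gbar == 0:
            continue
        Y += Y_channel(c)
        if c.calcium_coupled:
            # calcium-feedback path: T_m * dm/dCa * T_Ca * (dI_Ca/dV)
            m, tm, dm = kin(c.activation, V)
            caf = Ca / (Ca + c.ca_half)
            mK = caf * m
            dm_dCa = c.ca_half / (Ca + c.ca_half) ** 2 * m
            W = c.gbar * c.activation_exponent * mK ** (c.activation_exponent - 1) * (
                V - c.reversal
            )
            T_m = (1 / tm) / (p + 1 / tm)
            T_ca = -cal.F * (1 / cal.tau_Ca) / (p + 1 / cal.tau_Ca)
            Y_ca = sum(
                Y_channel(cc)
                for cc in params.channels
                if cc.reversal is None and cc.gbar > 0
            )
            Y += W * T_m * dm_dCa * T_ca * Y_ca
    return Y


class TestBranchAlgebra:
    def test_partial_fractions_match_direct_transfer(self, control, eq55, circuit55):
        """The branch decomposition must reproduce the channel admittances
        evaluated as raw transfer-function products."""
        rng = np.random.default_rng(7)
        freqs = rng.uniform(0.01, 10.0, size=20)
        for f in freqs:
            p = 1j * 2 * np.pi * f * 1e-3
            Y_circ = 1.0 / analytic_impedance(circuit55, f)
            Y_ref = direct_admittance(control, eq55.V_star, p)
            assert abs(Y_circ - Y_ref) / abs(Y_ref) < 1e-10

    def test_branch_rl_round_trip(self):
        b = RLBranch("x", R=17.7, L=5.3)
        p = 1j * 0.4
        assert b.admittance(p) == pytest.approx(
            b.slope / (p + b.pole), rel=1e-14
        )

    def test_flat_steady_state_gives_pure_conductance(self, control, eq55):
        """A gating variable with zero voltage sensitivity contributes no
        RL branch, only its instantaneous conductance."""
        from dataclasses import replace

        from pdresonance.model import GatingKinetics

        flat = GatingKinetics(-55.0, 1e12, 50.0, 0.0, -55.0, 1.0)  # dm/dV ~ 0
        chan = replace(control.channel("h"), activation=flat)
        params = replace(
            control, channels=tuple(
                chan if c.name == "h" else c for c in control.channels
            )
        )
        eq = find_equilibrium(params, -55.0)
        g, branches = linearize_channel(params.channel("h"), eq, params)
        assert g > 0
        assert all(abs(b.slope) < 1e-12 for b in branches)


class TestAssembly:
    def test_full_model_has_nine_labelled_branches(self, circuit55):
        assert {b.label for b in circuit55.branches} == FULL_LABELS
        assert len(circuit55.branches) == 9
        assert dict(circuit55.conductances).keys() == {
            "leak", "h", "CaT", "CaS", "KCa"
        }

    def test_h_knockout_removes_only_its_branch(self, control, eq55, circuit55):
        p0 = control.scale_gbar({"h": 0.0})
        circ = assemble_linear_circuit(p0, find_equilibrium(p0, -55.0))
        assert {b.label for b in circ.branches} == FULL_LABELS - {"m_h"}
        for b in circ.branches:
            ref = circuit55.branch(b.label)
            assert b.R == pytest.approx(ref.R, rel=1e-12)
            assert b.L == pytest.approx(ref.L, rel=1e-12)

    def test_kca_knockout_equals_branch_deletion(self, control, eq55, circuit55):
        p0 = control.scale_gbar({"KCa": 0.0})
        circ = assemble_linear_circuit(p0, find_equilibrium(p0, -55.0))
        kept = {b.label for b in circ.branches}
        assert kept == {"m_h", "m_CaT", "h_CaT", "m_CaS"}
        for b in circ.branches:
            assert b.R == pytest.approx(circuit55.branch(b.label).R, rel=1e-12)

    def test_dc_conductance_matches_iv_slope(self, control, circuit55):
        h = 1e-4
        slope = (
            steady_state_current(control, -55.0 + h)
            - steady_state_current(control, -55.0 - h)
        ) / (2 * h)
        assert circuit55.dc_conductance() == pytest.approx(slope, rel=1e-6)

    def test_mismatched_equilibrium_rejected(self, control):
        eq = find_equilibrium(control, -55.0)
        other = control.scale_gbar({"CaS": 0.5})
        with pytest.raises(LinearizationError):
            assemble_linear_circuit(other, eq)

    def test_sign_structure_at_rest(self, circuit55):
        """Calcium activation branches are amplifiers (V*-E_Ca < 0); every
        branch has matching R and L signs."""
        for b in circuit55.branches:
            assert (b.R > 0) == (b.L > 0), b.label
        assert circuit55.branch("m_CaT").R < 0
        assert circuit55.branch("m_CaS").R < 0
        for label in ("m_h", "h_CaT", "KCa2", "KCa3", "KCa4", "KCa5"):
            assert circuit55.branch(label).R > 0, label


class TestImpedanceAndSimulation:
    def test_dc_impedance_is_real_resistance(self, circuit55):
        Z0 = analytic_impedance(circuit55, 0.0)
        assert Z0.imag == 0.0
        assert Z0.real == pytest.approx(1.0 / circuit55.dc_conductance(), rel=1e-12)

    def test_capacitive_asymptote(self, circuit55):
        f = 1e6
        assert abs(analytic_impedance(circuit55, f)) == pytest.approx(
            1.0 / (2 * np.pi * f * 1e-3 * circuit55.C), rel=1e-3
        )

    def test_zero_stimulus_zero_response(self, circuit55):
        t = np.arange(0.0, 100.0, 0.05)
        _, v, cur = simulate_linear(circuit55, t, np.zeros_like(t))
        assert np.all(v == 0.0)
        assert all(np.all(c == 0.0) for c in cur.values())

    def test_rc_step_closed_form(self):
        from pdresonance.linearize import LinearCircuit

        circ = LinearCircuit(C=1.0, conductances=[("leak", 0.05)], branches=[])
        t = np.arange(0.0, 200.0, 0.05)
        I = np.full_like(t, 0.2)
        _, v, _ = simulate_linear(circ, t, I)
        expected = (0.2 / 0.05) * (1 - np.exp(-t * 0.05 / 1.0))
        assert np.abs(v - expected).max() < 1e-6

    def test_chirp_fft_matches_closed_form(self, circuit55):
        from pdresonance.impedance import impedance_profile

        spec = ChirpSpec()
        t, I = chirp_current(spec)
        n_tail = int(round(5000.0 / spec.dt))  # 5 s settle so the record is complete
        t = np.concatenate([t, t[-1] + spec.dt * np.arange(1, n_tail + 1)])
        I = np.concatenate([I, np.zeros(n_tail)])
        _, v, _ = simulate_linear(circuit55, t, I)
        prof = impedance_profile(v, I, dt=spec.dt)
        sel = (prof.f >= 0.1) & (prof.f <= 5.0)
        Za = np.abs(analytic_impedance(circuit55, prof.f[sel]))
        assert np.max(np.abs(prof.magnitude[sel] - Za) / Za) < 0.01

    def test_unstable_step_detected(self, circuit55):
        assert rk4_stable(circuit55, 0.05)
        assert not rk4_stable(circuit55, 1e4)
        t = np.arange(0.0, 10.0 * 1e4, 1e4)
        with pytest.raises(RuntimeError, match="unstable"):
            simulate_linear(circuit55, t, np.zeros_like(t))


class TestClassification:
    @pytest.mark.parametrize(
        "R,L,expected",
        [
            (17.7e3, 5.3e6, "resonator"),
            (-2.98e3, -0.0152e6, "amplifier"),
            (1.0, 0.0, "resonator"),  # degenerate pure-resistor branch
            (-1.0, 2.0, "unclassified"),
        ],
    )
    def test_examples(self, R, L, expected):
        assert classify_branch(RLBranch("x", R, L)) == expected

    def test_rest_circuit_roles(self, circuit55):
        roles = {b.label: classify_branch(b) for b in circuit55.branches}
        assert roles["m_h"] == "resonator"
        assert roles["m_CaT"] == "amplifier"
        assert roles["m_CaS"] == "amplifier"
        assert roles["KCa2"] == "resonator"


class TestComponentTable:
    def test_layout_and_scale(self, circuit55):
        df = component_table(circuit55)
        assert len(df) == 5 + 2 * 9  # 5 conductances, 9 branches x (R, L)
        row = df[df.component == "R_CaT0"].iloc[0]
        g = dict(circuit55.conductances)["CaT"]
        assert row.value == pytest.approx(printed_scale(1.0 / g, "R"))
        assert set(df.units) == {"GOhm", "GH"}
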