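"""Fixed-step RK4 integration of the nonlinear model and equilibria.

A fixed step (the stimulus sample interval) keeps the output on a uniform
grid suitable for FFT impedance estimation; the subthreshold dynamics are
non-stiff at the default 0.05 ms step. Holding a chosen resting potential
is done with a computed DC holding current (the experimental convention),
never by shifting the leak reversal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .model import (
    ModelState,
    PDModelParams,
    calcium_steady_state,
    eval_steady_state,
    gating_names,
    model_rhs,
    steady_state_current,
)

__all__ = ["Trace", "EquilibriumState", "integrate", "find_equilibrium"]


class IntegrationError(RuntimeError):
    pass


@dataclass
class Trace:
    """Simulated trajectory on a uniform time grid."""

    t: np.ndarray  # ms
    V: np.ndarray  # mV
    gating: dict[str, np.ndarray]
    Ca: np.ndarray  # µM
    I_inp: np.ndarray  # nA

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def to_frame(self):
        import pandas as pd

        cols = {"t_ms": self.t, "V_mV": self.V, "Ca_uM": self.Ca}
        cols.update({k: v for k, v in self.gating.items()})
        cols["I_nA"] = self.I_inp
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EquilibriumState:
    """A fixed point of the model under a constant holding current."""

    V_star: float  # mV
    gating_star: dict[str, float]
    Ca_star: float  # µM
    I_hold: float  # nA

    def as_model_state(self) -> ModelState:
        return ModelState(self.V_star, dict(self.gating_star), self.Ca_star)


def find_equilibrium(params: PDModelParams, V_star: float) -> EquilibriumState:
    """Closed-form equilibrium at a clamped potential.

    Gating sits at its steady state, calcium at its fixed point, and the
    holding current equals the total steady membrane current, so the
    returned state is a fixed point of the dynamics under I_hold.
    """
    Ca = calcium_steady_state(params, V_star)
    gating: dict[str, float] = {}
    for c in params.channels:
        m, h = eval_steady_state(c, V_star, Ca)
        gating[f"m_{c.name}"] = m
        if h is not None:
            gating[f"h_{c.name}"] = h
    I_hold = steady_state_current(params, V_star)
    return EquilibriumState(V_star, gating, Ca, I_hold)


def _state_vector(params: PDModelParams, state: ModelState) -> np.ndarray:
    names = gating_names(params)
    y = np.empty(2 + len(names))
    y[0] = state.V
    for i, nm in enumerate(names):
        y[1 + i] = state.gating[nm]
    y[-1] = state.Ca
    return y


def integrate(
    params: PDModelParams,
    t: np.ndarray,
    I_inp: np.ndarray,
    init: ModelState | EquilibriumState,
) -> Trace:
    """Classical RK4 with step equal to the stimulus sample interval."""
    t = np.asarray(t, dtype=float)
    I_inp = np.asarray(I_inp, dtype=float)
    if t.shape != I_inp.shape:
        raise ValueError("time grid and stimulus must have equal length")
    dts = np.diff(t)
    if len(dts) == 0 or not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
        raise ValueError("stimulus grid must be uniform")
    if isinstance(init, EquilibriumState):
        init = init.as_model_state()
    y0 = _state_vector(params, init)
    P, m_idx, h_idx, scal, nvar = _kernels.pack_params(params)
    Y = _kernels.rk4_run(y0, I_inp, float(dts[0]), P, m_idx, h_idx, scal)
    if Y.shape[0] < len(t):
        raise IntegrationError(
            f"state became non-finite at t = {t[Y.shape[0] - 1]:.3f} ms"
        )
    names = gating_names(params)
    gat = {nm: Y[:, 1 + i] for i, nm in enumerate(names)}
    return Trace(t=t, V=Y[:, 0], gating=gat, Ca=Y[:, -1], I_inp=I_inp)


def rhs_max_norm(params: PDModelParams, eq: EquilibriumState) -> float:
    """Max-norm of the model right-hand side at an equilibrium candidate."""
    d = model_rhs(eq.as_model_state(), eq.I_hold, params)
    vals = [abs(d.V), abs(d.Ca)] + [abs(v) for v in d.gating.values()]
    return max(vals)
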