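"""Input currents: the linear-frequency chirp (ZAP) and DC/step currents.

The chirp is I(t) = I_amp * sin(2*pi*f(t)*t) with f(t) = f0 + (fmax-f0)*t/(2T),
so the *instantaneous* frequency d/dt[f(t)*t] sweeps linearly from f0 to fmax
over the record. Time series are on a uniform grid in ms; currents in nA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ChirpSpec", "chirp_current", "dc_current", "write_series_csv"]


@dataclass(frozen=True)
class ChirpSpec:
    I_amp: float = 0.1  # nA
    f0: float = 0.0  # Hz
    f_max: float = 5.0  # Hz
    T: float = 10.0  # s
    dt: float = 0.05  # ms

    def __post_init__(self) -> None:
        if not (self.f_max > self.f0 >= 0):
            raise ValueError("need f_max > f0 >= 0")
        if self.T <= 0 or self.dt <= 0:
            raise ValueError("T and dt must be positive")
        if self.f_max * self.dt * 1e-3 >= 0.05:
            raise ValueError("dt too coarse: need >= 20 samples per fastest cycle")


def chirp_current(spec: ChirpSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (t_ms, I_nA) for the chirp over [0, T]."""
    t = np.arange(0.0, spec.T * 1000.0 + spec.dt / 2, spec.dt)
    ts = t * 1e-3  # s
    f = spec.f0 + (spec.f_max - spec.f0) * ts / (2.0 * spec.T)
    return t, spec.I_amp * np.sin(2.0 * np.pi * f * ts)


def dc_current(level: float, T: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Constant current of ``level`` nA over [0, T] s on a dt-ms grid."""
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    t = np.arange(0.0, T * 1000.0 + dt / 2, dt)
    return t, np.full_like(t, float(level))


def write_series_csv(path, t_ms: np.ndarray, I_nA: np.ndarray) -> None:
    np.savetxt(
        path,
        np.column_stack([t_ms, I_nA]),
        delimiter=",",
        header="t_ms,I_nA",
        comments="",
    )
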