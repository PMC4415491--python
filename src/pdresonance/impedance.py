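"""Impedance profiles from chirp responses and resonance metrics.

Z(f) = FFT(V - mean V) / FFT(I - mean I) at the positive frequency bins.
The resonance frequency f_res is the argmax of the (optionally LOWESS-
smoothed) impedance magnitude over f >= 0.1 Hz, refined by parabolic
interpolation through the peak bin; the resonance strength is
Q = |Z(f_res)| / |Z(0.5 Hz)|, with Q >= 1.01 the criterion for calling the
profile resonant. Profiles whose magnitude peaks at the low-frequency
boundary are non-resonant by convention (f_res absent, Q = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ImpedanceProfile",
    "impedance_profile",
    "magnitude_phase",
    "smooth_magnitude",
    "resonance_metrics",
]

Q_CRITERION = 1.01  # resonant iff peak magnitude >= 1% above |Z(0.5 Hz)|
F_MIN = 0.1  # Hz; lower bins are distorted and excluded from metrics
F_REF = 0.5  # Hz; the low-frequency reference of the Q-factor


@dataclass
class ImpedanceProfile:
    f: np.ndarray  # Hz, ascending
    Z: np.ndarray  # complex MΩ
    magnitude: np.ndarray  # MΩ
    phase: np.ndarray  # rad, in (-pi, pi]
    mag_smoothed: np.ndarray | None = None
    f_res: float | None = None
    Z_max: float | None = None
    Q: float | None = None
    is_resonant: bool | None = None

    def to_frame(self):
        import pandas as pd

        d = {
            "f_Hz": self.f,
            "Re_MOhm": self.Z.real,
            "Im_MOhm": self.Z.imag,
            "mag_MOhm": self.magnitude,
            "phase_rad": self.phase,
        }
        if self.mag_smoothed is not None:
            d["mag_smoothed"] = self.mag_smoothed
        return pd.DataFrame(d)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def metrics_dict(self) -> dict:
        return {
            "f_res": self.f_res,
            "Z_max": self.Z_max,
            "Q": self.Q,
            "is_resonant": self.is_resonant,
        }


def magnitude_phase(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-element modulus and atan2 phase of a complex series."""
    Z = np.asarray(Z)
    if not np.all(np.isfinite(Z)):
        raise ValueError("impedance series contains non-finite values")
    return np.abs(Z), np.angle(Z)


def impedance_profile(
    V: np.ndarray,
    I: np.ndarray,
    dt: float,
    f_max: float = 5.0,
    current_floor: float = 1e-6,
) -> ImpedanceProfile:
    """Ratio-of-FFTs impedance estimate from equal-length uniform traces.

    V in mV, I in nA, dt in ms; Z in MΩ. Bins where the stimulus spectrum
    is below ``current_floor`` times its maximum are dropped.
    """
    V = np.asarray(V, dtype=float)
    I = np.asarray(I, dtype=float)
    if V.shape != I.shape:
        raise ValueError("voltage and current traces must have equal length")
    if not np.any(I != 0):
        raise ValueError("input current is identically zero")
    Vf = np.fft.rfft(V - V.mean())
    If = np.fft.rfft(I - I.mean())
    f = np.fft.rfftfreq(len(V), d=dt * 1e-3)
    keep = (f > 0) & (f <= f_max) & (np.abs(If) >= current_floor * np.abs(If).max())
    Z = Vf[keep] / If[keep]
    mag, ph = magnitude_phase(Z)
    return ImpedanceProfile(f=f[keep], Z=Z, magnitude=mag, phase=ph)


def smooth_magnitude(
    magnitude: np.ndarray, span: float = 0.1, f: np.ndarray | None = None
) -> np.ndarray:
    """Locally weighted linear regression over the frequency axis.

    ``span`` is the fraction of points in each local window; output length
    equals input length, and a linear trend is reproduced exactly.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    magnitude = np.asarray(magnitude, dtype=float)
    x = np.arange(len(magnitude), dtype=float) if f is None else np.asarray(f, float)
    return lowess(magnitude, x, frac=span, return_sorted=False)


def resonance_metrics(profile: ImpedanceProfile, span: float | None = 0.1) -> ImpedanceProfile:
    """Attach (f_res, Z_max, Q, is_resonant) to a profile.

    The magnitude is smoothed with LOWESS (span=None skips smoothing, for
    noise-free analytic profiles), restricted to f >= 0.1 Hz, and its peak
    located with parabolic interpolation. Q uses |Z| at 0.5 Hz, linearly
    interpolated; the grid must cover 0.5 Hz.
    """
    f, mag = profile.f, profile.magnitude
    if span is not None:
        mag = smooth_magnitude(mag, span=span, f=f)
        profile.mag_smoothed = mag
    else:
        profile.mag_smoothed = mag.copy()
    sel = f >= F_MIN
    fs, ms = f[sel], mag[sel]
    if len(fs) < 3 or fs[0] > F_REF or fs[-1] < F_REF:
        raise ValueError("frequency grid must cover [0.1, 0.5] Hz and beyond")
    z_ref = float(np.interp(F_REF, fs, ms))
    i = int(np.argmax(ms))
    if i == 0:
        # peak at the low-frequency boundary: low-pass profile, no resonance
        profile.f_res = None
        profile.Z_max = float(ms[0])
        profile.Q = 1.0
        profile.is_resonant = False
        return profile
    if i < len(fs) - 1:
        y1, y2, y3 = ms[i - 1], ms[i], ms[i + 1]
        denom = y1 - 2 * y2 + y3
        d = 0.0 if denom == 0 else 0.5 * (y1 - y3) / denom
        f_res = fs[i] + d * (fs[1] - fs[0])
        z_max = y2 - 0.25 * (y1 - y3) * d
    else:
        f_res, z_max = float(fs[i]), float(ms[i])
    profile.f_res = float(f_res)
    profile.Z_max = float(z_max)
    profile.Q = float(z_max / z_ref)
    profile.is_resonant = bool(profile.Q >= Q_CRITERION)
    return profile
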