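"""Synthetic reference circuits and profiles with closed-form answers.

These fixtures validate every pipeline stage without the neuron model: a
single-branch parallel RLC-with-leak circuit has an impedance known in
closed form, so the FFT pipeline, the smoother and the peak finder can be
checked against oracles computed directly here (independently of the
linearization module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .linearize import LinearCircuit, RLBranch

__all__ = [
    "ReferenceCircuit",
    "make_reference_rlc",
    "reference_impedance",
    "reference_resonance",
    "generate_noisy_profile",
]

DEFAULT_SEED = 20150416  # fixed fixture seed; always caller-overridable


@dataclass(frozen=True)
class ReferenceCircuit:
    """Capacitance + leak + all-positive series-RL branches."""

    C: float  # nF
    gL: float  # µS
    branches: tuple[tuple[float, float], ...]  # (R MΩ, L MΩ·ms)

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gL <= 0 or not self.branches:
            raise ValueError("need positive C, gL and at least one branch")
        if any(R <= 0 or L <= 0 for R, L in self.branches):
            raise ValueError("reference branches must have positive elements")

    def to_linear_circuit(self) -> LinearCircuit:
        return LinearCircuit(
            C=self.C,
            conductances=[("leak", self.gL)],
            branches=[
                RLBranch(f"ref{i}", R=R, L=L)
                for i, (R, L) in enumerate(self.branches, 1)
            ],
        )


def make_reference_rlc(C: float, gL: float, R: float, L: float) -> ReferenceCircuit:
    """Single-branch parallel RLC-with-leak reference circuit.

    R in MΩ and L in MΩ·ms (1 MΩ·ms = 1 kH). Large L or large R sends the
    branch admittance to zero, recovering a passive RC membrane.
    """
    return ReferenceCircuit(C=C, gL=gL, branches=((R, L),))


def reference_impedance(circ: ReferenceCircuit, f) -> np.ndarray:
    """Closed-form Z(f) in MΩ, evaluated directly from the element values
    (this is the oracle; it shares no code with the pipeline under test)."""
    w = 2.0 * np.pi * np.asarray(f, dtype=float) * 1e-3  # rad/ms
    Y = 1j * w * circ.C + circ.gL
    for R, L in circ.branches:
        Y = Y + 1.0 / (R + 1j * w * L)
    return 1.0 / Y


def reference_resonance(
    circ: ReferenceCircuit, f_lo: float = 0.1, f_hi: float = 5.0, df: float = 1e-3
) -> tuple[float | None, float]:
    """Numerically locate the magnitude peak of the closed-form impedance.

    Returns (f_res, |Z|max); f_res is None when the magnitude is maximal at
    the low-frequency end (no resonance in the band).
    """
    f = np.arange(f_lo, f_hi + df / 2, df)
    mag = np.abs(reference_impedance(circ, f))
    i = int(np.argmax(mag))
    if i == 0:
        return None, float(mag[0])
    return float(f[i]), float(mag[i])


def generate_noisy_profile(
    seed: int | None, base_profile: np.ndarray, noise_sd: float
) -> np.ndarray:
    """Reproducible additive-Gaussian corruption of a magnitude series."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    base = np.asarray(base_profile, dtype=float)
    return base + rng.normal(0.0, noise_sd, size=base.shape)
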