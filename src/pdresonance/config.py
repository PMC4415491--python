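"""YAML (de)serialization of model parameter sets.

Keys mirror the published parameter tables: per-channel ``gbar``/``reversal``
/exponents and sigmoid kinetics (half, slope, tau_base, tau_amplitude,
tau_half, tau_slope), membrane ``C``/``g_leak``, calcium constants
``F``/``tau_Ca``/``C0``, and the constant ``E_Ca``. ``E_leak: auto`` asks
for the leak reversal that makes ``V_rest`` a zero-input equilibrium. The
bundled ``data/control.yaml`` reproduces the control condition exactly.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .model import (
    CalciumDynamics,
    ChannelSpec,
    GatingKinetics,
    PDModelParams,
    solve_leak_reversal,
)

__all__ = ["params_to_yaml", "params_from_yaml", "load_control_yaml"]


def _kin_dict(k: GatingKinetics) -> dict:
    return {
        "half": k.half_voltage,
        "slope": k.slope,
        "tau_base": k.tau_base,
        "tau_amplitude": k.tau_amplitude,
        "tau_half": k.tau_half_voltage,
        "tau_slope": k.tau_slope,
    }


def _kin_from(d: dict) -> GatingKinetics:
    return GatingKinetics(
        d["half"], d["slope"], d["tau_base"], d["tau_amplitude"], d["tau_half"],
        d["tau_slope"],
    )


def params_to_yaml(params: PDModelParams, path=None) -> str:
    doc: dict = {
        "C": params.C,
        "g_leak": params.g_leak,
        "E_leak": params.E_leak,
        "E_Ca": params.E_Ca,
        "calcium": {
            "F": params.calcium.F,
            "tau_Ca": params.calcium.tau_Ca,
            "C0": params.calcium.C0,
        },
        "channels": {},
    }
    for c in params.channels:
        entry = {
            "gbar": c.gbar,
            "reversal": "E_Ca" if c.reversal is None else c.reversal,
            "activation_exponent": c.activation_exponent,
            "activation": _kin_dict(c.activation),
        }
        if c.inactivation is not None:
            entry["inactivation"] = _kin_dict(c.inactivation)
        if c.calcium_coupled:
            entry["calcium_coupled"] = True
            entry["ca_half"] = c.ca_half
        doc["channels"][c.name] = entry
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def params_from_yaml(source) -> PDModelParams:
    """Load parameters from a YAML path or string."""
    s = str(source)
    text = Path(s).read_text() if ("\n" not in s and Path(s).is_file()) else s
    doc = yaml.safe_load(text)
    channels = []
    for name, e in doc["channels"].items():
        rev = e["reversal"]
        channels.append(
            ChannelSpec(
                name=name,
                gbar=float(e["gbar"]),
                reversal=None if rev == "E_Ca" else float(rev),
                activation_exponent=int(e["activation_exponent"]),
                activation=_kin_from(e["activation"]),
                inactivation=_kin_from(e["inactivation"]) if "inactivation" in e else None,
                calcium_coupled=bool(e.get("calcium_coupled", False)),
                ca_half=float(e.get("ca_half", 30.0)),
            )
        )
    cal = doc.get("calcium", {})
    params = PDModelParams(
        channels=tuple(channels),
        C=float(doc["C"]),
        g_leak=float(doc["g_leak"]),
        E_leak=0.0 if doc.get("E_leak") == "auto" else float(doc["E_leak"]),
        E_Ca=float(doc["E_Ca"]),
        calcium=CalciumDynamics(
            F=float(cal.get("F", 0.515)),
            tau_Ca=float(cal.get("tau_Ca", 300.0)),
            C0=float(cal.get("C0", 0.5)),
        ),
    )
    if doc.get("E_leak") == "auto":
        params = solve_leak_reversal(params, float(doc.get("V_rest", -55.0)))
    return params


def load_control_yaml() -> PDModelParams:
    """The bundled control condition."""
    text = resources.files("pdresonance").joinpath("data/control.yaml").read_text()
    return params_from_yaml(text)
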