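"""Canonical parameter sets and flat structured-text (INI) round-trip.

The original population analysis never published its fitted parameter
values, so the package ships a documented canonical truth set chosen so
that model steady-state exposures approximate the program's printed TK
metrics (monkey Cmax/AUC at 0.3/1/3 mg/kg/week; pediatric Cmax/AUC at
0.2 mg/kg/week) and the printed monkey-to-human AUC correspondence
(0.2 mg/kg/week in children comparable to 0.08 mg/kg/week in monkeys).
All recovery tests and the workflow reference this set; see
docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

import configparser
from dataclasses import fields

from .errors import ConfigError
from .pk_core import HumanPKParams, MonkeyPKParams
from .population import IIVSpec, ResidualErrorSpec
from .vacuolation import TransitPDParams

#: canonical monkey TK truth (ml/h/kg, ml/kg, ng/h/kg, ng/ml, -, h)
MONKEY_TRUTH = MonkeyPKParams(CL=0.55, Vc=50.0, Vmax=2200.0, Km=2000.0, F=0.8, Dzero=24.0)

#: canonical pediatric PK truth
HUMAN_TRUTH = HumanPKParams(CL=4.3, Vc=320.0, ka=0.03, frZero=0.5, Dzero=24.0, F=0.8)

#: canonical transit-PD truth; V0 equals the observed spontaneous
#: control background ratio at 52 weeks
PD_TRUTH = TransitPDParams(n_transit=3, ktr=0.002, kin=3.0e-9, kout=5.0e-5, V0=0.0595)

#: default inter-individual variability (20% CV on CL and Vc)
IIV_DEFAULT = IIVSpec({"CL": 0.04, "Vc": 0.04})

#: default residual error (15% proportional, additive SD a quarter of
#: the LLOQ — blank-sample noise essentially never clears the LLOQ)
ERROR_DEFAULT = ResidualErrorSpec(sigma_prop=0.15, sigma_add=2.0, lloq=8.0)

_SECTIONS = {
    "monkey_pk": MonkeyPKParams,
    "human_pk": HumanPKParams,
    "transit_pd": TransitPDParams,
    "residual_error": ResidualErrorSpec,
}


def save_params(path, sections: dict) -> None:
    """Write parameter sets to a flat key = value INI file; section names
    identify the parameter-set kind (monkey_pk, human_pk, transit_pd,
    residual_error, iiv)."""
    cp = configparser.ConfigParser()
    for name, obj in sections.items():
        if isinstance(obj, IIVSpec):
            cp[name] = {k: repr(v) for k, v in obj.omega2.items()}
        else:
            cp[name] = {
                f.name: repr(getattr(obj, f.name))
                for f in fields(obj)
                if getattr(obj, f.name) is not None
            }
    with open(path, "w") as fh:
        cp.write(fh)


def load_params(path) -> dict:
    """Read an INI parameter file back into typed parameter objects."""
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise ConfigError(f"cannot read parameter file {path}")
    out = {}
    for name in cp.sections():
        items = dict(cp[name])
        if name == "iiv":
            canon = {"cl": "CL", "vc": "Vc", "vmax": "Vmax", "km": "Km",
                     "ka": "ka", "f": "F", "frzero": "frZero", "dzero": "Dzero"}
            out[name] = IIVSpec({canon.get(k, k): float(v) for k, v in items.items()})
            continue
        cls = _SECTIONS.get(name)
        if cls is None:
            raise ConfigError(f"unknown parameter section [{name}]")
        field_map = {f.name.lower(): f.name for f in fields(cls)}
        kwargs = {}
        for k, v in items.items():
            if k.lower() not in field_map:
                raise ConfigError(f"unknown key {k!r} in section [{name}]")
            target = field_map[k.lower()]
            kwargs[target] = int(v) if target == "n_transit" else float(v)
        out[name] = cls(**kwargs)
    return out


def canonical_sections() -> dict:
    """The canonical truth configuration as a sections dict."""
    return {
        "monkey_pk": MONKEY_TRUTH,
        "human_pk": HUMAN_TRUTH,
        "transit_pd": PD_TRUTH,
        "residual_error": ERROR_DEFAULT,
        "iiv": IIV_DEFAULT,
    }
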