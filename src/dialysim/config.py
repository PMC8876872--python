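"""YAML case configuration.

Schema (version 1)::

    version: 1
    case: 1A                 # one of the 13 catalogue ids, or "validation"
    level: 1.0               # mesh-resolution scale factor
    resolution: [10, 24, 72] # optional explicit (n1, n2, n3)
    Q_B_ml_min: 300          # validation only
    Q_UF_ml_min: 10
    port_diameter_mm: 8
    slit_width_mm: 5
    solver:
      max_steps: 30
      tol: 0.005
      relax: 1.0

Unknown keys raise, so typos fail loudly.
"""
from __future__ import annotations

from pathlib import Path

import yaml

from .cases import comparison_case, validation_case, MLMIN
from .driver import CaseConfig, SolverSettings

_TOP_KEYS = {"version", "case", "level", "resolution", "Q_B_ml_min",
             "Q_UF_ml_min", "port_diameter_mm", "slit_width_mm", "solver"}
_SOLVER_KEYS = {"max_steps", "tol", "relax", "uf_tol", "fixed_Sh_D",
                "min_steps"}


class ConfigError(ValueError):
    pass


def load_case(path) -> CaseConfig:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if int(data.get("version", 1)) != 1:
        raise ConfigError("unsupported config version")
    solver_data = data.get("solver") or {}
    unknown = set(solver_data) - _SOLVER_KEYS
    if unknown:
        raise ConfigError(f"unknown solver keys: {sorted(unknown)}")
    solver = SolverSettings(**solver_data)
    case_id = str(data.get("case", "1A"))
    kw = dict(
        level=float(data.get("level", 1.0)),
        resolution=tuple(data["resolution"]) if "resolution" in data else None,
        solver=solver,
    )
    if case_id.lower().startswith("validation"):
        return validation_case(float(data.get("Q_B_ml_min", 300)), **kw)
    return comparison_case(
        case_id,
        Q_UF=float(data.get("Q_UF_ml_min", 10)) * MLMIN,
        port_diameter=float(data.get("port_diameter_mm", 8)) * 1e-3,
        slit_width=float(data.get("slit_width_mm", 5)) * 1e-3,
        **kw,
    )
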