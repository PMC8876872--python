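"""Ready-made case configurations.

``comparison_case`` builds any of the 13 geometry/port configurations of the
comparison study (same membrane area, shell porosity and total volume;
blood 300 mL/min at 20 mol/m^3 urea, dialysate 500 mL/min, 10 mL/min
ultrafiltration).  ``validation_case`` builds the commercial long
cylinder under the ISO-style in-vitro protocol: saline (dialysate
properties) in both compartments and zero oncotic pressure.
"""
from __future__ import annotations

import numpy as np

from .geometry import (derive_dimensions, dialysate_ports, blood_end_ports,
                       ModuleGeometry)
from .membrane import MembraneSpec, SoluteSpec
from .flow import PorousSideSpec
from .driver import CaseConfig, SolverSettings

MLMIN = 1e-6 / 60.0

CASE_IDS = ("1A", "1B", "1C", "1D", "2A", "2B", "2C", "2D",
            "3A", "3B", "4A", "4B", "4C")

_SHAPE = {"1": "long_cyl", "2": "short_cyl", "3": None, "4": "coaxial_cyl"}
_ARRANGEMENT = {
    "1A": "8x8", "1B": "1x1_same", "1C": "1x1_opposite", "1D": "slit",
    "2A": "8x8", "2B": "1x1_same", "2C": "1x1_opposite", "2D": "slit",
    "3A": "slit_cross", "3B": "slit_cross",
    "4A": "6x6", "4B": "4x1", "4C": "1x1",
}

# baseline mesh resolutions (n1, n2, n3); scaled by ``level``
_RESOLUTION = {
    "long_cyl": (10, 24, 72),
    "short_cyl": (14, 32, 26),
    "thick_rect": (18, 18, 44),
    "flat_rect": (36, 8, 40),
    "coaxial_cyl": (12, 24, 48),
}


def _scale_resolution(base, level):
    return tuple(max(3, int(round(n * level))) for n in base)


def default_fluids(solute: SoluteSpec, Q_B=300 * MLMIN, Q_D=500 * MLMIN,
                   saline: bool = False):
    """Blood- and dialysate-side specs (standard fluid properties; ``saline``
    replaces the blood properties with dialysate ones, the in-vitro
    validation protocol)."""
    if saline:
        blood = PorousSideSpec("blood", 0.29, 3.4e-10, 0.0, 1000.0,
                               7.62e-4, solute.D_D, Q_in=Q_B,
                               C_in=solute.C_in_blood)
    else:
        blood = PorousSideSpec("blood", 0.29, 3.4e-10, 0.0, 1000.0,
                               3.5e-3, solute.D_B, Q_in=Q_B,
                               C_in=solute.C_in_blood)
    dial = PorousSideSpec("dialysate", 0.51, 3.4e-10, 3.2e-11, 1000.0,
                          7.62e-4, solute.D_D, Q_in=Q_D,
                          C_in=solute.C_in_dial)
    return blood, dial


def _shape_for(case_id: str) -> str:
    fam = case_id[0]
    if fam == "3":
        return "thick_rect" if case_id == "3A" else "flat_rect"
    return _SHAPE[fam]


def comparison_case(case_id: str, level: float = 1.0,
                resolution: tuple | None = None,
                Q_UF: float = 10 * MLMIN,
                port_diameter: float = 8e-3,
                slit_width: float = 5e-3,
                solver: SolverSettings | None = None) -> CaseConfig:
    case_id = case_id.upper()
    if case_id not in CASE_IDS:
        raise ValueError(f"unknown case {case_id!r}; choose from {CASE_IDS}")
    shape = _shape_for(case_id)
    geo = derive_dimensions(shape)
    ports = blood_end_ports() + dialysate_ports(
        geo, _ARRANGEMENT[case_id], port_diameter=port_diameter,
        slit_width=slit_width)
    geo.port_layout = ports
    mem = MembraneSpec()
    sol = SoluteSpec()
    blood, dial = default_fluids(sol)
    res = resolution or _scale_resolution(_RESOLUTION[shape], level)
    return CaseConfig(case_id, geo, res, ports, mem, sol, blood, dial,
                      Q_UF=Q_UF, solver=solver or SolverSettings())


def validation_case(Q_B_ml_min: float, level: float = 1.0,
                    resolution: tuple | None = None,
                    solver: SolverSettings | None = None) -> CaseConfig:
    """Commercial module (8 inlets/8 outlets) under the saline validation
    protocol at the given blood-side flow rate."""
    geo = derive_dimensions("long_cyl")
    ports = blood_end_ports() + dialysate_ports(geo, "8x8")
    geo.port_layout = ports
    mem = MembraneSpec(p_onc=0.0)
    # saline in both compartments: the lumen-side solute diffusivity is the
    # aqueous (dialysate) one
    sol = SoluteSpec(D_B=SoluteSpec().D_D)
    blood, dial = default_fluids(sol, Q_B=Q_B_ml_min * MLMIN, saline=True)
    res = resolution or _scale_resolution(_RESOLUTION["long_cyl"], level)
    return CaseConfig(f"validation_QB{Q_B_ml_min:g}", geo, res, ports, mem,
                      sol, blood, dial, Q_UF=10 * MLMIN,
                      solver=solver or SolverSettings())
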