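"""Reduced-order exchanger oracles and small test fixtures.

The classic effectiveness-NTU theory of mass/heat exchangers gives the
clearance of an idealised module with uniform overall coefficient U and
no ultrafiltration.  With NTU = U A / Q_B and capacity ratio
R = Q_B / Q_D the counter-flow effectiveness is

    E = (1 - exp(-NTU (1 - R))) / (1 - R exp(-NTU (1 - R)))

(limiting to NTU/(1+NTU) at R = 1), and CL = E Q_B.  These closed forms
are used only as independent oracles for the 3-D solver; they are never
part of the simulation itself.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class ExchangerSpec1D:
    U: float                 # m/s, uniform overall coefficient
    A: float                 # m^2, transfer area
    Q_B: float               # m^3/s
    Q_D: float               # m^3/s
    arrangement: str = "counter"   # "counter" | "co" | "cross-unmixed"

    def __post_init__(self):
        if self.Q_B <= 0 or self.Q_D <= 0:
            raise ValueError("flows must be positive")
        if not math.isfinite(self.U * self.A):
            raise ValueError("U*A must be finite")


def effectiveness(NTU: float, R: float, arrangement: str = "counter") -> float:
    if NTU < 0 or R < 0:
        raise ValueError("NTU and R must be nonnegative")
    if NTU == 0:
        return 0.0
    if arrangement == "counter":
        if abs(1.0 - R) < 1e-12:
            return NTU / (1.0 + NTU)
        x = math.exp(-NTU * (1.0 - R))
        return (1.0 - x) / (1.0 - R * x)
    if arrangement == "co":
        return (1.0 - math.exp(-NTU * (1.0 + R))) / (1.0 + R)
    if arrangement == "cross-unmixed":
        # standard both-streams-unmixed approximation
        if R == 0:
            return 1.0 - math.exp(-NTU)
        return 1.0 - math.exp(NTU ** 0.22 / R
                              * (math.exp(-R * NTU ** 0.78) - 1.0))
    raise ValueError(f"unknown arrangement {arrangement!r}")


def clearance_1d(spec: ExchangerSpec1D) -> float:
    """Clearance of the uniform-U exchanger (same units as Q_B)."""
    NTU = spec.U * spec.A / spec.Q_B
    R = spec.Q_B / spec.Q_D
    return effectiveness(NTU, R, spec.arrangement) * spec.Q_B


# --------------------------------------------------------------------- fixtures
def make_fixture(kind: str) -> dict:
    """Tiny configuration + oracle-computed expectations for the test suite.

    Kinds: ``darcy_1d`` (closed-form axial pressure drop),
    ``advection_1d`` (constant-sink axial decay), ``counterflow_box``
    (uniform-U exchanger cuboid) and ``symmetric_ports`` (mirrored
    two-port cylinder).
    """
    from .membrane import MembraneSpec, SoluteSpec, SH_B
    from .flow import PorousSideSpec
    from .geometry import ModuleGeometry, PortPatch, blood_end_ports
    from .driver import CaseConfig, SolverSettings

    if kind == "darcy_1d":
        L, A = 0.2, 1e-3
        spec = PorousSideSpec("blood", eps=0.29, K_z=3.4e-10, K_t=0.0,
                              rho=1000.0, mu=3.5e-3, D=7.4e-10,
                              Q_in=5e-6, p_out=0.0, C_in=20.0)
        dp = spec.mu * (spec.Q_in / A) * L / spec.K_z
        return {"kind": kind, "L": L, "A_cross": A, "spec": spec,
                "expected_dp": dp, "n_cells": 10}

    if kind == "advection_1d":
        # u dC/dz = -k C  ->  C(z) = C_in exp(-k z / u)
        L, A, u, k, C_in = 0.2, 1e-3, 2e-3, 0.05, 20.0
        return {"kind": kind, "L": L, "A_cross": A, "u": u, "sink_rate": k,
                "C_in": C_in,
                "profile": lambda z: C_in * np.exp(-k * np.asarray(z) / u)}

    if kind == "counterflow_box":
        L, w = 0.25, 0.03
        V = w * w * L
        mem = MembraneSpec(L_p=1e-30, A_ext=1.2)  # UF switched off
        sol = SoluteSpec()
        fixed_Sh = 14.0
        geo = ModuleGeometry("thick_rect", L, {"width": w, "height": w},
                             V, mem.A_ext)
        blood = PorousSideSpec("blood", 0.29, 3.4e-10, 0.0, 1000.0, 3.5e-3,
                               sol.D_B, Q_in=5e-6, C_in=20.0)
        dial = PorousSideSpec("dialysate", 0.51, 3.4e-10, 3.2e-11, 1000.0,
                              7.62e-4, sol.D_D, Q_in=500e-6 / 60, C_in=0.0)
        ports = blood_end_ports() + [
            PortPatch("dialysate", "inlet", {"surface": "end_plus",
                                             "full": True}),
            PortPatch("dialysate", "outlet", {"surface": "end_minus",
                                              "full": True}),
        ]
        case = CaseConfig("counterflow_box", geo, (3, 3, 120), ports, mem,
                          sol, blood, dial, Q_UF=0.0,
                          solver=SolverSettings(fixed_Sh_D=fixed_Sh))
        # oracle U from the frozen Sherwood numbers
        from .membrane import hydraulic_diameter
        d_h = hydraulic_diameter(mem.d_o, dial.eps)
        k_B = SH_B * sol.D_B / mem.d_i
        k_D = fixed_Sh * sol.D_D / d_h
        U = 1.0 / (1 / k_B + 1 / mem.k_M + 1 / k_D)
        oracle = ExchangerSpec1D(U=U, A=mem.A_ext, Q_B=blood.Q_in,
                                 Q_D=dial.Q_in, arrangement="counter")
        return {"kind": kind, "case": case, "oracle": oracle,
                "expected_CL_ml_min": clearance_1d(oracle) * 6.0e7}

    if kind == "symmetric_ports":
        from .cases import comparison_case
        # level 1.0 so the 8-mm port circles span matching face columns on
        # both sides of the theta = 0 / pi mirror plane (coarser grids fall
        # back to a single, off-plane face column and break the symmetry of
        # the *setup*, not of the solver)
        case = comparison_case("1C", level=1.0)
        return {"kind": kind, "case": case, "mirror_plane": "y"}

    raise ValueError(f"unknown fixture kind {kind!r}")
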