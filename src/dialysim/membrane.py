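"""Transmembrane water and solute exchange closures.

The membrane couples the two porous compartments through a water flux
(ultrafiltration, driven by the transmembrane pressure minus the oncotic
pressure) and a solute flux combining convection through the membrane with
diffusion down the concentration difference:

    j = L_p (p_B - p_D - p_onc) (1 - sigma) C_sM  +  U (C_B - C_D)

with C_sM the arithmetic mean of the two bulk concentrations and U the
overall mass-transfer coefficient from three resistances in series,

    1/U = 1/k_B + 1/k_M + 1/k_D .

The lumen-side coefficient uses a constant Sherwood number Sh_B = 4
(between the uniform-concentration and uniform-flux laminar duct values);
the shell-side one uses the fiber-bundle cross-flow correlation

    Sh_D = 9.85 (1 + 1.41 Re_t^0.38)

which at zero transverse Reynolds number returns the purely axial value
9.85, so taking "the larger of the axial and cross-flow Sherwood numbers"
is automatic.  Re_t is built from the local transverse superficial
velocity and the bundle hydraulic diameter d_h = d_o eps/(1 - eps).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SH_B = 4.0
SH_AXIAL = 9.85
_SH_COEF = 1.41
_SH_EXP = 0.38


@dataclass
class MembraneSpec:
    """Fiber and membrane data (commercial polyphenylene membrane defaults)."""
    d_i: float = 200e-6          # m, fiber inner diameter
    s: float = 30e-6             # m, wall thickness
    k_M: float = 1.1e-5          # m/s, diffusive permeability (urea)
    L_p: float = 6.6e-11         # m/(s Pa), hydraulic permeability
    sigma: float = 0.0           # Staverman reflection coefficient (urea: 0)
    A_ext: float = 1.7           # m^2, membrane area
    p_onc: float = 0.0           # Pa, oncotic pressure (validation protocol: 0)

    def __post_init__(self):
        if not (self.d_i > 0 and self.s >= 0):
            raise ValueError("fiber dimensions must be positive")
        if not (0.0 <= self.sigma <= 1.0):
            raise ValueError("sigma must lie in [0, 1]")
        if self.L_p <= 0:
            raise ValueError("L_p must be positive")

    @property
    def d_o(self) -> float:
        return self.d_i + 2 * self.s


@dataclass
class SoluteSpec:
    name: str = "urea"
    MW: float = 60.0             # Da
    D_B: float = 7.4e-10         # m^2/s in blood
    D_D: float = 1.8e-9          # m^2/s in dialysate
    C_in_blood: float = 20.0     # mol/m^3
    C_in_dial: float = 0.0

    def __post_init__(self):
        if self.D_B <= 0 or self.D_D <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass
class TransferState:
    """Per-cell mass-transfer fields on the shared mesh (arrays)."""
    Re_t: np.ndarray
    Sh_D: np.ndarray
    k_B: float
    k_D: np.ndarray
    U: np.ndarray
    d_h: float
    j: np.ndarray | None = None
    j_conv: np.ndarray | None = None
    j_diff: np.ndarray | None = None


def hydraulic_diameter(d_o: float, eps: float) -> float:
    """Bundle hydraulic diameter, 4 x free volume / wetted fiber surface."""
    return d_o * eps / (1.0 - eps)


def sherwood_shell(Re_t):
    """Shell-side Sherwood number of the fiber bundle at transverse
    Reynolds number ``Re_t`` (scalar or array); >= 9.85, monotone."""
    Re_t = np.asarray(Re_t, float)
    if np.any(Re_t < 0):
        raise ValueError("Re_t must be nonnegative")
    out = SH_AXIAL * (1.0 + _SH_COEF * Re_t ** _SH_EXP)
    return float(out) if out.ndim == 0 else out


def transverse_reynolds(u_t_mag, rho_D: float, mu_D: float, d_h: float):
    return rho_D * np.asarray(u_t_mag, float) * d_h / mu_D


def transfer_coefficients(u_t_mag, membrane: MembraneSpec, solute: SoluteSpec,
                          rho_D: float, mu_D: float, eps_shell: float,
                          fixed_Sh_D: float | None = None):
    """Local mass-transfer coefficients and overall U from the dialysate
    transverse superficial speed ``u_t_mag`` (scalar or per-cell array).

    ``fixed_Sh_D`` freezes the shell Sherwood number (used by the
    uniform-U exchanger fixtures); otherwise the cross-flow correlation is
    evaluated at the local Re_t.
    """
    d_h = hydraulic_diameter(membrane.d_o, eps_shell)
    if fixed_Sh_D is not None:
        Re_t = np.zeros_like(np.asarray(u_t_mag, float))
        Sh_D = np.full_like(Re_t, float(fixed_Sh_D))
    else:
        Re_t = transverse_reynolds(u_t_mag, rho_D, mu_D, d_h)
        Sh_D = sherwood_shell(Re_t)
    k_B = SH_B * solute.D_B / membrane.d_i
    k_D = Sh_D * solute.D_D / d_h
    U = 1.0 / (1.0 / k_B + 1.0 / membrane.k_M + 1.0 / k_D)
    return TransferState(Re_t=np.atleast_1d(Re_t), Sh_D=np.atleast_1d(Sh_D),
                         k_B=k_B, k_D=np.atleast_1d(k_D), U=np.atleast_1d(U),
                         d_h=d_h)


def solute_flux(p_B, p_D, C_B, C_D, U, membrane: MembraneSpec):
    """Transmembrane solute flux (positive blood -> dialysate) and its
    convective/diffusive parts, per cell."""
    dp_tm = np.asarray(p_B, float) - np.asarray(p_D, float) - membrane.p_onc
    C_sM = 0.5 * (np.asarray(C_B, float) + np.asarray(C_D, float))
    j_conv = membrane.L_p * dp_tm * (1.0 - membrane.sigma) * C_sM
    j_diff = np.asarray(U, float) * (np.asarray(C_B, float) - np.asarray(C_D, float))
    return j_conv + j_diff, j_conv, j_diff


def mass_source(p_B, p_D, membrane: MembraneSpec, V_tot: float, rho: float,
                side: str):
    """Ultrafiltration mass source S_M [kg m^-3 s^-1]; the blood loses what
    the dialysate gains, cell by cell."""
    dp_tm = np.asarray(p_B, float) - np.asarray(p_D, float) - membrane.p_onc
    s = membrane.A_ext / V_tot * rho * membrane.L_p * dp_tm
    if side == "blood":
        return -s
    if side == "dialysate":
        return +s
    raise ValueError(f"unknown side {side!r}")
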