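"""Steady anisotropic Darcy flow in one porous compartment.

In the Darcy-dominated limit the momentum balance reduces to
``u = -(K/mu) grad p`` with K = diag(K_t, K_t, K_z); substituting into
continuity with the ultrafiltration mass source gives a symmetric
anisotropic-diffusion problem for the pressure,

    -div( (K/mu) grad p ) = S_M / rho ,

discretised with cell-centred two-point fluxes and harmonic face
mobilities.  The membrane leak is linear in the local pressure, so it is
taken implicitly (it adds a positive diagonal), which keeps the system
SPD and makes every solve exact in one factorisation.

Boundary conditions: imposed total flow on inlet patches (uniform flux
density over the port faces), imposed pressure on outlet patches
(Dirichlet through half-cell transmissibilities), no-flux walls.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import StructuredMesh


class FlowError(RuntimeError):
    pass


@dataclass
class PorousSideSpec:
    """Porous-medium and fluid description of one compartment."""
    side: str                    # "blood" | "dialysate"
    eps: float                   # porosity
    K_z: float                   # m^2, axial Darcy permeability
    K_t: float                   # m^2, transverse (blood: 0, laterally confined)
    rho: float                   # kg/m^3
    mu: float                    # Pa s
    D: float                     # m^2/s solute diffusivity in this fluid
    Q_in: float                  # m^3/s imposed inlet flow
    p_out: float = 0.0           # Pa imposed outlet pressure
    C_in: float = 0.0            # mol/m^3 inlet concentration

    def __post_init__(self):
        if not (0.0 < self.eps < 1.0):
            raise ValueError("porosity must lie in (0, 1)")
        if self.K_z <= 0 or self.K_t < 0:
            raise ValueError("need K_z > 0 and K_t >= 0")


@dataclass
class FlowField:
    p: np.ndarray                # Pa per cell
    u: np.ndarray                # (n_cells, 3) superficial velocity, native comps
    F_int: np.ndarray            # m^3/s, internal face fluxes (owner -> neighbour)
    F_bnd: np.ndarray            # m^3/s, boundary face fluxes (positive outward)
    Q_in: float
    Q_out: float
    source_volume: float         # m^3/s, net membrane volume gain of this side


def darcy_mobility(mesh: StructuredMesh, spec: PorousSideSpec) -> np.ndarray:
    lam = np.empty((mesh.n_cells, 3))
    lam[:, 0] = spec.K_t / spec.mu
    lam[:, 1] = spec.K_t / spec.mu
    lam[:, 2] = spec.K_z / spec.mu
    return lam


class DarcyOperator:
    """Factorised pressure operator for one side.

    The matrix depends only on the mesh, the mobilities, the leak
    coefficient field and the patch layout -- not on the frozen
    opposite-side pressure nor on the outlet pressure, which enter the
    right-hand side.  One LU factorisation therefore serves every coupling
    step and every ultrafiltration-tuning probe.
    """

    def __init__(self, mesh: StructuredMesh, spec: PorousSideSpec,
                 inlet_patch: str, outlet_patch: str,
                 leak: np.ndarray | float = 0.0):
        self.mesh = mesh
        self.spec = spec
        lam = darcy_mobility(mesh, spec)
        T_int, T_bnd = mesh.transmissibility(lam)
        T_int = np.where(mesh.blocked(spec.side), 0.0, T_int)
        self.T_int = T_int
        n = mesh.n_cells

        self.inlet_faces = mesh.patches[inlet_patch]
        self.outlet_faces = mesh.patches[outlet_patch]
        self.inlet_area = float(mesh.b_area[self.inlet_faces].sum())
        if self.inlet_area <= 0:
            raise FlowError("inlet patch has zero area")
        self.T_out = T_bnd[self.outlet_faces]
        self.T_in = T_bnd[self.inlet_faces]
        if not np.any(self.T_out > 0):
            raise FlowError("outlet patch is impermeable")

        leak = np.broadcast_to(np.asarray(leak, float), (n,))
        self.leak_vol = leak * mesh.vol      # m^3/(Pa s) per cell

        own, nb = mesh.f_own, mesh.f_nb
        diag = np.bincount(own, T_int, n) + np.bincount(nb, T_int, n)
        diag += np.bincount(self.outlet_faces * 0 + mesh.b_own[self.outlet_faces],
                            self.T_out, n)
        diag += self.leak_vol
        if not np.all(diag > 0):
            raise FlowError("singular pressure system (isolated cells with no "
                            "Dirichlet face and no leak)")
        A = sp.coo_matrix(
            (np.concatenate([diag, -T_int, -T_int]),
             (np.concatenate([np.arange(n), own, nb]),
              np.concatenate([np.arange(n), nb, own]))),
            shape=(n, n)).tocsc()
        self._lu = splu(A)

    def rhs(self, p_out: float, p_other=0.0, onc_sign: float = +1.0,
            p_onc: float = 0.0, extra_source=None) -> np.ndarray:
        """Assemble the right-hand side.

        ``onc_sign`` is +1 for blood (leak toward p_other + p_onc) and -1
        for dialysate.  ``extra_source`` is an optional per-cell volumetric
        source [m^3/s] (the explicit mass-source interface)."""
        mesh = self.mesh
        b = self.leak_vol * (np.broadcast_to(np.asarray(p_other, float),
                                             (mesh.n_cells,))
                             + onc_sign * p_onc)
        b = b.copy()
        np.add.at(b, mesh.b_own[self.outlet_faces], self.T_out * p_out)
        q = self.spec.Q_in / self.inlet_area
        np.add.at(b, mesh.b_own[self.inlet_faces],
                  q * mesh.b_area[self.inlet_faces])
        if extra_source is not None:
            b += np.asarray(extra_source, float)
        return b

    def solve(self, p_out: float | None = None, p_other=0.0,
              onc_sign: float = +1.0, p_onc: float = 0.0,
              extra_source=None) -> FlowField:
        mesh = self.mesh
        if p_out is None:
            p_out = self.spec.p_out
        p = self._lu.solve(self.rhs(p_out, p_other, onc_sign, p_onc, extra_source))
        F_int = self.T_int * (p[mesh.f_own] - p[mesh.f_nb])
        F_bnd = np.zeros(mesh.n_bnd)
        F_bnd[self.outlet_faces] = self.T_out * (p[mesh.b_own[self.outlet_faces]]
                                                 - p_out)
        q = self.spec.Q_in / self.inlet_area
        F_bnd[self.inlet_faces] = -q * mesh.b_area[self.inlet_faces]
        u = mesh.cell_velocities(F_int, F_bnd)
        Q_out = float(F_bnd[self.outlet_faces].sum())
        src = float((self.leak_vol * ((np.broadcast_to(np.asarray(p_other, float),
                                                       (mesh.n_cells,))
                                       + onc_sign * p_onc) - p)).sum())
        if extra_source is not None:
            src += float(np.sum(extra_source))
        return FlowField(p=p, u=u, F_int=F_int, F_bnd=F_bnd,
                         Q_in=self.spec.Q_in, Q_out=Q_out, source_volume=src)


def assemble_darcy(mesh: StructuredMesh, spec: PorousSideSpec,
                   mass_source_field=None,
                   inlet_patch: str | None = None,
                   outlet_patch: str | None = None):
    """Explicit-source convenience wrapper: build the pressure operator for
    a given mass source field S_M [kg m^-3 s^-1] (may be None/zero).

    Returns ``(operator, volumetric_source)`` where the source is
    ``S_M V / rho`` per cell, to be passed to :meth:`DarcyOperator.solve`.
    """
    inlet_patch = inlet_patch or f"{spec.side}:inlet"
    outlet_patch = outlet_patch or f"{spec.side}:outlet"
    op = DarcyOperator(mesh, spec, inlet_patch, outlet_patch, leak=0.0)
    if mass_source_field is None:
        src = None
    else:
        src = np.asarray(mass_source_field, float) * mesh.vol / spec.rho
    return op, src


def solve_flow(operator: DarcyOperator, p_out: float | None = None,
               extra_source=None) -> FlowField:
    """Solve the assembled Darcy system and check global mass balance."""
    ff = operator.solve(p_out=p_out, extra_source=extra_source)
    imbalance = ff.Q_in - ff.Q_out + ff.source_volume
    scale = max(abs(ff.Q_in), 1e-30)
    if abs(imbalance) > 1e-3 * scale:
        raise FlowError(f"global mass imbalance {imbalance:.3e} m^3/s "
                        f"({100*abs(imbalance)/scale:.3f}% of Q_in)")
    return ff
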