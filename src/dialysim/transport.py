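"""Steady advection-diffusion of solute in one compartment.

    div(u C) - div(eps D grad C) = S_C

with first-order upwind advection (discrete maximum principle), central
diffusion through the porosity-scaled diffusivity ``eps D``, imposed
advective influx ``Q_in C_in`` at inlet ports, pure advective outflow at
outlet ports and zero-flux walls.  The membrane solute source is linear
in the local concentration, so its own-side part is taken implicitly
(positive diagonal) while the frozen opposite-side part goes to the
right-hand side; with the flux split of the exchange closure this makes
the discrete concentrations provably bounded by the two inlet values.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .mesh import StructuredMesh
from .flow import FlowField, PorousSideSpec


class TransportError(RuntimeError):
    pass


@dataclass
class ConcentrationField:
    C: np.ndarray                  # mol/m^3 per cell
    C_out: float                   # mixing-cup outlet concentration
    inflow: float                  # mol/s advected in
    outflow: float                 # mol/s advected out
    source: float                  # mol/s net membrane source


def assemble_transport(mesh: StructuredMesh, flow: FlowField,
                       spec: PorousSideSpec,
                       inlet_patch: str, outlet_patch: str,
                       diag_source=0.0, rhs_source=0.0):
    """Build the sparse transport system for one side.

    ``diag_source`` [m^3/s per cell] is the implicit own-concentration
    membrane coefficient (added to the diagonal), ``rhs_source`` [mol/s
    per cell] the explicit part built from the frozen opposite side.
    """
    if flow is None:
        raise TransportError("a converged flow field is required")
    n = mesh.n_cells
    lam = np.full((n, 3), spec.eps * spec.D)
    T_int, _ = mesh.transmissibility(lam)
    T_int = np.where(mesh.blocked(spec.side), 0.0, T_int)

    own, nb = mesh.f_own, mesh.f_nb
    F = flow.F_int
    Fp = np.maximum(F, 0.0)        # owner -> neighbour
    Fm = np.maximum(-F, 0.0)       # neighbour -> owner

    diag = np.bincount(own, Fp + T_int, n) + np.bincount(nb, Fm + T_int, n)
    off_on = -(Fm + T_int)         # coefficient (own, nb)
    off_no = -(Fp + T_int)         # coefficient (nb, own)

    diag = diag + np.broadcast_to(np.asarray(diag_source, float), (n,))

    rhs = np.zeros(n) + np.broadcast_to(np.asarray(rhs_source, float), (n,))
    # inlet: advective influx at C_in (F_bnd is negative there)
    inlet_faces = mesh.patches[inlet_patch]
    inflow_flux = -flow.F_bnd[inlet_faces]
    np.add.at(rhs, mesh.b_own[inlet_faces], inflow_flux * spec.C_in)
    # outlet: advective outflow (upwind = cell value)
    outlet_faces = mesh.patches[outlet_patch]
    np.add.at(diag, mesh.b_own[outlet_faces],
              np.maximum(flow.F_bnd[outlet_faces], 0.0))

    A = sp.coo_matrix(
        (np.concatenate([diag, off_on, off_no]),
         (np.concatenate([np.arange(n), own, nb]),
          np.concatenate([np.arange(n), nb, own]))),
        shape=(n, n)).tocsc()
    return A, rhs


def solve_transport(A, rhs, mesh: StructuredMesh, flow: FlowField,
                    inlet_patch: str, outlet_patch: str,
                    spec: PorousSideSpec,
                    diag_source=0.0, rhs_source=0.0) -> ConcentrationField:
    """Direct solve plus balance bookkeeping and a residual check."""
    C = splu(A).solve(rhs)
    res = np.linalg.norm(A @ C - rhs)
    scale = np.linalg.norm(rhs) or 1.0
    if not np.isfinite(res) or res > 1e-8 * scale:
        raise TransportError(f"transport solve residual {res:.3e}")

    inlet_faces = mesh.patches[inlet_patch]
    outlet_faces = mesh.patches[outlet_patch]
    inflow = float((-flow.F_bnd[inlet_faces]).sum() * spec.C_in)
    F_out = np.maximum(flow.F_bnd[outlet_faces], 0.0)
    outflow = float((F_out * C[mesh.b_own[outlet_faces]]).sum())
    Q_out = float(F_out.sum())
    C_out = outflow / Q_out if Q_out > 0 else 0.0
    source = float(np.sum(np.broadcast_to(np.asarray(rhs_source, float),
                                          C.shape)
                          - np.broadcast_to(np.asarray(diag_source, float),
                                            C.shape) * C))
    return ConcentrationField(C=C, C_out=C_out, inflow=inflow,
                              outflow=outflow, source=source)
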