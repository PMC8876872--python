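"""Alternating blood/dialysate coupling with ultrafiltration tuning.

The two compartments are solved in turn.  The first blood step sees zero
dialysate pressure and concentration; every subsequent step reads the
last stored opposite-side pressure and concentration fields (the exchange
buffer).  Within each blood step the blood outlet pressure is adjusted so
that the net transmembrane water flow matches the prescribed
ultrafiltration rate -- the leak is affine in the outlet pressure and the
pressure matrix does not change, so two probe solves on one factorisation
pin the root exactly.  The run stops when, for both sides, outlet flow
rate and mixing-cup outlet concentration change by less than 0.5%
between consecutive steps.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ModuleGeometry, PortPatch, build_mesh, patch_faces
from .membrane import (MembraneSpec, SoluteSpec, TransferState,
                       transfer_coefficients, solute_flux)
from .flow import PorousSideSpec, DarcyOperator, FlowField
from .transport import assemble_transport, solve_transport, ConcentrationField
from . import report


class ConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class SolverSettings:
    max_steps: int = 30          # per side
    tol: float = 0.005           # 0.5% on outlet flow and concentration
    relax: float = 1.0           # plain alternation
    uf_tol: float = 0.01         # |Q_UF - target| < 1% of target
    fixed_Sh_D: float | None = None
    min_steps: int = 2


@dataclass
class CaseConfig:
    name: str
    geometry: ModuleGeometry
    resolution: tuple
    port_layout: list            # list[PortPatch], both sides
    membrane: MembraneSpec
    solute: SoluteSpec
    blood: PorousSideSpec
    dialysate: PorousSideSpec
    Q_UF: float = 10e-6 / 60.0   # m^3/s (10 mL/min)
    solver: SolverSettings = field(default_factory=SolverSettings)


@dataclass
class IterationRecord:
    step: int
    side: str
    Q_out: float
    C_out: float
    CL: float                    # mL/min estimate (blood steps)
    rel_change_Q: float
    rel_change_C: float


@dataclass
class ExchangeBuffer:
    """Frozen opposite-side fields, updated only at the end of a side's step."""
    p_B: np.ndarray
    C_B: np.ndarray
    p_D: np.ndarray
    C_D: np.ndarray
    u_t_D: np.ndarray            # dialysate transverse speed (for Sh_D)

    @classmethod
    def zeros(cls, n):
        z = lambda: np.zeros(n)
        return cls(z(), z(), z(), z(), z())

    def update(self, side, p, C, relax, u_t=None):
        if side == "blood":
            self.p_B = relax * p + (1 - relax) * self.p_B
            self.C_B = relax * C + (1 - relax) * self.C_B
        else:
            self.p_D = relax * p + (1 - relax) * self.p_D
            self.C_D = relax * C + (1 - relax) * self.C_D
            if u_t is not None:
                self.u_t_D = relax * u_t + (1 - relax) * self.u_t_D


def _rel(new, old):
    return abs(new - old) / max(abs(old), 1e-30)


def _transfer(case: CaseConfig, u_t_D) -> TransferState:
    return transfer_coefficients(
        u_t_D, case.membrane, case.solute,
        rho_D=case.dialysate.rho, mu_D=case.dialysate.mu,
        eps_shell=case.dialysate.eps,
        fixed_Sh_D=case.solver.fixed_Sh_D)


def tune_ultrafiltration(op: DarcyOperator, target: float, p_out0: float,
                         p_other, onc_sign: float, p_onc: float,
                         tol_frac: float) -> tuple[float, FlowField]:
    """Find the blood outlet pressure giving the target ultrafiltration rate.

    Q_UF(p_out) is affine for a linear Darcy system, so a single secant
    step from two probes lands on the root; a final solve verifies it.
    """
    if target >= op.spec.Q_in:
        raise ValueError("ultrafiltration target must be below the inlet flow")
    ff = op.solve(p_out=p_out0, p_other=p_other, onc_sign=onc_sign, p_onc=p_onc)
    q_uf = ff.Q_in - ff.Q_out
    tol = tol_frac * max(abs(target), 1e-30)
    for _ in range(6):
        if abs(q_uf - target) <= tol:
            return p_out0, ff
        dp = 500.0
        ff2 = op.solve(p_out=p_out0 + dp, p_other=p_other, onc_sign=onc_sign,
                       p_onc=p_onc)
        slope = ((ff2.Q_in - ff2.Q_out) - q_uf) / dp
        if slope == 0.0:
            raise ValueError("ultrafiltration target unreachable: leak does "
                             "not respond to outlet pressure (L_p = 0?)")
        p_out0 = p_out0 + (target - q_uf) / slope
        ff = op.solve(p_out=p_out0, p_other=p_other, onc_sign=onc_sign,
                      p_onc=p_onc)
        q_uf = ff.Q_in - ff.Q_out
    raise ValueError(f"ultrafiltration tuning failed: Q_UF={q_uf:.3e}, "
                     f"target={target:.3e}")


def run_coupled(case: CaseConfig, mesh=None) -> "report.RunResult":
    """Run the alternating coupling to convergence and post-process."""
    if mesh is None:
        mesh = build_mesh(case.geometry, case.resolution)
        patch_faces(mesh, case.port_layout)
    mem = case.membrane
    beta = mem.A_ext / case.geometry.V_tot * mem.L_p   # 1/(Pa s)
    eta = mem.A_ext / case.geometry.V_tot * mesh.vol   # m^2 per cell

    blood_op = DarcyOperator(mesh, case.blood, "blood:inlet", "blood:outlet",
                             leak=beta)
    dial_op = DarcyOperator(mesh, case.dialysate, "dialysate:inlet",
                            "dialysate:outlet", leak=beta)

    buf = ExchangeBuffer.zeros(mesh.n_cells)
    history: list[IterationRecord] = []
    cl_history: list[float] = []
    s = case.solver
    tune = mem.L_p > 0 and case.Q_UF > 0
    # initial guess: uniform transmembrane pressure matching the UF target
    p_B_out = (case.Q_UF / (beta * case.geometry.V_tot) + mem.p_onc
               if tune else case.blood.p_out)
    prev = {"blood": (np.nan, np.nan), "dialysate": (np.nan, np.nan)}
    Q_Bi = case.blood.Q_in
    C_Bi = case.blood.C_in
    blood_ff = dial_ff = None
    blood_cf = dial_cf = None
    ts = None
    converged = False

    for step in range(1, s.max_steps + 1):
        # ---- blood step
        if tune:
            p_B_out, blood_ff = tune_ultrafiltration(
                blood_op, case.Q_UF, p_B_out, buf.p_D, +1.0, mem.p_onc,
                s.uf_tol)
        else:
            blood_ff = blood_op.solve(p_out=p_B_out, p_other=buf.p_D,
                                      onc_sign=+1.0, p_onc=mem.p_onc)
        ts = _transfer(case, buf.u_t_D)
        g = 0.5 * mem.L_p * (blood_ff.p - buf.p_D - mem.p_onc) * (1 - mem.sigma)
        diag_b = eta * (g + ts.U)
        rhs_b = eta * (ts.U - g) * buf.C_D
        A, rhs = assemble_transport(mesh, blood_ff, case.blood,
                                    "blood:inlet", "blood:outlet",
                                    diag_source=diag_b, rhs_source=rhs_b)
        blood_cf = solve_transport(A, rhs, mesh, blood_ff, "blood:inlet",
                                   "blood:outlet", case.blood,
                                   diag_source=diag_b, rhs_source=rhs_b)
        buf.update("blood", blood_ff.p, blood_cf.C, s.relax)
        cl = report.clearance(Q_Bi * report.M3S_TO_MLMIN, C_Bi,
                              blood_ff.Q_out * report.M3S_TO_MLMIN,
                              blood_cf.C_out)
        cl_history.append(cl)
        dq = _rel(blood_ff.Q_out, prev["blood"][0])
        dc = _rel(blood_cf.C_out, prev["blood"][1])
        history.append(IterationRecord(step, "blood", blood_ff.Q_out,
                                       blood_cf.C_out, cl, dq, dc))
        prev["blood"] = (blood_ff.Q_out, blood_cf.C_out)

        # ---- dialysate step
        dial_ff = dial_op.solve(p_other=buf.p_B, onc_sign=-1.0,
                                p_onc=mem.p_onc)
        u_t = np.hypot(dial_ff.u[:, 0], dial_ff.u[:, 1])
        ts = _transfer(case, u_t)
        g = 0.5 * mem.L_p * (buf.p_B - dial_ff.p - mem.p_onc) * (1 - mem.sigma)
        diag_d = eta * (ts.U - g)
        rhs_d = eta * (ts.U + g) * buf.C_B
        A, rhs = assemble_transport(mesh, dial_ff, case.dialysate,
                                    "dialysate:inlet", "dialysate:outlet",
                                    diag_source=diag_d, rhs_source=rhs_d)
        dial_cf = solve_transport(A, rhs, mesh, dial_ff, "dialysate:inlet",
                                  "dialysate:outlet", case.dialysate,
                                  diag_source=diag_d, rhs_source=rhs_d)
        buf.update("dialysate", dial_ff.p, dial_cf.C, s.relax, u_t=u_t)
        dq = _rel(dial_ff.Q_out, prev["dialysate"][0])
        dc = _rel(dial_cf.C_out, prev["dialysate"][1])
        history.append(IterationRecord(step, "dialysate", dial_ff.Q_out,
                                       dial_cf.C_out, cl, dq, dc))
        prev["dialysate"] = (dial_ff.Q_out, dial_cf.C_out)

        recent = history[-2:]
        if step >= s.min_steps and all(
                r.rel_change_Q < s.tol and r.rel_change_C < s.tol
                for r in recent):
            converged = True
            break

    if not converged:
        raise ConvergenceError(
            f"no convergence in {s.max_steps} steps per side", history)

    # ---- final exchange fields at the converged state
    j, j_conv, j_diff = solute_flux(buf.p_B, buf.p_D, buf.C_B, buf.C_D,
                                    ts.U, mem)
    ts.j, ts.j_conv, ts.j_diff = j, j_conv, j_diff

    return report.RunResult(
        case_name=case.name,
        CL=cl_history[-1],
        dp_B=report.pressure_drop(mesh, blood_op, blood_ff, p_B_out),
        dp_D=report.pressure_drop(mesh, dial_op, dial_ff,
                                  case.dialysate.p_out),
        Sh_avg=report.average_sherwood(ts, mesh),
        UF_pct=report.uf_contribution(ts, mesh),
        Q_Bi=Q_Bi, Q_Bo=blood_ff.Q_out, C_Bi=C_Bi, C_Bo=blood_cf.C_out,
        Q_Di=case.dialysate.Q_in, Q_Do=dial_ff.Q_out, C_Do=dial_cf.C_out,
        p_B_out=p_B_out,
        Q_UF=Q_Bi - blood_ff.Q_out,
        n_steps=step,
        cl_history=cl_history,
        history=history,
        fields={"p_B": buf.p_B, "C_B": buf.C_B, "u_B": blood_ff.u,
                "p_D": buf.p_D, "C_D": buf.C_D, "u_D": dial_ff.u,
                "Sh_D": np.broadcast_to(ts.Sh_D, (mesh.n_cells,)).copy(),
                "Re_t": np.broadcast_to(ts.Re_t, (mesh.n_cells,)).copy()},
        mesh=mesh,
    )
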