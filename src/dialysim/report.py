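"""Performance metrics and result export.

Clearance, per-side pressure drops, the volume-averaged shell Sherwood
number and the percentage contribution of ultrafiltration to solute
transport -- plus CSV/JSON tables, VTK field files and a clearance bar
chart for multi-case sweeps.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

M3S_TO_MLMIN = 6.0e7


@dataclass
class RunResult:
    case_name: str
    CL: float                    # mL/min
    dp_B: float                  # Pa
    dp_D: float                  # Pa
    Sh_avg: float
    UF_pct: float
    Q_Bi: float                  # m^3/s
    Q_Bo: float
    C_Bi: float                  # mol/m^3
    C_Bo: float
    Q_Di: float
    Q_Do: float
    C_Do: float
    p_B_out: float               # Pa, tuned blood outlet pressure
    Q_UF: float                  # m^3/s achieved
    n_steps: int
    cl_history: list = field(default_factory=list)
    history: list = field(default_factory=list)
    fields: dict = field(default_factory=dict)
    mesh: object = None

    def summary(self) -> dict:
        return {
            "case": self.case_name,
            "dp_B_Pa": round(self.dp_B, 1),
            "dp_D_Pa": round(self.dp_D, 1),
            "Sh_D_avg": round(self.Sh_avg, 2),
            "CL_ml_min": round(self.CL, 1),
            "UF_pct": round(self.UF_pct, 2),
            "Q_UF_ml_min": round(self.Q_UF * M3S_TO_MLMIN, 3),
            "n_steps": self.n_steps,
        }


def clearance(Q_Bi, C_Bi, Q_Bo, C_Bo) -> float:
    """Solute clearance (Q_Bi C_Bi - Q_Bo C_Bo)/C_Bi, in the flow-rate
    units of the inputs."""
    if C_Bi <= 0:
        raise ValueError("inlet concentration must be positive")
    return (Q_Bi * C_Bi - Q_Bo * C_Bo) / C_Bi


def pressure_drop(mesh, op, ff, p_out: float) -> float:
    """Area-weighted mean inlet-face pressure minus the imposed outlet
    pressure (end manifolds are outside the computational domain)."""
    faces = op.inlet_faces
    p_face = ff.p[mesh.b_own[faces]].copy()
    ok = op.T_in > 0
    p_face[ok] -= ff.F_bnd[faces][ok] / op.T_in[ok]
    a = mesh.b_area[faces]
    return float((p_face * a).sum() / a.sum() - p_out)


def pressure_drops(mesh, blood_op, blood_ff, p_B_out,
                   dial_op, dial_ff, p_D_out) -> tuple[float, float]:
    return (pressure_drop(mesh, blood_op, blood_ff, p_B_out),
            pressure_drop(mesh, dial_op, dial_ff, p_D_out))


def average_sherwood(transfer_state, mesh) -> float:
    """Volume-weighted mean shell-side Sherwood number."""
    sh = np.broadcast_to(transfer_state.Sh_D, (mesh.n_cells,))
    return float((sh * mesh.vol).sum() / mesh.vol.sum())


def uf_contribution(transfer_state, mesh) -> float:
    """Percent of the integrated transmembrane solute flux carried by
    ultrafiltration (the convective addend)."""
    j = np.broadcast_to(transfer_state.j, (mesh.n_cells,))
    jc = np.broadcast_to(transfer_state.j_conv, (mesh.n_cells,))
    tot = float((j * mesh.vol).sum())
    if tot == 0.0:
        raise ValueError("zero net transmembrane flux; UF share undefined")
    return 100.0 * float((jc * mesh.vol).sum()) / tot


def results_table(results: list[RunResult]) -> pd.DataFrame:
    if not results:
        import warnings
        warnings.warn("no results to tabulate")
        return pd.DataFrame(columns=["case", "dp_B_Pa", "dp_D_Pa", "Sh_D_avg",
                                     "CL_ml_min", "UF_pct", "Q_UF_ml_min",
                                     "n_steps"])
    return pd.DataFrame([r.summary() for r in results])


def write_report(results: list[RunResult], outdir, vtk: bool = True,
                 chart: bool = True) -> Path:
    """Write the summary CSV/JSON, per-case VTK fields and the clearance
    bar chart; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = results_table(results)
    df.to_csv(outdir / "summary.csv", index=False)
    (outdir / "summary.json").write_text(
        json.dumps(df.to_dict(orient="records"), indent=1))
    if vtk:
        from .io_vtk import write_vtk_fields
        for r in results:
            if r.mesh is not None and r.fields:
                write_vtk_fields(r.mesh, r.fields,
                                 outdir / f"{r.case_name}.vtk")
    if chart and len(results):
        _bar_chart(df, outdir / "clearance.png")
    return outdir


def _bar_chart(df: pd.DataFrame, path: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    families = {"1": "tab:orange", "2": "gold", "3": "tab:green",
                "4": "skyblue"}
    colors = [families.get(str(c)[0], "gray") for c in df["case"]]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(df["case"].astype(str), df["CL_ml_min"], color=colors)
    ax.set_ylabel("urea clearance CL (mL/min)")
    ax.set_xlabel("configuration")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
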