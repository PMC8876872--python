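import numpy as np
import pytest

from dialysim.mesh import StructuredMesh, LOC_D2_MIN, LOC_D2_MAX
from dialysim.flow import PorousSideSpec, FlowField
from dialysim.transport import (assemble_transport, solve_transport,
                                TransportError)
from dialysim.reference import make_fixture


def uniform_flow_column(fx, n, D=1e-12):
    """A column mesh with an imposed uniform axial plug flow."""
    w = np.sqrt(fx["A_cross"])
    m = StructuredMesh("cartesian", [0, w], [0, w],
                       np.linspace(0, fx["L"], n + 1))
    m.assign_patch("blood:inlet", np.flatnonzero(m.b_loc == LOC_D2_MIN))
    m.assign_patch("blood:outlet", np.flatnonzero(m.b_loc == LOC_D2_MAX))
    spec = PorousSideSpec("blood", 0.29, 3.4e-10, 0.0, 1000.0, 3.5e-3, D,
                          Q_in=fx["u"] * fx["A_cross"], C_in=fx["C_in"])
    Q = spec.Q_in
    F_int = np.where(m.f_dir == 2, Q, 0.0)
    F_bnd = np.zeros(m.n_bnd)
    F_bnd[m.patches["blood:inlet"]] = -Q
    F_bnd[m.patches["blood:outlet"]] = Q
    ff = FlowField(p=np.zeros(m.n_cells), u=m.cell_velocities(F_int, F_bnd),
                   F_int=F_int, F_bnd=F_bnd, Q_in=Q, Q_out=Q,
                   source_volume=0.0)
    return m, spec, ff


def test_advection_with_sink_matches_exponential_profile():
    fx = make_fixture("advection_1d")
    n = 400
    m, spec, ff = uniform_flow_column(fx, n)
    sink = fx["sink_rate"] * m.vol        # m^3/s implicit coefficient
    A, rhs = assemble_transport(m, ff, spec, "blood:inlet", "blood:outlet",
                                diag_source=sink, rhs_source=0.0)
    cf = solve_transport(A, rhs, m, ff, "blood:inlet", "blood:outlet", spec,
                         diag_source=sink, rhs_source=0.0)
    z = m.centers_native[:, 2]
    exact = fx["profile"](z)
    assert np.max(np.abs(cf.C - exact) / fx["C_in"]) < 0.01  # first order
    # relative error at the outlet grows like N (dz)^2 in the exponent
    assert cf.C_out == pytest.approx(float(fx["profile"](fx["L"])), rel=0.05)


def test_upwind_first_order_convergence():
    fx = make_fixture("advection_1d")
    errs = []
    for n in (100, 200, 400):
        m, spec, ff = uniform_flow_column(fx, n)
        sink = fx["sink_rate"] * m.vol
        A, rhs = assemble_transport(m, ff, spec, "blood:inlet",
                                    "blood:outlet", diag_source=sink)
        cf = solve_transport(A, rhs, m, ff, "blood:inlet", "blood:outlet",
                             spec, diag_source=sink)
        errs.append(np.max(np.abs(cf.C - fx["profile"](m.centers_native[:, 2]))))
    order = np.log2(errs[0] / errs[1]), np.log2(errs[1] / errs[2])
    assert min(order) > 0.9


def test_pure_advection_preserves_inlet_value():
    fx = make_fixture("advection_1d")
    m, spec, ff = uniform_flow_column(fx, 30)
    A, rhs = assemble_transport(m, ff, spec, "blood:inlet", "blood:outlet")
    cf = solve_transport(A, rhs, m, ff, "blood:inlet", "blood:outlet", spec)
    assert np.allclose(cf.C, fx["C_in"], rtol=1e-10)
    assert cf.inflow == pytest.approx(cf.outflow, rel=1e-10)


def test_boundedness_with_source_split():
    # implicit own-side sink + explicit frozen opposite side keeps C within
    # the inlet bounds even for a strong exchange
    fx = make_fixture("advection_1d")
    m, spec, ff = uniform_flow_column(fx, 60)
    U = 5e-4 * m.vol / m.vol.mean()
    C_other = 7.0
    A, rhs = assemble_transport(m, ff, spec, "blood:inlet", "blood:outlet",
                                diag_source=U, rhs_source=U * C_other)
    cf = solve_transport(A, rhs, m, ff, "blood:inlet", "blood:outlet", spec,
                         diag_source=U, rhs_source=U * C_other)
    assert cf.C.min() >= min(C_other, fx["C_in"]) - 1e-12
    assert cf.C.max() <= max(C_other, fx["C_in"]) + 1e-12


def test_missing_flow_rejected():
    fx = make_fixture("advection_1d")
    m, spec, _ = uniform_flow_column(fx, 10)
    with pytest.raises(TransportError):
        assemble_transport(m, None, spec, "blood:inlet", "blood:outlet")
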