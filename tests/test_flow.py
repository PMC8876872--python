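import numpy as np
import pytest

from dialysim.mesh import StructuredMesh, LOC_D2_MIN, LOC_D2_MAX
from dialysim.flow import (PorousSideSpec, DarcyOperator, assemble_darcy,
                           solve_flow, FlowError)
from dialysim.reference import make_fixture


def column_mesh(fx, n=None):
    n = n or fx["n_cells"]
    w = np.sqrt(fx["A_cross"])
    return StructuredMesh("cartesian", [0, w], [0, w],
                          np.linspace(0, fx["L"], n + 1))


def setup_column(fx, n=None):
    m = column_mesh(fx, n)
    m.assign_patch("blood:inlet", np.flatnonzero(m.b_loc == LOC_D2_MIN))
    m.assign_patch("blood:outlet", np.flatnonzero(m.b_loc == LOC_D2_MAX))
    return m


def test_darcy_1d_exact_pressure_drop():
    fx = make_fixture("darcy_1d")
    m = setup_column(fx)
    op, src = assemble_darcy(m, fx["spec"])
    ff = solve_flow(op)
    # cell-centre extrapolated inlet pressure equals the closed form
    from dialysim.report import pressure_drop
    dp = pressure_drop(m, op, ff, fx["spec"].p_out)
    assert dp == pytest.approx(fx["expected_dp"], rel=1e-10)
    assert ff.Q_out == pytest.approx(fx["spec"].Q_in, rel=1e-12)


def test_darcy_mass_balance_with_leak():
    fx = make_fixture("darcy_1d")
    m = setup_column(fx)
    op = DarcyOperator(m, fx["spec"], "blood:inlet", "blood:outlet",
                       leak=1e-9)
    ff = op.solve(p_out=0.0, p_other=0.0, onc_sign=+1.0, p_onc=0.0)
    assert ff.Q_in - ff.Q_out + ff.source_volume == pytest.approx(
        0.0, abs=1e-12 * ff.Q_in)
    # positive pressures leak outward: this side loses volume
    assert ff.source_volume < 0


def test_blocked_transverse_direction():
    # lumen K_t = 0: transverse velocities vanish identically
    fx = make_fixture("darcy_1d")
    m = setup_column(fx)
    op, _ = assemble_darcy(m, fx["spec"])
    ff = solve_flow(op)
    assert np.allclose(ff.u[:, :2], 0.0)
    assert np.allclose(ff.u[:, 2], fx["spec"].Q_in / fx["A_cross"],
                       rtol=1e-10)


def test_explicit_mass_source_changes_outflow():
    fx = make_fixture("darcy_1d")
    m = setup_column(fx)
    spec = fx["spec"]
    S_M = np.full(m.n_cells, -0.5)  # kg m^-3 s^-1, uniform loss
    op, src = assemble_darcy(m, spec, mass_source_field=S_M)
    ff = solve_flow(op, extra_source=src)
    lost = 0.5 * m.total_volume() / spec.rho
    assert ff.Q_out == pytest.approx(spec.Q_in - lost, rel=1e-10)


def test_singular_system_detected():
    fx = make_fixture("darcy_1d")
    m = column_mesh(fx)
    m.assign_patch("blood:inlet", np.flatnonzero(m.b_loc == LOC_D2_MIN))
    m.assign_patch("blood:outlet", np.flatnonzero(m.b_loc == LOC_D2_MAX))
    spec = PorousSideSpec("blood", 0.29, 3.4e-10, 0.0, 1000.0, 3.5e-3,
                          7.4e-10, Q_in=5e-6)
    # block every internal axial face: outlet cells still see the Dirichlet
    # face but upstream cells become isolated -> singular
    m.block_internal("blood", np.ones(m.n_int, bool))
    with pytest.raises(FlowError):
        DarcyOperator(m, spec, "blood:inlet", "blood:outlet")


def test_spec_validation():
    with pytest.raises(ValueError):
        PorousSideSpec("blood", 1.2, 3.4e-10, 0.0, 1000.0, 3.5e-3, 7.4e-10,
                       Q_in=5e-6)
    with pytest.raises(ValueError):
        PorousSideSpec("blood", 0.29, 0.0, 0.0, 1000.0, 3.5e-3, 7.4e-10,
                       Q_in=5e-6)
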