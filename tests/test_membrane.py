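import numpy as np
import pytest

from dialysim.membrane import (MembraneSpec, SoluteSpec, sherwood_shell,
                               hydraulic_diameter, transverse_reynolds,
                               transfer_coefficients, solute_flux,
                               mass_source, SH_B)


def test_sherwood_axial_limit():
    assert sherwood_shell(0.0) == pytest.approx(9.85, abs=0)


def test_sherwood_hand_values():
    assert sherwood_shell(1.0) == pytest.approx(9.85 * (1 + 1.41), rel=1e-12)
    assert sherwood_shell(0.01) == pytest.approx(
        9.85 * (1 + 1.41 * 0.01 ** 0.38), rel=1e-12)
    assert sherwood_shell(0.01) == pytest.approx(12.26, abs=0.01)


def test_sherwood_negative_reynolds_rejected():
    with pytest.raises(ValueError):
        sherwood_shell(-1.0)


def test_hydraulic_diameter():
    mem = MembraneSpec()
    d_h = hydraulic_diameter(mem.d_o, 0.51)
    assert mem.d_o == pytest.approx(260e-6, rel=1e-12)
    assert d_h == pytest.approx(2.706e-4, rel=1e-3)


def test_lumen_coefficient_chain():
    mem, sol = MembraneSpec(), SoluteSpec()
    ts = transfer_coefficients(0.0, mem, sol, rho_D=1000.0, mu_D=7.62e-4,
                               eps_shell=0.51)
    assert ts.k_B == pytest.approx(SH_B * 7.4e-10 / 200e-6, rel=1e-12)
    assert ts.k_B == pytest.approx(1.48e-5, rel=1e-3)


def test_overall_coefficient_hand_value():
    # frozen Sh_D = 14.1: k_D ~ 9.38e-5, U ~ 5.91e-6
    mem, sol = MembraneSpec(), SoluteSpec()
    ts = transfer_coefficients(0.0, mem, sol, rho_D=1000.0, mu_D=7.62e-4,
                               eps_shell=0.51, fixed_Sh_D=14.1)
    assert float(ts.k_D[0]) == pytest.approx(9.38e-5, rel=2e-3)
    assert float(ts.U[0]) == pytest.approx(5.91e-6, rel=2e-3)


def test_overall_coefficient_below_each_resistance():
    mem, sol = MembraneSpec(), SoluteSpec()
    ts = transfer_coefficients(np.array([0.0, 0.01, 0.1]), mem, sol,
                               rho_D=1000.0, mu_D=7.62e-4, eps_shell=0.51)
    assert np.all(ts.U < ts.k_B)
    assert np.all(ts.U < mem.k_M)
    assert np.all(ts.U < ts.k_D)


def test_transverse_reynolds_linear():
    d_h = hydraulic_diameter(260e-6, 0.51)
    assert transverse_reynolds(0.02, 1000.0, 7.62e-4, d_h) == pytest.approx(
        1000.0 * 0.02 * d_h / 7.62e-4, rel=1e-12)


def test_solute_flux_diffusive_hand_value():
    mem = MembraneSpec()
    j, jc, jd = solute_flux(0.0, 0.0, 20.0, 0.0, 5.91e-6, mem)
    assert jc == pytest.approx(0.0, abs=0)
    assert jd == pytest.approx(1.182e-4, rel=1e-6)
    assert j == pytest.approx(jd)


def test_solute_flux_antisymmetric_in_concentrations():
    mem = MembraneSpec()
    j1, _, _ = solute_flux(0.0, 0.0, 15.0, 5.0, 5.91e-6, mem)
    j2, _, _ = solute_flux(0.0, 0.0, 5.0, 15.0, 5.91e-6, mem)
    assert j1 == pytest.approx(-j2, rel=1e-12)


def test_mass_source_hand_value_and_antisymmetry():
    mem = MembraneSpec()
    s_b = mass_source(1.0e4, 0.0, mem, V_tot=3.07e-4, rho=1000.0, side="blood")
    s_d = mass_source(1.0e4, 0.0, mem, V_tot=3.07e-4, rho=1000.0,
                      side="dialysate")
    assert abs(float(s_b)) == pytest.approx(3.65, rel=2e-3)
    assert float(s_b) < 0 < float(s_d)
    assert float(s_b) == pytest.approx(-float(s_d), rel=1e-12)
    with pytest.raises(ValueError):
        mass_source(0.0, 0.0, mem, 3.07e-4, 1000.0, side="membrane")


def test_spec_validation():
    with pytest.raises(ValueError):
        MembraneSpec(L_p=0.0)
    with pytest.raises(ValueError):
        MembraneSpec(sigma=1.5)
    with pytest.raises(ValueError):
        SoluteSpec(D_B=-1e-9)


def test_lumen_porosity_consistency():
    # lumen porosity ~ shell fiber fraction x (d_i/d_o)^2
    mem = MembraneSpec()
    assert (1 - 0.51) * (mem.d_i / mem.d_o) ** 2 == pytest.approx(0.29,
                                                                  abs=0.001)
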