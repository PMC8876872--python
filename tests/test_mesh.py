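import numpy as np
import pytest

from dialysim.mesh import (StructuredMesh, MeshError,
                           LOC_D2_MIN, LOC_D2_MAX, LOC_D0_MAX)


def box(n=(4, 5, 6), L=(0.1, 0.2, 0.3)):
    return StructuredMesh("cartesian",
                          np.linspace(0, L[0], n[0] + 1),
                          np.linspace(0, L[1], n[1] + 1),
                          np.linspace(0, L[2], n[2] + 1))


def cylinder(n=(4, 8, 6), R=0.02, L=0.3):
    return StructuredMesh("cylindrical",
                          np.linspace(0, R, n[0] + 1),
                          np.linspace(0, 2 * np.pi, n[1] + 1),
                          np.linspace(0, L, n[2] + 1))


def test_cartesian_volume_closure():
    m = box()
    assert m.total_volume() == pytest.approx(0.1 * 0.2 * 0.3, rel=1e-12)


def test_cylindrical_volume_closure():
    m = cylinder()
    assert m.total_volume() == pytest.approx(np.pi * 0.02 ** 2 * 0.3, rel=1e-12)


def test_cylindrical_is_periodic_in_theta():
    m = cylinder()
    assert m.periodic2
    # no theta boundary faces, no inner radial boundary at the axis
    assert set(np.unique(m.b_loc)) == {LOC_D0_MAX, LOC_D2_MIN, LOC_D2_MAX}


def test_half_cylinder_not_periodic():
    m = StructuredMesh("cylindrical", np.linspace(0.0, 0.02, 4),
                       np.linspace(0, np.pi, 5), np.linspace(0, 0.1, 4))
    assert not m.periodic2


def test_face_areas_close_each_cell():
    # sum of signed face areas per direction closes for interior cells
    m = box()
    total_bnd = m.b_area.sum()
    expected = 2 * (0.2 * 0.3 + 0.1 * 0.3 + 0.1 * 0.2)
    assert total_bnd == pytest.approx(expected, rel=1e-12)


def test_transmissibility_harmonic_and_blocked():
    m = box(n=(2, 1, 1))
    lam = np.ones((m.n_cells, 3))
    T_int, T_bnd = m.transmissibility(lam)
    # uniform mobility: T = A / d for the single internal x-face
    f = np.flatnonzero(m.f_dir == 0)
    assert f.size == 1
    assert T_int[f[0]] == pytest.approx(m.f_area[f[0]] /
                                        (m.f_d_own[f[0]] + m.f_d_nb[f[0]]))
    # zero mobility on one side blocks the face, no division error
    lam[0] = 0.0
    T_int, _ = m.transmissibility(lam)
    assert T_int[f[0]] == 0.0


def test_cell_velocities_uniform_axial_flow():
    m = box(n=(3, 3, 5))
    q = 2.5e-4  # superficial velocity m/s
    F_int = np.where(m.f_dir == 2, q * m.f_area, 0.0)
    F_bnd = np.zeros(m.n_bnd)
    F_bnd[m.b_loc == LOC_D2_MIN] = -q * m.b_area[m.b_loc == LOC_D2_MIN]
    F_bnd[m.b_loc == LOC_D2_MAX] = q * m.b_area[m.b_loc == LOC_D2_MAX]
    u = m.cell_velocities(F_int, F_bnd)
    assert np.allclose(u[:, 2], q, rtol=1e-12)
    assert np.allclose(u[:, :2], 0.0)


def test_patch_assignment_and_area():
    m = box()
    ids = np.flatnonzero(m.b_loc == LOC_D2_MIN)
    m.assign_patch("blood:inlet", ids)
    assert m.patch_area("blood:inlet") == pytest.approx(0.1 * 0.2, rel=1e-12)
    with pytest.raises(MeshError):
        m.assign_patch("empty", np.array([], int))


def test_block_internal_mask_shape_checked():
    m = box()
    with pytest.raises(MeshError):
        m.block_internal("dialysate", np.zeros(3, bool))
    mask = np.zeros(m.n_int, bool)
    mask[0] = True
    m.block_internal("dialysate", mask)
    assert m.blocked("dialysate")[0]
    assert not m.blocked("blood").any()


def test_bad_edges_rejected():
    with pytest.raises(MeshError):
        StructuredMesh("cartesian", [0.0, 0.0, 1.0], [0, 1], [0, 1])
    with pytest.raises(MeshError):
        StructuredMesh("spherical", [0, 1], [0, 1], [0, 1])
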