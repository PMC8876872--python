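import math

import numpy as np
import pytest

from dialysim.geometry import (derive_dimensions, build_mesh, patch_faces,
                               blood_end_ports, dialysate_ports,
                               GeometryError, PortPatch, SHAPES)
from dialysim.mesh import MeshError


def test_long_cylinder_calibrated_dimensions():
    geo = derive_dimensions("long_cyl")
    # L^2 = dp K_z V / (mu Q) with dp = 9833 Pa
    L = math.sqrt(9833.0 * 3.4e-10 * 307e-6 / (3.5e-3 * (300e-6 / 60)))
    assert geo.length == pytest.approx(L, rel=1e-12)
    assert geo.cross_area * geo.length == pytest.approx(307e-6, rel=1e-12)
    # plausible commercial envelope
    assert 0.15 < geo.length < 0.25
    assert 0.02 < geo.cross_section["diameter"] < 0.05


def test_short_cylinder_scaling():
    long = derive_dimensions("long_cyl")
    short = derive_dimensions("short_cyl")
    assert short.length == pytest.approx(long.length / 4.0, rel=1e-12)
    assert short.cross_section["diameter"] == pytest.approx(
        2.0 * long.cross_section["diameter"], rel=1e-12)
    assert short.cross_area * short.length == pytest.approx(307e-6, rel=1e-12)


def test_rectangles_share_volume_and_aspect():
    thick = derive_dimensions("thick_rect")
    flat = derive_dimensions("flat_rect")
    assert thick.cross_section["width"] == pytest.approx(
        thick.cross_section["height"], rel=1e-12)
    assert flat.cross_section["width"] / flat.cross_section["height"] == \
        pytest.approx(16.0, rel=1e-12)
    for g in (thick, flat):
        assert g.cross_area * g.length == pytest.approx(307e-6, rel=1e-12)


def test_all_shapes_consistent():
    for shape in SHAPES:
        geo = derive_dimensions(shape)
        assert geo.V_tot == pytest.approx(307e-6)
        assert geo.membrane_area == pytest.approx(1.7)


def test_inconsistent_constraints_raise():
    with pytest.raises(GeometryError):
        derive_dimensions("long_cyl", membrane_area=5.0)
    with pytest.raises(GeometryError):
        derive_dimensions("hexagonal")


def test_build_mesh_volume_closure():
    for shape in SHAPES:
        geo = derive_dimensions(shape)
        m = build_mesh(geo, (6, 8, 12))
        assert m.total_volume() == pytest.approx(geo.V_tot, rel=5e-3)


def test_build_mesh_minimum_resolution():
    geo = derive_dimensions("long_cyl")
    with pytest.raises(MeshError):
        build_mesh(geo, (2, 8, 12))


def test_coaxial_partition_blocks_dialysate_only():
    geo = derive_dimensions("coaxial_cyl")
    m = build_mesh(geo, (8, 8, 12))
    blocked = m.blocked("dialysate")
    assert blocked.any()
    assert not m.blocked("blood").any()
    # blocked faces are axial and lie inside the partition radius
    r_own = m.centers_native[m.f_own, 0]
    R = geo.cross_section["diameter"] / 2
    assert np.all(m.f_dir[blocked] == 2)
    assert np.all(r_own[blocked] < R - geo.cross_section["annulus_width"])
    # the peripheral annulus stays open
    axial_inner = (m.f_dir == 2)
    assert (axial_inner & ~blocked).any()


def test_patch_faces_roles_and_areas():
    geo = derive_dimensions("long_cyl")
    m = build_mesh(geo, (6, 16, 24))
    layout = blood_end_ports() + dialysate_ports(geo, "8x8")
    patches = patch_faces(m, layout)
    assert set(patches) == {"blood:inlet", "blood:outlet",
                            "dialysate:inlet", "dialysate:outlet"}
    # blood ports are the full end faces
    assert m.patch_area("blood:inlet") == pytest.approx(geo.cross_area,
                                                        rel=1e-12)
    assert m.patch_area("dialysate:inlet") > 0


def test_overlapping_ports_rejected():
    geo = derive_dimensions("long_cyl")
    m = build_mesh(geo, (6, 16, 24))
    layout = blood_end_ports() + [
        PortPatch("dialysate", "inlet", {"surface": "end_minus", "full": True}),
        PortPatch("dialysate", "outlet", {"surface": "end_minus", "full": True}),
    ]
    with pytest.raises(GeometryError):
        patch_faces(m, layout)


def test_dialysate_needs_inlet_and_outlet():
    geo = derive_dimensions("long_cyl")
    m = build_mesh(geo, (6, 16, 24))
    layout = blood_end_ports() + [
        PortPatch("dialysate", "inlet",
                  {"surface": "shell", "theta": 0.0, "z": geo.length / 2,
                   "diameter": 8e-3}),
    ]
    with pytest.raises(GeometryError):
        patch_faces(m, layout)


def test_counter_current_port_bias():
    # dialysate inlets sit near the blood-outlet (z+) end
    geo = derive_dimensions("long_cyl")
    for arrangement in ("8x8", "1x1_same", "1x1_opposite"):
        ports = dialysate_ports(geo, arrangement)
        z_in = [p.location["z"] for p in ports if p.kind == "inlet"]
        z_out = [p.location["z"] for p in ports if p.kind == "outlet"]
        assert min(z_in) > max(z_out)


def test_slit_ports_span_full_length():
    geo = derive_dimensions("flat_rect")
    m = build_mesh(geo, (24, 6, 20))
    layout = blood_end_ports() + dialysate_ports(geo, "slit_cross")
    patches = patch_faces(m, layout)
    # full-length slit: inlet area equals height x length of one side wall
    cs = geo.cross_section
    assert m.patch_area("dialysate:inlet") == pytest.approx(
        cs["height"] * geo.length, rel=1e-12)
    assert m.patch_area("dialysate:outlet") == pytest.approx(
        m.patch_area("dialysate:inlet"), rel=1e-12)


def test_unknown_arrangement_raises():
    geo = derive_dimensions("long_cyl")
    with pytest.raises(GeometryError):
        dialysate_ports(geo, "3x3")
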