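"""Module geometries and inlet/outlet port layouts.

Five housing shapes are supported, all sharing the same membrane area
(1.7 m^2), shell-side porosity (0.51) and total volume (307 cm^3) but
differing in aspect ratio and port arrangement:

* ``long_cyl``    -- the commercial long cylindrical unit,
* ``short_cyl``   -- twice the diameter, a quarter of the length,
* ``thick_rect``  -- rectangular cross-flow housing, near-square section,
* ``flat_rect``   -- rectangular cross-flow housing, wide and thin,
* ``coaxial_cyl`` -- two axial compartments divided by a partition disc and
  joined by a peripheral annular passage (Liqui-Cel-style).

The fibre length of the long cylinder is not printed anywhere as a number;
it is recovered from the blood-side pressure drop via the exact 1-D axial
Darcy relation (the lumen flow is purely axial because its transverse
permeability is zero)::

    L**2 = dp_B * K_z * V_tot / (mu_B * Q_B)

which with dp_B = 9833 Pa, K_z = 3.4e-10 m^2, V_tot = 307 cm^3,
mu_B = 3.5e-3 Pa s and Q_B = 300 mL/min gives L = 0.2422 m and hence a
diameter of 4.02 cm -- inside the typical 2-5 cm / 15-25 cm commercial
range.  The same inversion with dp_B = 3347 Pa and 8132 Pa fixes the
rectangular (L = 0.1413 m) and coaxial (L = 0.2202 m) lengths.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

import numpy as np

from .mesh import StructuredMesh, MeshError, LOC_D0_MAX, LOC_D2_MIN, LOC_D2_MAX

SHAPES = ("long_cyl", "short_cyl", "thick_rect", "flat_rect", "coaxial_cyl")

# reference operating/physical constants used only for the geometric
# calibration of housing dimensions (blood side, axial Darcy flow)
_CAL = {
    "V_tot": 307e-6,          # m^3
    "membrane_area": 1.7,     # m^2
    "K_z": 3.4e-10,           # m^2 (lumen axial Darcy permeability)
    "mu_B": 3.5e-3,           # Pa s (blood)
    "Q_B": 300e-6 / 60.0,     # m^3/s (300 mL/min)
    "dp_B": {"long_cyl": 9833.0, "thick_rect": 3347.0,
             "flat_rect": 3347.0, "coaxial_cyl": 8132.0},
    "flat_aspect": 16.0,      # flat rectangle: width/height = 16 x the
                              # near-square thick section (4x wider, 4x thinner)
}


class GeometryError(ValueError):
    pass


@dataclass
class PortPatch:
    """One dialysate or blood opening on the housing boundary.

    ``location`` is a small descriptor dict understood by
    :func:`patch_faces`; see the selector functions there for keys.
    """
    side: str                  # "blood" | "dialysate"
    kind: str                  # "inlet" | "outlet"
    location: dict
    multiplicity: int = 1
    slit: bool = False


@dataclass
class ModuleGeometry:
    shape: str
    length: float                      # m, along the fiber axis
    cross_section: dict                # shape-dependent descriptor
    V_tot: float
    membrane_area: float
    fiber_axis: tuple = (0.0, 0.0, 1.0)
    port_layout: list = field(default_factory=list)

    @property
    def cross_area(self) -> float:
        cs = self.cross_section
        if "diameter" in cs:
            return math.pi * cs["diameter"] ** 2 / 4.0
        return cs["width"] * cs["height"]


def derive_dimensions(shape: str,
                      V_tot: float = _CAL["V_tot"],
                      membrane_area: float = _CAL["membrane_area"],
                      porosities: tuple = (0.29, 0.51),
                      fiber_dims: tuple = (200e-6, 30e-6),
                      flat_aspect: float = _CAL["flat_aspect"],
                      annulus_width: float = 3e-3,
                      ) -> ModuleGeometry:
    """Derive housing dimensions for a given shape from printed constraints.

    Raises :class:`GeometryError` when the constraint set is inconsistent
    (membrane area recomputed from volume, porosity and fiber dimensions
    deviating by more than 10% from the stated one).
    """
    if shape not in SHAPES:
        raise GeometryError(f"unknown shape {shape!r}")
    if V_tot <= 0 or membrane_area <= 0:
        raise GeometryError("V_tot and membrane_area must be positive")
    eps_lumen, eps_shell = porosities
    d_i, s = fiber_dims
    d_o = d_i + 2 * s

    # consistency: the fiber count implied by the shell porosity must give a
    # lumen-side membrane area within 10% of the stated one.
    n_fib_per_area = (1.0 - eps_shell) / (math.pi * d_o ** 2 / 4.0)

    def check_area(L, A_cross):
        n_fib = n_fib_per_area * A_cross
        a_inner = n_fib * math.pi * d_i * L
        if abs(a_inner - membrane_area) / membrane_area > 0.10:
            raise GeometryError(
                f"inconsistent constraints: membrane area from geometry "
                f"{a_inner:.3f} m^2 vs stated {membrane_area:.3f} m^2")

    def length_from_dp(dp):
        return math.sqrt(dp * _CAL["K_z"] * V_tot / (_CAL["mu_B"] * _CAL["Q_B"]))

    if shape in ("long_cyl", "short_cyl"):
        L_long = length_from_dp(_CAL["dp_B"]["long_cyl"])
        A_long = V_tot / L_long
        D_long = math.sqrt(4 * A_long / math.pi)
        if shape == "long_cyl":
            L, D = L_long, D_long
        else:  # short cylinder: 2x diameter, 1/4 length; volume unchanged
            L, D = L_long / 4.0, 2.0 * D_long
        check_area(L, math.pi * D ** 2 / 4.0)
        return ModuleGeometry(shape, L, {"diameter": D}, V_tot, membrane_area)

    if shape in ("thick_rect", "flat_rect"):
        L = length_from_dp(_CAL["dp_B"][shape])
        A = V_tot / L
        if shape == "thick_rect":
            w = h = math.sqrt(A)
        else:
            w = math.sqrt(A * flat_aspect)
            h = A / w
        check_area(L, A)
        return ModuleGeometry(shape, L, {"width": w, "height": h},
                              V_tot, membrane_area)

    # coaxial cylinder
    L = length_from_dp(_CAL["dp_B"]["coaxial_cyl"])
    A = V_tot / L
    D = math.sqrt(4 * A / math.pi)
    check_area(L, A)
    cs = {"diameter": D, "partition_z": L / 2.0, "annulus_width": annulus_width}
    return ModuleGeometry("coaxial_cyl", L, cs, V_tot, membrane_area)


# ---------------------------------------------------------------------- meshing
def build_mesh(geometry: ModuleGeometry, resolution) -> StructuredMesh:
    """Build the structured hexahedral mesh for a module geometry.

    ``resolution`` is ``(n1, n2, n3)``: (nr, ntheta, nz) for cylinders,
    (nx, ny, nz) for rectangles, each >= 3.  For the coaxial shape the
    mid-length partition disc is inserted as dialysate-blocked internal
    faces (the blood, confined to the fiber lumina, passes through).
    """
    n1, n2, n3 = (int(v) for v in resolution)
    if min(n1, n2, n3) < 3:
        raise MeshError("resolution must be >= 3 cells per direction")
    L = geometry.length
    cs = geometry.cross_section
    if "diameter" in cs:
        R = cs["diameter"] / 2.0
        # align z edges with the partition plane if present
        if geometry.shape == "coaxial_cyl" and n3 % 2:
            n3 += 1
        mesh = StructuredMesh(
            "cylindrical",
            np.linspace(0.0, R, n1 + 1),
            np.linspace(0.0, 2 * np.pi, n2 + 1),
            np.linspace(0.0, L, n3 + 1),
        )
    else:
        mesh = StructuredMesh(
            "cartesian",
            np.linspace(-cs["width"] / 2, cs["width"] / 2, n1 + 1),
            np.linspace(-cs["height"] / 2, cs["height"] / 2, n2 + 1),
            np.linspace(0.0, L, n3 + 1),
        )
    vol_err = abs(mesh.total_volume() - geometry.V_tot) / geometry.V_tot
    if vol_err > 0.005:
        raise MeshError(f"mesh volume off by {100*vol_err:.2f}%")

    if geometry.shape == "coaxial_cyl":
        _insert_partition(mesh, cs["partition_z"], R - cs["annulus_width"])
    return mesh


def _insert_partition(mesh, z_part, r_block):
    """Block dialysate axial flux through the partition disc (r < r_block)
    at the z-edge closest to ``z_part``."""
    e3 = mesh.edges[2]
    k = int(np.argmin(np.abs(e3[1:-1] - z_part))) + 1  # interior edge index
    z_edge = e3[k]
    r_own = mesh.centers_native[mesh.f_own, 0]
    # the two cells sandwiching the partition edge have centres straddling it
    mask = (mesh.f_dir == 2) & (mesh.centers_native[mesh.f_own, 2] < z_edge) & \
           (mesh.centers_native[mesh.f_nb, 2] > z_edge) & \
           (np.abs(0.5 * (mesh.centers_native[mesh.f_own, 2]
                          + mesh.centers_native[mesh.f_nb, 2]) - z_edge)
            < 0.51 * np.max(np.diff(e3))) & (r_own < r_block)
    mesh.block_internal("dialysate", mask)


# ---------------------------------------------------------------------- patches
def _wrap_angle(dth):
    return (dth + np.pi) % (2 * np.pi) - np.pi


def _select(mesh: StructuredMesh, loc: dict) -> np.ndarray:
    """Return boundary-face ids matching a port location descriptor."""
    surf = loc["surface"]
    c = mesh.b_center_native
    if surf == "shell":  # outer radial surface of a cylinder
        onsurf = mesh.b_loc == LOC_D0_MAX
        R = mesh.edges[0][-1]
        dz = c[:, 2] - loc["z"]
        darc = R * _wrap_angle(c[:, 1] - loc["theta"])
        if loc.get("slit", False):
            sel = onsurf & (np.abs(darc) <= loc["width"] / 2 + 1e-12)
            if not (sel & onsurf).any():
                # coarse theta grid: take the nearest face column
                amin = np.min(np.abs(darc)[onsurf])
                sel = onsurf & (np.abs(darc) <= amin + 1e-12)
            zr = loc.get("z_range")
            if zr is not None:
                sel &= (c[:, 2] >= zr[0]) & (c[:, 2] <= zr[1])
        else:
            d = loc["diameter"]
            sel = onsurf & (dz ** 2 + darc ** 2 <= (d / 2) ** 2)
            if not sel.any():  # coarse mesh: take the nearest shell face
                dist = np.where(onsurf, dz ** 2 + darc ** 2, np.inf)
                sel = np.zeros(mesh.n_bnd, bool)
                sel[int(np.argmin(dist))] = True
    elif surf in ("end_minus", "end_plus"):
        onsurf = mesh.b_loc == (LOC_D2_MIN if surf == "end_minus" else LOC_D2_MAX)
        if loc.get("full", False):
            sel = onsurf
        elif "r_max" in loc:  # central disc
            sel = onsurf & (c[:, 0] <= loc["r_max"] + 1e-12)
            if not sel.any():
                dist = np.where(onsurf, c[:, 0], np.inf)
                sel = np.zeros(mesh.n_bnd, bool)
                sel[int(np.argmin(dist))] = True
        else:  # small circle at (r_pos, theta) on the end face
            x = c[:, 0] * np.cos(c[:, 1]); y = c[:, 0] * np.sin(c[:, 1])
            x0 = loc["r_pos"] * np.cos(loc["theta"])
            y0 = loc["r_pos"] * np.sin(loc["theta"])
            d2 = (x - x0) ** 2 + (y - y0) ** 2
            sel = onsurf & (d2 <= (loc["diameter"] / 2) ** 2)
            if not sel.any():
                dist = np.where(onsurf, d2, np.inf)
                sel = np.zeros(mesh.n_bnd, bool)
                sel[int(np.argmin(dist))] = True
    elif surf in ("x_minus", "x_plus"):
        onsurf = mesh.b_loc == (0 if surf == "x_minus" else 1)
        sel = onsurf
        if "y_range" in loc:
            sel = sel & (c[:, 1] >= loc["y_range"][0]) & (c[:, 1] <= loc["y_range"][1])
        if "z_range" in loc:
            sel = sel & (c[:, 2] >= loc["z_range"][0]) & (c[:, 2] <= loc["z_range"][1])
        if not sel.any() and onsurf.any():
            sel = onsurf.copy()
    else:
        raise GeometryError(f"unknown port surface {surf!r}")
    return np.flatnonzero(sel)


def patch_faces(mesh: StructuredMesh, port_layout: list[PortPatch]) -> dict:
    """Resolve a port layout into named boundary patches on the mesh.

    Creates patches ``"<side>:<kind>"`` (faces of all ports of that role
    combined -- the imposed inlet flux is spread uniformly over them, which
    is the area-weighted equal-flux-density rule for multi-port inlets).
    Ports of the same side must not overlap.  Boundary faces left
    unassigned act as impermeable walls.
    """
    by_role: dict[str, list] = {}
    claimed: dict[str, np.ndarray] = {}
    sides = {p.side for p in port_layout}
    if "dialysate" in sides:
        kinds = {p.kind for p in port_layout if p.side == "dialysate"}
        if "inlet" not in kinds or "outlet" not in kinds:
            raise GeometryError("dialysate needs at least one inlet and one outlet")
    for p in port_layout:
        ids = _select(mesh, p.location)
        if ids.size == 0:
            raise GeometryError(f"port {p} selects no boundary faces")
        seen = claimed.setdefault(p.side, np.zeros(mesh.n_bnd, bool))
        if seen[ids].any():
            raise GeometryError(f"overlapping ports on side {p.side!r}")
        seen[ids] = True
        by_role.setdefault(f"{p.side}:{p.kind}", []).append(ids)
    out = {}
    for role, chunks in by_role.items():
        ids = np.concatenate(chunks)
        mesh.assign_patch(role, ids)
        out[role] = mesh.patches[role]
    return out


# ------------------------------------------------------------- standard layouts
def blood_end_ports() -> list[PortPatch]:
    """Blood enters the full z- end face and leaves the full z+ end face."""
    return [
        PortPatch("blood", "inlet", {"surface": "end_minus", "full": True}),
        PortPatch("blood", "outlet", {"surface": "end_plus", "full": True}),
    ]


def dialysate_ports(geometry: ModuleGeometry, arrangement: str,
                    port_diameter: float = 8e-3,
                    slit_width: float = 5e-3) -> list[PortPatch]:
    """Dialysate port layouts for the cylindrical and rectangular housings.

    ``arrangement``: ``"8x8"``, ``"1x1_same"``, ``"1x1_opposite"``,
    ``"slit"`` (cylinders); ``"slit_cross"`` (rectangles); ``"6x6"``,
    ``"4x1"``, ``"1x1"`` (coaxial).  Dialysate runs counter-current to the
    blood: its inlets sit near the blood-outlet (z+) end.
    """
    L = geometry.length
    ports: list[PortPatch] = []
    z_in = L - 1.0 * port_diameter
    z_out = 1.0 * port_diameter

    def ring(kind, z, n):
        for m in range(n):
            ports.append(PortPatch("dialysate", kind,
                                   {"surface": "shell", "theta": 2 * np.pi * m / n,
                                    "z": z, "diameter": port_diameter},
                                   multiplicity=n))

    if arrangement == "8x8":
        ring("inlet", z_in, 8)
        ring("outlet", z_out, 8)
    elif arrangement == "1x1_same":
        ring("inlet", z_in, 1)
        ring("outlet", z_out, 1)
    elif arrangement == "1x1_opposite":
        ring("inlet", z_in, 1)
        ports.append(PortPatch("dialysate", "outlet",
                               {"surface": "shell", "theta": np.pi, "z": z_out,
                                "diameter": port_diameter}))
    elif arrangement == "slit":
        ports.append(PortPatch("dialysate", "inlet",
                               {"surface": "shell", "theta": 0.0, "z": L / 2,
                                "slit": True, "width": slit_width}, slit=True))
        ports.append(PortPatch("dialysate", "outlet",
                               {"surface": "shell", "theta": np.pi, "z": L / 2,
                                "slit": True, "width": slit_width}, slit=True))
    elif arrangement == "slit_cross":
        # rectangular housings: full-length slits on the two faces normal to
        # the wide transverse direction (pure cross-flow)
        ports.append(PortPatch("dialysate", "inlet",
                               {"surface": "x_minus"}, slit=True))
        ports.append(PortPatch("dialysate", "outlet",
                               {"surface": "x_plus"}, slit=True))
    elif arrangement in ("6x6", "4x1", "1x1"):
        R = geometry.cross_section["diameter"] / 2.0
        r_pos = 0.45 * R
        d = min(port_diameter, 0.5 * R)
        n_in = {"6x6": 6, "4x1": 4, "1x1": 1}[arrangement]
        n_out = {"6x6": 6, "4x1": 1, "1x1": 1}[arrangement]

        def end_ring(kind, surf, n):
            if n == 1:
                ports.append(PortPatch("dialysate", kind,
                                       {"surface": surf, "r_max": 0.3 * R}))
            else:
                for m in range(n):
                    ports.append(PortPatch("dialysate", kind,
                                           {"surface": surf, "r_pos": r_pos,
                                            "theta": 2 * np.pi * m / n,
                                            "diameter": d}, multiplicity=n))
        # counter-current bias: dialysate enters at the blood-outlet end
        end_ring("inlet", "end_plus", n_in)
        end_ring("outlet", "end_minus", n_out)
    else:
        raise GeometryError(f"unknown dialysate arrangement {arrangement!r}")
    return ports
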