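"""Structured orthogonal finite-volume meshes.

Two coordinate systems are supported: Cartesian boxes ``(x, y, z)`` and
cylinders ``(r, theta, z)``, with the fiber bundle axis always along the
third logical direction.  Both hemodialyzer compartments (blood and
dialysate) share one mesh; per-side behaviour (blocked internal faces,
boundary patches) is carried as named masks on the mesh.

The mesh exposes exactly what a two-point-flux finite-volume solver needs:
cell volumes, internal faces (owner, neighbour, area, centre-to-face
distances, direction) and boundary faces grouped into named patches.
"""
from __future__ import annotations

import numpy as np

AXIAL = 2  # logical direction of the fiber axis

# boundary location codes
LOC_D0_MIN, LOC_D0_MAX = 0, 1
LOC_D1_MIN, LOC_D1_MAX = 2, 3
LOC_D2_MIN, LOC_D2_MAX = 4, 5


class MeshError(ValueError):
    pass


class StructuredMesh:
    """Orthogonal structured hexahedral mesh.

    Parameters
    ----------
    system : {"cartesian", "cylindrical"}
    e1, e2, e3 : array_like
        Monotone edge coordinates along the three logical directions.
        Cartesian: x, y, z [m].  Cylindrical: r [m], theta [rad], z [m];
        if ``e1[0] == 0`` the axis is included and no inner radial
        boundary exists; theta spanning a full circle makes direction 1
        periodic automatically.
    """

    def __init__(self, system: str, e1, e2, e3):
        if system not in ("cartesian", "cylindrical"):
            raise MeshError(f"unknown coordinate system {system!r}")
        self.system = system
        e1 = np.asarray(e1, float)
        e2 = np.asarray(e2, float)
        e3 = np.asarray(e3, float)
        for e in (e1, e2, e3):
            if e.size < 2 or np.any(np.diff(e) <= 0):
                raise MeshError("edge coordinates must be strictly increasing, >=2 each")
        n1, n2, n3 = e1.size - 1, e2.size - 1, e3.size - 1
        if min(n1, n2, n3) < 1:
            raise MeshError("degenerate mesh")
        self.edges = (e1, e2, e3)
        self.shape = (n1, n2, n3)
        self.n_cells = n1 * n2 * n3
        self.periodic2 = bool(
            system == "cylindrical" and abs((e2[-1] - e2[0]) - 2 * np.pi) < 1e-12
        )
        self._build_geometry()
        self._build_faces()
        self._build_cell_face_map()
        # named per-side masks over internal faces (True = blocked)
        self.face_blocks: dict[str, np.ndarray] = {}
        # named boundary patches: name -> array of boundary-face indices
        self.patches: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------ geometry
    def _build_geometry(self):
        e1, e2, e3 = self.edges
        n1, n2, n3 = self.shape
        c1 = 0.5 * (e1[:-1] + e1[1:])
        c2 = 0.5 * (e2[:-1] + e2[1:])
        c3 = 0.5 * (e3[:-1] + e3[1:])
        w1, w2, w3 = np.diff(e1), np.diff(e2), np.diff(e3)
        self.centers_native = np.stack(
            np.meshgrid(c1, c2, c3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        if self.system == "cylindrical":
            r2h = 0.5 * (e1[1:] ** 2 - e1[:-1] ** 2)  # int r dr per radial cell
            vol3 = r2h[:, None, None] * w2[None, :, None] * w3[None, None, :]
        else:
            vol3 = w1[:, None, None] * w2[None, :, None] * w3[None, None, :]
        self.vol = vol3.reshape(-1)
        self._c = (c1, c2, c3)
        self._w = (w1, w2, w3)
        r, t, z = self.centers_native.T
        if self.system == "cylindrical":
            self.centers_xyz = np.column_stack([r * np.cos(t), r * np.sin(t), z])
        else:
            self.centers_xyz = self.centers_native.copy()

    def _face_area(self, direction, i_edge, i2, i3):
        """Area of a face normal to `direction`; indices are (edge index along
        the direction, cell indices along the two remaining directions in
        logical order)."""
        e1, _, _ = self.edges
        w1, w2, w3 = self._w
        if self.system == "cartesian":
            if direction == 0:
                return w2[i2] * w3[i3]
            if direction == 1:
                return w1[i2] * w3[i3]
            return w1[i2] * w2[i3]
        # cylindrical (r, theta, z)
        if direction == 0:  # radial face at r = e1[i_edge]
            return e1[i_edge] * w2[i2] * w3[i3]
        if direction == 1:  # theta face: dr x dz plane
            return w1[i2] * w3[i3]
        # axial face: area = int r dr dtheta
        r2h = 0.5 * (e1[1:] ** 2 - e1[:-1] ** 2)
        return r2h[i2] * w2[i3]

    # ------------------------------------------------------------------ faces
    def _build_faces(self):
        n1, n2, n3 = self.shape
        e1, e2, e3 = self.edges
        c1, c2, c3 = self._c
        idx = np.arange(self.n_cells).reshape(self.shape)

        own, nb, area, d_own, d_nb, fdir = [], [], [], [], [], []
        bown, barea, bdist, bdir, bloc = [], [], [], [], []
        bcent = []  # native coords of boundary-face centres

        def metric(direction, coord):
            # physical length per unit coordinate along `direction` at a cell
            if self.system == "cylindrical" and direction == 1:
                return coord  # arc length = r * dtheta
            return 1.0

        # --- direction 0 (x or r)
        I2, I3 = np.meshgrid(np.arange(n2), np.arange(n3), indexing="ij")
        for i in range(n1 - 1):
            o = idx[i, :, :].ravel()
            n = idx[i + 1, :, :].ravel()
            a = np.broadcast_to(
                self._face_area(0, i + 1, I2, I3), (n2, n3)
            ).ravel()
            own.append(o); nb.append(n); area.append(a)
            d_own.append(np.full(o.size, e1[i + 1] - c1[i]))
            d_nb.append(np.full(o.size, c1[i + 1] - e1[i + 1]))
            fdir.append(np.zeros(o.size, int))
        # boundaries in direction 0
        for side, i_edge, i_cell, loc in ((-1, 0, 0, LOC_D0_MIN), (1, n1, n1 - 1, LOC_D0_MAX)):
            a = np.broadcast_to(self._face_area(0, i_edge, I2, I3), (n2, n3)).ravel()
            if np.all(a <= 0):  # cylindrical axis: zero-area, no boundary
                continue
            o = idx[i_cell, :, :].ravel()
            bown.append(o); barea.append(a)
            bdist.append(np.full(o.size, abs(e1[i_edge] - c1[i_cell])))
            bdir.append(np.zeros(o.size, int))
            bloc.append(np.full(o.size, loc))
            cc = np.stack(
                np.broadcast_arrays(
                    np.full((n2, n3), e1[i_edge]), c2[:, None], c3[None, :]
                ),
                axis=-1,
            ).reshape(-1, 3)
            bcent.append(cc)

        # --- direction 1 (y or theta)
        I1, I3 = np.meshgrid(np.arange(n1), np.arange(n3), indexing="ij")
        rmet = c1 if (self.system == "cylindrical") else np.ones(n1)
        for j in range(n2 - 1):
            o = idx[:, j, :].ravel()
            n = idx[:, j + 1, :].ravel()
            a = np.broadcast_to(self._face_area(1, j + 1, I1, I3), (n1, n3)).ravel()
            own.append(o); nb.append(n); area.append(a)
            m = np.broadcast_to(rmet[:, None], (n1, n3)).ravel()
            d_own.append(m * (e2[j + 1] - c2[j]))
            d_nb.append(m * (c2[j + 1] - e2[j + 1]))
            fdir.append(np.ones(o.size, int))
        if self.periodic2:
            o = idx[:, n2 - 1, :].ravel()
            n = idx[:, 0, :].ravel()
            a = np.broadcast_to(self._face_area(1, 0, I1, I3), (n1, n3)).ravel()
            own.append(o); nb.append(n); area.append(a)
            m = np.broadcast_to(rmet[:, None], (n1, n3)).ravel()
            d_own.append(m * (e2[-1] - c2[-1]))
            d_nb.append(m * (c2[0] - e2[0]))
            fdir.append(np.ones(o.size, int))
        else:
            for side, j_edge, j_cell, loc in ((-1, 0, 0, LOC_D1_MIN), (1, n2, n2 - 1, LOC_D1_MAX)):
                o = idx[:, j_cell, :].ravel()
                a = np.broadcast_to(self._face_area(1, j_edge, I1, I3), (n1, n3)).ravel()
                m = np.broadcast_to(rmet[:, None], (n1, n3)).ravel()
                bown.append(o); barea.append(a)
                bdist.append(m * abs(e2[j_edge] - c2[j_cell]))
                bdir.append(np.ones(o.size, int))
                bloc.append(np.full(o.size, loc))
                cc = np.stack(
                    np.broadcast_arrays(
                        c1[:, None], np.full((n1, n3), e2[j_edge]), c3[None, :]
                    ),
                    axis=-1,
                ).reshape(-1, 3)
                bcent.append(cc)

        # --- direction 2 (z, axial)
        I1, I2 = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
        for k in range(n3 - 1):
            o = idx[:, :, k].ravel()
            n = idx[:, :, k + 1].ravel()
            a = np.broadcast_to(self._face_area(2, k + 1, I1, I2), (n1, n2)).ravel()
            own.append(o); nb.append(n); area.append(a)
            d_own.append(np.full(o.size, e3[k + 1] - c3[k]))
            d_nb.append(np.full(o.size, c3[k + 1] - e3[k + 1]))
            fdir.append(np.full(o.size, 2))
        for side, k_edge, k_cell, loc in ((-1, 0, 0, LOC_D2_MIN), (1, n3, n3 - 1, LOC_D2_MAX)):
            o = idx[:, :, k_cell].ravel()
            a = np.broadcast_to(self._face_area(2, k_edge, I1, I2), (n1, n2)).ravel()
            bown.append(o); barea.append(a)
            bdist.append(np.full(o.size, abs(e3[k_edge] - c3[k_cell])))
            bdir.append(np.full(o.size, 2))
            bloc.append(np.full(o.size, loc))
            cc = np.stack(
                np.broadcast_arrays(
                    c1[:, None], c2[None, :], np.full((n1, n2), e3[k_edge])
                ),
                axis=-1,
            ).reshape(-1, 3)
            bcent.append(cc)

        self.f_own = np.concatenate(own)
        self.f_nb = np.concatenate(nb)
        self.f_area = np.concatenate(area).astype(float)
        self.f_d_own = np.concatenate(d_own).astype(float)
        self.f_d_nb = np.concatenate(d_nb).astype(float)
        self.f_dir = np.concatenate(fdir)
        self.n_int = self.f_own.size

        self.b_own = np.concatenate(bown)
        self.b_area = np.concatenate(barea).astype(float)
        self.b_dist = np.concatenate(bdist).astype(float)
        self.b_dir = np.concatenate(bdir)
        self.b_loc = np.concatenate(bloc)
        self.b_center_native = np.concatenate(bcent, axis=0)
        self.n_bnd = self.b_own.size

    def _build_cell_face_map(self):
        """For each cell and direction, the (global) ids of the minus- and
        plus-side faces, used to reconstruct cell-centred velocities.
        Global ids: internal faces 0..n_int-1, then boundary faces.
        -1 where no face exists (cylindrical axis)."""
        n1, n2, n3 = self.shape
        idx = np.arange(self.n_cells).reshape(self.shape)
        fm = np.full((self.n_cells, 3), -1, dtype=int)
        fp = np.full((self.n_cells, 3), -1, dtype=int)

        # reproduce the construction-order offsets
        off = 0
        # dir0 internal: (n1-1) slabs of n2*n3
        for i in range(n1 - 1):
            ids = off + np.arange(n2 * n3)
            fp[idx[i, :, :].ravel(), 0] = ids
            fm[idx[i + 1, :, :].ravel(), 0] = ids
            off += n2 * n3
        # dir1 internal: (n2-1) slabs of n1*n3 (+ wrap)
        for j in range(n2 - 1):
            ids = off + np.arange(n1 * n3)
            fp[idx[:, j, :].ravel(), 1] = ids
            fm[idx[:, j + 1, :].ravel(), 1] = ids
            off += n1 * n3
        if self.periodic2:
            ids = off + np.arange(n1 * n3)
            fp[idx[:, n2 - 1, :].ravel(), 1] = ids
            fm[idx[:, 0, :].ravel(), 1] = ids
            off += n1 * n3
        # dir2 internal
        for k in range(n3 - 1):
            ids = off + np.arange(n1 * n2)
            fp[idx[:, :, k].ravel(), 2] = ids
            fm[idx[:, :, k + 1].ravel(), 2] = ids
            off += n1 * n2
        assert off == self.n_int

        # boundary faces, in construction order
        minus_loc = {LOC_D0_MIN: 0, LOC_D1_MIN: 1, LOC_D2_MIN: 2}
        plus_loc = {LOC_D0_MAX: 0, LOC_D1_MAX: 1, LOC_D2_MAX: 2}
        for b in range(self.n_bnd):
            gid = self.n_int + b
            loc = self.b_loc[b]
            c = self.b_own[b]
            if loc in minus_loc:
                fm[c, minus_loc[loc]] = gid
            else:
                fp[c, plus_loc[loc]] = gid
        self.cell_face_minus = fm
        self.cell_face_plus = fp

    # ------------------------------------------------------------------ utilities
    def transmissibility(self, lam):
        """Two-point-flux transmissibilities for a per-cell, per-direction
        mobility field ``lam`` (shape (n_cells, 3)); harmonic averaging.

        Returns (T_int, T_bnd) where T_bnd is the half-cell coefficient
        used for Dirichlet boundary faces.  Zero mobility gives zero
        transmissibility (blocked direction), never a division error.
        """
        lam = np.asarray(lam, float)
        lo = lam[self.f_own, self.f_dir]
        ln = lam[self.f_nb, self.f_dir]
        with np.errstate(divide="ignore", invalid="ignore"):
            denom = np.where(lo > 0, self.f_d_own / np.where(lo > 0, lo, 1.0), np.inf) + \
                np.where(ln > 0, self.f_d_nb / np.where(ln > 0, ln, 1.0), np.inf)
            T_int = np.where(np.isfinite(denom), self.f_area / denom, 0.0)
            lb = lam[self.b_own, self.b_dir]
            T_bnd = np.where(lb > 0, lb * self.b_area / self.b_dist, 0.0)
        return T_int, T_bnd

    def cell_velocities(self, F_int, F_bnd):
        """Cell-centred superficial velocity components from face fluxes.

        ``F_int`` is positive owner -> neighbour (i.e. along the +direction);
        ``F_bnd`` is positive outward.  Components are native (x,y,z) or
        (r,theta,z)."""
        nf = self.n_int + self.n_bnd
        flux = np.concatenate([F_int, F_bnd])
        farea = np.concatenate([self.f_area, self.b_area])
        # boundary flux sign: outward -> along +dir on a plus-face, along -dir on minus
        sign = np.ones(nf)
        minus = np.isin(self.b_loc, (LOC_D0_MIN, LOC_D1_MIN, LOC_D2_MIN))
        sign[self.n_int:][minus] = -1.0
        u = np.zeros((self.n_cells, 3))
        for d in range(3):
            fm = self.cell_face_minus[:, d]
            fp = self.cell_face_plus[:, d]
            fs = np.zeros(self.n_cells)
            asum = np.zeros(self.n_cells)
            ok = fm >= 0
            fs[ok] += sign[fm[ok]] * flux[fm[ok]]
            asum[ok] += farea[fm[ok]]
            ok = fp >= 0
            fs[ok] += sign[fp[ok]] * flux[fp[ok]]
            asum[ok] += farea[fp[ok]]
            with np.errstate(divide="ignore", invalid="ignore"):
                u[:, d] = np.where(asum > 0, fs / asum, 0.0)
        return u

    # ------------------------------------------------------------------ patches
    def assign_patch(self, name: str, face_ids: np.ndarray):
        face_ids = np.unique(np.asarray(face_ids, int))
        if face_ids.size == 0:
            raise MeshError(f"patch {name!r} selects no boundary faces")
        self.patches[name] = face_ids

    def patch_area(self, name: str) -> float:
        return float(self.b_area[self.patches[name]].sum())

    def block_internal(self, side: str, mask: np.ndarray):
        """Mark internal faces as impermeable walls for one side only."""
        mask = np.asarray(mask, bool)
        if mask.shape != (self.n_int,):
            raise MeshError("block mask must cover internal faces")
        base = self.face_blocks.get(side, np.zeros(self.n_int, bool))
        self.face_blocks[side] = base | mask

    def blocked(self, side: str) -> np.ndarray:
        return self.face_blocks.get(side, np.zeros(self.n_int, bool))

    # total volume check used by tests and build_mesh
    def total_volume(self) -> float:
        return float(self.vol.sum())
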