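"""Static lung-tumor phantom geometry and material/path queries.

Coordinate frame: right-handed, ``z`` along the beam, ``x`` along the motion
direction, origin at the isocenter.  All lengths are millimetres.  The whole
phantom can be rigidly displaced along ``x`` by a motion offset; every query
takes the offset explicitly so callers never mutate geometry state.

The phantom is a PMMA-walled cube ("aquarium") filled with low-density foam,
with a PMMA cylinder whose spherical proximal end is centred on the isocenter
at zero offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Material",
    "AIR",
    "PMMA",
    "FOAM",
    "WATER",
    "PhantomGeometry",
]


@dataclass(frozen=True)
class Material:
    """A homogeneous material.

    Parameters
    ----------
    name : str
        Label used in path segments and reports.
    density : float
        Mass density in g/cm^3.
    wer : float
        Water-equivalent ratio (geometric mm -> water-equivalent mm).
    x0_mm : float
        Radiation length in mm (used for multiple-Coulomb-scattering).
    """

    name: str
    density: float
    wer: float
    x0_mm: float

    def __post_init__(self) -> None:
        if self.density < 0 or self.wer < 0 or self.x0_mm <= 0:
            raise ValueError(f"unphysical material: {self}")


# Radiation lengths from mass radiation lengths (PMMA 40.55 g/cm^2,
# polystyrene foam 43.8 g/cm^2, air 36.62 g/cm^2) divided by density.
AIR = Material("air", 0.0012, 0.0, 3.04e5)
PMMA = Material("pmma", 1.17, 1.16, 346.6)
FOAM = Material("foam", 0.23, 0.23, 1904.0)
WATER = Material("water", 1.0, 1.0, 360.8)

_EPS = 1e-12


@dataclass(frozen=True)
class PhantomGeometry:
    """Aquarium + foam + PMMA insert, displaceable along ``x``.

    The insert is a cylinder of ``cylinder_diameter`` aligned with the beam
    axis whose spherical (hemispherical) end faces upstream; the sphere
    centre sits at ``sphere_center`` (the isocenter at zero offset) and the
    cylinder body extends ``cylinder_length`` downstream of it.

    Wall thicknesses are derived per axis from the outer cube edge and the
    foam block dimensions: (outer - foam)/2 on each side.
    """

    aquarium_outer: float = 260.0
    foam_dims: tuple[float, float, float] = (240.0, 250.0, 250.0)
    cylinder_diameter: float = 50.0
    cylinder_length: float = 100.0
    sphere_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    wall_material: Material = PMMA
    foam_material: Material = FOAM
    insert_material: Material = PMMA
    outside_material: Material = AIR

    def __post_init__(self) -> None:
        for d in self.foam_dims:
            if d > self.aquarium_outer:
                raise ValueError("foam does not fit inside the aquarium")
        if self.cylinder_diameter <= 0 or self.cylinder_length < 0:
            raise ValueError("invalid insert dimensions")
        r = self.sphere_radius
        cx, cy, cz = self.sphere_center
        if (abs(cx) + r > self.foam_dims[0] / 2.0
                or abs(cy) + r > self.foam_dims[1] / 2.0
                or cz + self.cylinder_length > self.foam_dims[2] / 2.0
                or cz - r < -self.foam_dims[2] / 2.0):
            raise ValueError("insert does not fit inside the foam block")

    # -- derived extents ---------------------------------------------------

    @property
    def sphere_radius(self) -> float:
        return self.cylinder_diameter / 2.0

    @property
    def outer_half(self) -> float:
        return self.aquarium_outer / 2.0

    @property
    def foam_half(self) -> tuple[float, float, float]:
        return tuple(d / 2.0 for d in self.foam_dims)  # type: ignore[return-value]

    @property
    def wall_thickness(self) -> tuple[float, float, float]:
        return tuple((self.aquarium_outer - d) / 2.0 for d in self.foam_dims)  # type: ignore[return-value]

    @property
    def z_range(self) -> tuple[float, float]:
        """z extent of the aquarium (offset-independent; motion is along x)."""
        return (-self.outer_half, self.outer_half)

    def with_materials(self, **kw: Material) -> "PhantomGeometry":
        return replace(self, **kw)

    # -- point queries -----------------------------------------------------

    def _in_insert(self, x: float, y: float, z: float, offset: float) -> bool:
        cx, cy, cz = self.sphere_center
        dx, dy, dz = x - cx - offset, y - cy, z - cz
        r = self.sphere_radius
        if dz <= 0.0:
            return dx * dx + dy * dy + dz * dz <= r * r
        if dz <= self.cylinder_length:
            return dx * dx + dy * dy <= r * r
        return False

    def material_at(self, point, offset: float = 0.0) -> Material:
        """Material at ``point`` (mm) with the phantom displaced by ``offset``
        along x.  Points outside the aquarium return the outside material."""
        x, y, z = (float(v) for v in point)
        if not (np.isfinite(x) and np.isfinite(y) and np.isfinite(z)):
            raise ValueError("point must be finite")
        oh = self.outer_half
        xr = x - offset  # phantom frame
        if abs(xr) > oh or abs(y) > oh or abs(z) > oh:
            return self.outside_material
        fx, fy, fz = self.foam_half
        if abs(xr) > fx or abs(y) > fy or abs(z) > fz:
            return self.wall_material
        if self._in_insert(x, y, z, offset):
            return self.insert_material
        return self.foam_material

    # -- ray queries ---------------------------------------------------------

    def _box_chord(self, o: np.ndarray, d: np.ndarray, half: np.ndarray,
                   center: np.ndarray) -> tuple[float, float] | None:
        """Slab intersection of a ray (t >= 0 not enforced) with an AABB."""
        t0, t1 = -np.inf, np.inf
        for k in range(3):
            if abs(d[k]) < _EPS:
                if abs(o[k] - center[k]) > half[k]:
                    return None
                continue
            ta = (center[k] - half[k] - o[k]) / d[k]
            tb = (center[k] + half[k] - o[k]) / d[k]
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
        if t1 <= t0:
            return None
        return t0, t1

    def _quadratic_ts(self, a: float, b: float, c: float) -> list[float]:
        if abs(a) < _EPS:
            return [] if abs(b) < _EPS else [-c / b]
        disc = b * b - 4 * a * c
        if disc <= 0:
            return []
        s = np.sqrt(disc)
        return [(-b - s) / (2 * a), (-b + s) / (2 * a)]

    def path_segments(self, origin, direction, offset: float = 0.0,
                      ) -> list[tuple[Material, float]]:
        """Ordered (material, length mm) segments of a ray inside the aquarium
        bounding box.  Segment lengths sum to the in-box chord length."""
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        nd = np.linalg.norm(d)
        if nd == 0:
            raise ValueError("direction must be non-zero")
        d = d / nd

        oh = self.outer_half
        center = np.array([offset, 0.0, 0.0])
        chord = self._box_chord(o, d, np.array([oh] * 3), center)
        if chord is None:
            return []
        t_in, t_out = chord

        ts = {t_in, t_out}
        # inner (foam) box faces
        fh = np.asarray(self.foam_half)
        inner = self._box_chord(o, d, fh, center)
        if inner is not None:
            ts.update(inner)
        # per-axis plane crossings of the foam box (edges where material can
        # change even if the full-slab chord already covers them)
        for k in range(3):
            if abs(d[k]) > _EPS:
                ck = center[k]
                ts.add((ck - fh[k] - o[k]) / d[k])
                ts.add((ck + fh[k] - o[k]) / d[k])
        # sphere
        cx, cy, cz = self.sphere_center
        sc = np.array([cx + offset, cy, cz])
        w = o - sc
        ts.update(self._quadratic_ts(1.0, 2 * float(w @ d),
                                     float(w @ w) - self.sphere_radius ** 2))
        # infinite cylinder (x, y only) + cap planes
        a = d[0] ** 2 + d[1] ** 2
        b = 2 * (w[0] * d[0] + w[1] * d[1])
        c = w[0] ** 2 + w[1] ** 2 - self.sphere_radius ** 2
        ts.update(self._quadratic_ts(a, b, c))
        if abs(d[2]) > _EPS:
            ts.add((cz - o[2]) / d[2])
            ts.add((cz + self.cylinder_length - o[2]) / d[2])

        edges = sorted(t for t in ts if t_in - _EPS <= t <= t_out + _EPS)
        segs: list[tuple[Material, float]] = []
        for ta, tb in zip(edges[:-1], edges[1:]):
            if tb - ta <= _EPS:
                continue
            mid = o + d * (0.5 * (ta + tb))
            m = self.material_at(mid, offset)
            length = tb - ta
            if segs and segs[-1][0] is m:
                segs[-1] = (m, segs[-1][1] + length)
            else:
                segs.append((m, length))
        return segs

    def wepl_to_depth(self, origin, direction, stop_z: float,
                      offset: float = 0.0) -> float:
        """Water-equivalent path length accumulated up to plane z = stop_z.

        Sum over path segments of length x WER, truncating the walk at the
        ray point whose z coordinate equals ``stop_z``.  Monotonically
        non-decreasing in ``stop_z`` for forward (dz > 0) rays.
        """
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        segs = self.path_segments(o, d, offset)
        if not segs:
            return 0.0
        chord = self._box_chord(o, d, np.array([self.outer_half] * 3),
                                np.array([offset, 0.0, 0.0]))
        assert chord is not None
        t = chord[0]
        if abs(d[2]) < _EPS:
            t_stop = np.inf
        else:
            t_stop = (stop_z - o[2]) / d[2]
        wepl = 0.0
        for mat, length in segs:
            if t >= t_stop:
                break
            use = min(length, t_stop - t)
            wepl += mat.wer * use
            t += length
        return wepl

    def depth_for_wepl(self, origin, direction, wepl: float,
                       offset: float = 0.0) -> float:
        """Inverse of :meth:`wepl_to_depth`: the z coordinate at which the
        accumulated WEPL first reaches ``wepl``.  Returns +inf if the ray
        exits the aquarium before accumulating that much."""
        o = np.asarray(origin, dtype=float)
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        if d[2] <= 0:
            raise ValueError("depth_for_wepl requires a forward (dz > 0) ray")
        segs = self.path_segments(o, d, offset)
        if not segs:
            return np.inf
        chord = self._box_chord(o, d, np.array([self.outer_half] * 3),
                                np.array([offset, 0.0, 0.0]))
        assert chord is not None
        t = chord[0]
        acc = 0.0
        for mat, length in segs:
            step = mat.wer * length
            if acc + step >= wepl and mat.wer > 0:
                t_hit = t + (wepl - acc) / mat.wer
                return float(o[2] + d[2] * t_hit)
            acc += step
            t += length
        return np.inf


# ---------------------------------------------------------------------------
# Vectorised near-axial tracing (fast path used by the forward simulator).
# ---------------------------------------------------------------------------

@dataclass
class AxialTrace:
    """Piecewise-constant material structure of N near-axial rays.

    ``z_edges`` has shape (N, 8): z positions of the material boundaries
    (clipped so empty segments have zero extent).  ``wer`` / ``density`` /
    ``inv_x0`` have shape (N, 7): per-segment material properties in order
    front wall, foam, insert(a), foam gap, insert(b), foam, back wall.
    """

    z_edges: np.ndarray
    wer: np.ndarray
    density: np.ndarray
    inv_x0: np.ndarray
    ds_dz: np.ndarray  # path-length factor sqrt(1 + ax^2 + ay^2)


def trace_axial(geom: PhantomGeometry, x0, y0, ax, ay, z0: float,
                offsets) -> AxialTrace:
    """Trace rays x(z) = x0 + ax (z - z0), y(z) = y0 + ay (z - z0) through the
    phantom, parameterised by z.  Valid for near-axial rays that enter and
    exit through the front/back faces (|lateral| within the foam box at the
    walls); lateral wall exits are not modelled here (use ``path_segments``).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    n = x0.shape[0]
    y0 = np.broadcast_to(np.asarray(y0, dtype=float), (n,)).copy()
    ax = np.broadcast_to(np.asarray(ax, dtype=float), (n,)).copy()
    ay = np.broadcast_to(np.asarray(ay, dtype=float), (n,)).copy()
    off = np.broadcast_to(np.asarray(offsets, dtype=float), (n,)).copy()

    oh = geom.outer_half
    fz = geom.foam_half[2]
    cx, cy, cz = geom.sphere_center
    r = geom.sphere_radius
    zc0, zc1 = cz, cz + geom.cylinder_length

    # lateral coordinates relative to the (displaced) insert axis at z
    # u(z) = x0 + ax (z - z0) - cx - off ; v(z) = y0 + ay (z - z0) - cy
    # sphere: u^2 + v^2 + (z - cz)^2 = r^2 -> quadratic in z
    u0 = x0 + ax * (cz - z0) - cx - off  # value at z = cz
    v0 = y0 + ay * (cz - z0) - cy

    def interval(a, b, c):
        disc = b * b - 4.0 * a * c
        ok = disc > 0
        s = np.sqrt(np.where(ok, disc, 0.0))
        z1 = np.where(ok, (-b - s) / (2 * a) + cz, np.inf)
        z2 = np.where(ok, (-b + s) / (2 * a) + cz, np.inf)
        return z1, z2

    # sphere quadratic in w = z - cz
    a_s = ax * ax + ay * ay + 1.0
    b_s = 2.0 * (u0 * ax + v0 * ay)
    c_s = u0 * u0 + v0 * v0 - r * r
    s1, s2 = interval(a_s, b_s, c_s)
    s1c = np.clip(s1, -np.inf, zc0)
    s2c = np.clip(s2, -np.inf, zc0)
    sph_ok = np.isfinite(s1) & (s2c > s1c)
    s_lo = np.where(sph_ok, s1c, zc0)
    s_hi = np.where(sph_ok, s2c, zc0)

    # cylinder lateral quadratic in w = z - cz
    a_c = ax * ax + ay * ay
    b_c = 2.0 * (u0 * ax + v0 * ay)
    c_c = u0 * u0 + v0 * v0 - r * r
    # handle a_c == 0 (perfectly axial): inside iff c_c < 0
    axial = a_c < 1e-16
    with np.errstate(divide="ignore", invalid="ignore"):
        c1, c2 = interval(np.where(axial, 1.0, a_c), b_c, c_c)
    c1 = np.where(axial, np.where(c_c < 0, -np.inf, np.inf), c1)
    c2 = np.where(axial, np.where(c_c < 0, np.inf, np.inf), c2)
    c1c = np.clip(c1, zc0, zc1)
    c2c = np.clip(c2, zc0, zc1)
    cyl_ok = np.isfinite(c1) & (c2c > c1c)
    c_lo = np.where(cyl_ok, c1c, zc1)
    c_hi = np.where(cyl_ok, c2c, zc1)

    # assemble insert intervals [s_lo, s_hi] and [c_lo, c_hi]; they can only
    # touch at z = cz.  Normalise empties to zero-length at their clip point.
    p1a, p1b = s_lo, s_hi
    p2a, p2b = c_lo, c_hi

    z_edges = np.empty((n, 8))
    z_edges[:, 0] = -oh
    z_edges[:, 1] = -fz
    z_edges[:, 2] = np.clip(p1a, -fz, fz)
    z_edges[:, 3] = np.clip(p1b, -fz, fz)
    z_edges[:, 4] = np.clip(p2a, -fz, fz)
    z_edges[:, 5] = np.clip(p2b, -fz, fz)
    z_edges[:, 6] = fz
    z_edges[:, 7] = oh
    # enforce monotone edges
    np.maximum.accumulate(z_edges, axis=1, out=z_edges)

    wall, foam, ins = geom.wall_material, geom.foam_material, geom.insert_material
    mats = [wall, foam, ins, foam, ins, foam, wall]
    wer = np.tile(np.array([m.wer for m in mats]), (n, 1))
    density = np.tile(np.array([m.density for m in mats]), (n, 1))
    inv_x0 = np.tile(np.array([1.0 / m.x0_mm for m in mats]), (n, 1))
    ds_dz = np.sqrt(1.0 + ax * ax + ay * ay)
    return AxialTrace(z_edges, wer, density, inv_x0, ds_dz)
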