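"""Primary-track building, closest-approach vertexing and per-spot summaries.

Two primary-track variants exist: method "a" extrapolates a single line from
the MWPC-averaged beam centroid with slopes set by the scanner-magnet pivot
through the planned voxel; method "b" additionally randomises the origin with
the measured beam widths and blurs the slopes with the Highland
multiple-scattering of the upstream material layers.  With zero widths and
scattering disabled, method b degenerates bit-identically to method a.

A vertex is the midpoint of the closest-approach segment between the primary
line and a back-projected secondary track; per-spot vertex distributions are
summarised by coordinate means (x, y) and an empirical-quantile position (z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragsim import carbon_pbc, highland_sigma_path
from .phantom import PhantomGeometry
from .plan import BeamSpot, ScannerGeometry, spot_slopes
from .trackrec import SecondaryTrack

__all__ = [
    "PrimaryTrack",
    "Vertex",
    "VertexDistribution",
    "ComputedVertex",
    "QuantileConfig",
    "primary_track_a",
    "primary_track_b",
    "closest_approach",
    "closest_approach_many",
    "reconstruct_vertices",
    "computed_vertex_z",
    "computed_vertex",
    "computed_vertex_xy",
    "choose_q",
    "vertices_to_frame",
]

CARBON_CHARGE = 6.0


@dataclass(frozen=True)
class PrimaryTrack:
    """Extrapolated primary beam line x(z) = x0 + ax (z - z0)."""

    x0: float
    y0: float
    z0: float
    ax: float
    ay: float
    method: str = "a"
    spot_index: int = -1

    def point(self) -> np.ndarray:
        return np.array([self.x0, self.y0, self.z0])

    def direction(self) -> np.ndarray:
        d = np.array([self.ax, self.ay, 1.0])
        return d / np.linalg.norm(d)

    def at(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return np.stack([self.x0 + self.ax * (z - self.z0),
                         self.y0 + self.ay * (z - self.z0),
                         z], axis=-1)


@dataclass(frozen=True)
class Vertex:
    x: float
    y: float
    z: float
    dca: float
    spot_index: int
    arm: int
    method: str


@dataclass
class VertexDistribution:
    """All reconstructed vertices of one beam spot."""

    spot_index: int
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    dca: np.ndarray
    arm: np.ndarray
    method: str = "a"

    @property
    def count(self) -> int:
        return int(self.z.size)


@dataclass(frozen=True)
class ComputedVertex:
    """Per-spot summary position: means in x/y, quantile in z."""

    spot_index: int
    v_x: float
    v_y: float
    v_z: float
    n_vertices: int
    valid: bool


@dataclass(frozen=True)
class QuantileConfig:
    q: float = 0.9
    grid: tuple[float, ...] = tuple(np.round(np.arange(0.50, 1.0001, 0.05), 2))
    min_vertices: int = 50

    def __post_init__(self) -> None:
        if not (0.5 <= self.q <= 1.0):
            raise ValueError("q must be in [0.5, 1.0]")
        if any(not (0.5 <= g <= 1.0) for g in self.grid):
            raise ValueError("grid values must be in [0.5, 1.0]")


# ---------------------------------------------------------------------------
# Primary tracks
# ---------------------------------------------------------------------------

_RECORD_FIELDS = ("x_i", "y_i", "sigma_x_i", "sigma_y_i", "z_i")


def _check_record(record) -> None:
    for f in _RECORD_FIELDS:
        v = record.get(f) if isinstance(record, dict) else getattr(record, f,
                                                                   None)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(f"spot record missing MWPC field {f!r}")


def _field(record, name: str) -> float:
    return float(record[name] if isinstance(record, dict)
                 else getattr(record, name))


def primary_track_a(record, spot: BeamSpot, scanner: ScannerGeometry,
                    ) -> PrimaryTrack:
    """Method a: origin at the MWPC-averaged centroid, slopes through the
    planned voxel from the scanner-magnet pivots."""
    _check_record(record)
    ax, ay = spot_slopes(spot, scanner)
    return PrimaryTrack(_field(record, "x_i"), _field(record, "y_i"),
                        _field(record, "z_i"), ax, ay, "a", spot.spot_index)


def upstream_scattering_sigma(geom: PhantomGeometry, spot: BeamSpot,
                              scanner: ScannerGeometry,
                              offset: float = 0.0) -> float:
    """Highland angle of the primary carbon ion over the phantom layers
    upstream of the planned voxel depth."""
    ax, ay = spot_slopes(spot, scanner)
    origin = np.array([spot.x_v + ax * (-geom.outer_half - 50 - spot.z_v),
                       spot.y_v + ay * (-geom.outer_half - 50 - spot.z_v),
                       -geom.outer_half - 50.0])
    direction = np.array([ax, ay, 1.0])
    segs = geom.path_segments(origin, direction, offset)
    # truncate at the voxel depth
    xs = []
    z = -geom.outer_half
    dz_per_len = 1.0 / np.sqrt(1 + ax * ax + ay * ay)
    for mat, length in segs:
        z_end = z + length * dz_per_len
        use = length
        if z_end > spot.z_v:
            use = max(0.0, (spot.z_v - z) / dz_per_len)
        if use > 0 and mat.x0_mm > 0:
            xs.append(use / mat.x0_mm)
        z = z_end
        if z >= spot.z_v:
            break
    pbc = carbon_pbc(spot.energy)
    return highland_sigma_path(pbc, CARBON_CHARGE, xs)


def primary_track_b(record, spot: BeamSpot, scanner: ScannerGeometry,
                    rng: np.random.Generator,
                    geom: PhantomGeometry | None = None,
                    scattering: bool = True,
                    offset: float = 0.0) -> PrimaryTrack:
    """Method b: randomised origin (measured beam widths) and slopes blurred
    by the Highland scattering of the upstream layer materials."""
    base = primary_track_a(record, spot, scanner)
    sx = _field(record, "sigma_x_i")
    sy = _field(record, "sigma_y_i")
    x0 = base.x0 + rng.normal(0.0, 1.0) * sx
    y0 = base.y0 + rng.normal(0.0, 1.0) * sy
    ax, ay = base.ax, base.ay
    if scattering:
        if geom is None:
            raise ValueError("method b with scattering needs the phantom")
        theta = upstream_scattering_sigma(geom, spot, scanner, offset)
        ax = ax + rng.normal(0.0, 1.0) * theta
        ay = ay + rng.normal(0.0, 1.0) * theta
    return PrimaryTrack(x0, y0, base.z0, ax, ay, "b", spot.spot_index)


# ---------------------------------------------------------------------------
# Closest approach of two lines
# ---------------------------------------------------------------------------

def closest_approach(p1, d1, p2, d2) -> tuple[np.ndarray, float]:
    """Midpoint and distance of closest approach of two 3D lines.

    For parallel lines the distance is the perpendicular offset and the
    midpoint is taken at the projection of the first line's reference point
    onto the second line (documented convention).
    """
    mid, dca = closest_approach_many(np.asarray(p1, float),
                                     np.asarray(d1, float),
                                     np.atleast_2d(np.asarray(p2, float)),
                                     np.atleast_2d(np.asarray(d2, float)))
    return mid[0], float(dca[0])


def closest_approach_many(p1: np.ndarray, d1: np.ndarray, p2: np.ndarray,
                          d2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised closest approach of one line against many lines."""
    d1 = d1 / np.linalg.norm(d1)
    d2 = d2 / np.linalg.norm(d2, axis=1, keepdims=True)
    w0 = p1[None, :] - p2
    b = d2 @ d1
    d = w0 @ d1
    e = np.sum(w0 * d2, axis=1)
    den = 1.0 - b * b
    par = den < 1e-12
    den_safe = np.where(par, 1.0, den)
    s = np.where(par, 0.0, (b * e - d) / den_safe)
    t = np.where(par, e, (e - b * d) / den_safe)
    q1 = p1[None, :] + s[:, None] * d1[None, :]
    q2 = p2 + t[:, None] * d2
    mid = 0.5 * (q1 + q2)
    dca = np.linalg.norm(q1 - q2, axis=1)
    return mid, dca


# ---------------------------------------------------------------------------
# Vertex distributions and computed vertices
# ---------------------------------------------------------------------------

def reconstruct_vertices(primary: PrimaryTrack,
                         secondaries: list[SecondaryTrack],
                         geom: PhantomGeometry,
                         dca_cut: float = 5.0) -> VertexDistribution:
    """One vertex per (primary, secondary) pairing passing the dca cut and
    the aquarium-z filter."""
    if not secondaries:
        e = np.empty(0)
        return VertexDistribution(primary.spot_index, e, e, e, e,
                                  np.empty(0, dtype=int), primary.method)
    p2 = np.stack([t.point for t in secondaries])
    d2 = np.stack([t.direction for t in secondaries])
    arms = np.array([t.arm for t in secondaries], dtype=int)
    mid, dca = closest_approach_many(primary.point(), primary.direction(),
                                     p2, d2)
    z_lo, z_hi = geom.z_range
    keep = (dca <= dca_cut) & (mid[:, 2] >= z_lo) & (mid[:, 2] <= z_hi)
    return VertexDistribution(primary.spot_index, mid[keep, 0], mid[keep, 1],
                              mid[keep, 2], dca[keep], arms[keep],
                              primary.method)


def computed_vertex_z(z_samples, q: float) -> float:
    """Smallest sample z whose empirical cumulative fraction reaches q."""
    z = np.sort(np.asarray(z_samples, dtype=float))
    n = z.size
    if n == 0:
        raise ValueError("empty distribution")
    if not (0.0 < q <= 1.0):
        raise ValueError("q must be in (0, 1]")
    k = int(np.ceil(q * n)) - 1
    return float(z[min(max(k, 0), n - 1)])


def computed_vertex_xy(vdist: VertexDistribution) -> tuple[float, float]:
    """Arithmetic means of the member x and y positions."""
    if vdist.count == 0:
        raise ValueError("empty distribution")
    return float(vdist.x.mean()), float(vdist.y.mean())


def computed_vertex(vdist: VertexDistribution, q: float,
                    min_vertices: int = 50) -> ComputedVertex:
    n = vdist.count
    valid = n >= min_vertices
    if n == 0:
        return ComputedVertex(vdist.spot_index, np.nan, np.nan, np.nan, 0,
                              False)
    vx, vy = computed_vertex_xy(vdist)
    vz = computed_vertex_z(vdist.z, q)
    return ComputedVertex(vdist.spot_index, vx, vy, vz, n, valid)


def choose_q(vdists_in: dict[int, np.ndarray],
             vdists_out: dict[int, np.ndarray],
             grid=None, min_vertices: int = 50) -> float:
    """Quantile maximising the mean absolute per-spot difference of the
    computed vertex z between two static cases; ties break toward smaller q.

    ``vdists_in``/``vdists_out`` map spot index to that spot's vertex z
    samples; only spots valid (>= min_vertices) in both cases contribute.
    """
    if grid is None:
        grid = QuantileConfig().grid
    spots = [s for s in vdists_in
             if s in vdists_out
             and len(vdists_in[s]) >= min_vertices
             and len(vdists_out[s]) >= min_vertices]
    if not spots:
        raise ValueError("no spots valid in both static cases")
    best_q, best_val = None, -np.inf
    for q in sorted(grid):
        diffs = [abs(computed_vertex_z(vdists_in[s], q)
                     - computed_vertex_z(vdists_out[s], q)) for s in spots]
        val = float(np.mean(diffs))
        if val > best_val + 1e-12:
            best_q, best_val = float(q), val
    assert best_q is not None
    return best_q


def vertices_to_frame(vdists: list[VertexDistribution]) -> pd.DataFrame:
    """Tabular view: ``spot,arm,method,x_mm,y_mm,z_mm,dca_mm``."""
    frames = []
    for vd in vdists:
        frames.append(pd.DataFrame({
            "spot": vd.spot_index, "arm": vd.arm, "method": vd.method,
            "x_mm": vd.x, "y_mm": vd.y, "z_mm": vd.z, "dca_mm": vd.dca,
        }))
    cols = ["spot", "arm", "method", "x_mm", "y_mm", "z_mm", "dca_mm"]
    if not frames:
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)[cols]
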