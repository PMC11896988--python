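"""Seeded forward simulator of spot-by-spot carbon-ion delivery.

Each primary ion is transported along its (near-axial) beam line through the
possibly displaced phantom; nuclear interaction points are sampled by
exponential thinning with a water mean free path scaled by local density;
light fragments (modelled as protons) are emitted forward-peaked, scattered
per traversed material layer via the Highland approximation, and recorded as
per-sensor cluster observations on four 3-sensor CMOS tracker arms.

All randomness flows through explicit ``numpy.random.Generator`` objects;
the per-spot generators are keyed by (run seed, spot index) so a run is
bit-reproducible regardless of execution order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import motion as motion_mod
from .motion import LujanParams
from .phantom import PhantomGeometry, trace_axial
from .plan import (BeamSpot, FpgaLog, RangeModel, ScannerGeometry,
                   make_fpga_log, make_spot_log, plan_to_frame,
                   read_fpga_log, read_spot_log, spot_slopes,
                   write_fpga_log, write_spot_log)

__all__ = [
    "TrackerGeometry",
    "SimConfig",
    "highland_sigma",
    "highland_sigma_path",
    "proton_pbc",
    "carbon_pbc",
    "proton_energy_from_range",
    "sample_fragmentation_vertices",
    "emit_fragments",
    "propagate_to_trackers",
    "arm_acceptance",
    "simulate_spot",
    "simulate_delivery",
    "simulate_alignment_run",
    "RunBundle",
    "write_run",
    "read_run",
    "CLUSTER_COLS",
]

_M_PROTON = 938.272  # MeV
_M_NUCLEON = 931.494  # MeV per u

CLUSTER_COLS = ["arm", "sensor", "frame", "u_mm", "v_mm", "truth_vertex"]


# ---------------------------------------------------------------------------
# Multiple Coulomb scattering (Highland) and simple kinematics
# ---------------------------------------------------------------------------

def highland_sigma(pbc_mev, charge, x_over_x0):
    """Highland RMS scattering angle (rad).

    theta0 = 13.6 MeV / (p beta c) * z * sqrt(x/X0) * [1 + 0.038 ln(x/X0)].
    x/X0 = 0 returns 0 (continuity); the bracket is clamped at 0 so the
    result never goes negative for extremely thin layers.
    """
    x = np.asarray(x_over_x0, dtype=float)
    if np.any(x < 0):
        raise ValueError("x_over_x0 must be >= 0")
    pbc = np.asarray(pbc_mev, dtype=float)
    if np.any(pbc <= 0):
        raise ValueError("p*beta*c must be > 0")
    with np.errstate(divide="ignore"):
        bracket = np.where(x > 0, 1.0 + 0.038 * np.log(np.where(x > 0, x, 1.0)),
                           0.0)
    theta = 13.6 / pbc * abs(charge) * np.sqrt(x) * np.clip(bracket, 0.0, None)
    return float(theta) if theta.ndim == 0 else theta


def highland_sigma_path(pbc_mev: float, charge: float, x_over_x0_list):
    """Highland angle over consecutive layers, summed in quadrature.

    The logarithmic correction uses the *total* x/X0 of the path, which makes
    the result exactly invariant under splitting a layer into sub-layers
    (per-layer logs would not be quadrature-additive).
    """
    xs = np.asarray(x_over_x0_list, dtype=float)
    if np.any(xs < 0):
        raise ValueError("layer thicknesses must be >= 0")
    total = float(xs.sum())
    if total == 0.0:
        return 0.0
    bracket = max(0.0, 1.0 + 0.038 * np.log(total))
    var = np.sum((13.6 / pbc_mev * abs(charge)) ** 2 * xs * bracket ** 2)
    return float(np.sqrt(var))


def proton_pbc(kinetic_mev):
    """p*beta*c (MeV) of a proton with the given kinetic energy."""
    t = np.asarray(kinetic_mev, dtype=float)
    pc2 = t * t + 2.0 * t * _M_PROTON
    out = pc2 / (t + _M_PROTON)
    return float(out) if out.ndim == 0 else out


def carbon_pbc(kinetic_mev_per_u, a: int = 12):
    """p*beta*c (MeV) of a carbon ion at the given MeV/u."""
    tu = np.asarray(kinetic_mev_per_u, dtype=float)
    pc = a * np.sqrt(tu * tu + 2.0 * tu * _M_NUCLEON)
    e = a * (tu + _M_NUCLEON)
    out = pc * pc / e
    return float(out) if out.ndim == 0 else out


def proton_energy_from_range(range_mm_water):
    """Kinetic energy (MeV) of a proton with the given water range (mm),
    via the Bragg-Kleeman style power law R[mm] = (E[MeV]/9.3)^1.8."""
    r = np.clip(np.asarray(range_mm_water, dtype=float), 1e-6, None)
    out = 9.3 * r ** (1.0 / 1.8)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Tracker geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackerGeometry:
    """Four 3-sensor tracker arms downstream of the phantom.

    Arms lie in the x-z plane at the given angles from the beam axis; each
    arm's sensors are coplanar, normal to the arm axis, the first at
    ``radial_mm`` from the isocenter and the rest spaced ``sensor_spacing_mm``
    further out.
    """

    angles_deg: tuple[float, ...] = (-21.0, -10.5, 10.5, 21.0)
    radial_mm: float = 248.0
    sensors_per_arm: int = 3
    sensor_spacing_mm: float = 20.0
    pixel_pitch_mm: float = 0.0207
    n_rows: int = 928
    n_cols: int = 960
    frame_time_s: float = 186.5e-6

    def __post_init__(self) -> None:
        if self.sensor_spacing_mm <= 0:
            raise ValueError("sensor spacing must be > 0")

    @property
    def n_arms(self) -> int:
        return len(self.angles_deg)

    @property
    def half_u(self) -> float:
        return self.n_rows * self.pixel_pitch_mm / 2.0

    @property
    def half_v(self) -> float:
        return self.n_cols * self.pixel_pitch_mm / 2.0

    def basis(self, arm: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(u_hat, v_hat, w_hat): in-plane axes and outward arm axis."""
        a = np.deg2rad(self.angles_deg[arm])
        w = np.array([np.sin(a), 0.0, np.cos(a)])
        u = np.array([np.cos(a), 0.0, -np.sin(a)])
        v = np.array([0.0, 1.0, 0.0])
        return u, v, w

    def sensor_distance(self, sensor: int) -> float:
        return self.radial_mm + sensor * self.sensor_spacing_mm

    def sensor_center(self, arm: int, sensor: int) -> np.ndarray:
        _, _, w = self.basis(arm)
        return w * self.sensor_distance(sensor)

    def to_global(self, arm: int, sensor: int, u, v) -> np.ndarray:
        """Global 3D point(s) of in-plane coordinates (u, v) on a sensor."""
        uh, vh, w = self.basis(arm)
        c = self.sensor_center(arm, sensor)
        u = np.asarray(u, dtype=float)[..., None]
        v = np.asarray(v, dtype=float)[..., None]
        return c + u * uh + v * vh


def arm_acceptance(tracker: TrackerGeometry, points: np.ndarray,
                   dirs: np.ndarray, margin: float = 0.0,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Geometric acceptance of straight rays by the tracker arms.

    Returns (arm_id, us, vs): arm_id is -1 for undetected rays, otherwise the
    first arm whose three sensors are all crossed inside the (margin-grown)
    active area; ``us``/``vs`` are (m, sensors) in-plane crossing coordinates.
    """
    points = np.atleast_2d(points)
    dirs = np.atleast_2d(dirs)
    m = points.shape[0]
    arm_id = np.full(m, -1, dtype=int)
    ns = tracker.sensors_per_arm
    us = np.full((m, ns), np.nan)
    vs = np.full((m, ns), np.nan)
    hu = tracker.half_u + margin
    hv = tracker.half_v + margin
    for arm in range(tracker.n_arms):
        uh, vh, w = tracker.basis(arm)
        wp = points @ w
        wd = dirs @ w
        todo = arm_id < 0
        ok = todo & (wd > 1e-9)
        if not np.any(ok):
            continue
        u_arm = np.empty((m, ns))
        v_arm = np.empty((m, ns))
        inside = ok.copy()
        for k in range(ns):
            d_k = tracker.sensor_distance(k)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(ok, (d_k - wp) / wd, np.nan)
            q = points + t[:, None] * dirs
            u_arm[:, k] = q @ uh
            v_arm[:, k] = q @ vh
            inside &= (t > 0) & (np.abs(u_arm[:, k]) <= hu) \
                & (np.abs(v_arm[:, k]) <= hv)
        arm_id[inside] = arm
        us[inside] = u_arm[inside]
        vs[inside] = v_arm[inside]
    return arm_id, us, vs


# ---------------------------------------------------------------------------
# Simulator configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Tunable physics/detector parameters of the forward simulator."""

    lambda_w_mm: float = 260.0          # nuclear mean free path in water
    fragments_per_vertex: int = 3
    frag_range_multiplier: float = 2.5  # fragment water range vs residual ion range
    frag_angle_sigma: float = 0.080     # rad, Gaussian transverse-slope sigma
    cluster_sigma_mm: float = 0.010     # per-axis cluster position resolution
    beam_sigma_mm: float = 1.0          # per-ion lateral beam spread
    scattering: bool = True
    smearing: bool = True
    noise_cluster_rate: float = 0.0     # noise clusters per arm-sensor-frame
    prefilter_margin_mm: float | None = 10.0
    max_ions_per_spot: int | None = None

    def replace(self, **kw) -> "SimConfig":
        from dataclasses import replace as _r
        return _r(self, **kw)


# ---------------------------------------------------------------------------
# Core vectorised transport
# ---------------------------------------------------------------------------

def _interp_cum(z_edges, cum, slope, z):
    """Value of a piecewise-linear cumulative (edges, cum at edges, per-segment
    slope d/dz) at per-row positions z."""
    n, ne = z_edges.shape
    j = np.clip(np.sum(z_edges[:, :-1] <= z[:, None], axis=1) - 1, 0, ne - 2)
    rows = np.arange(n)
    return cum[rows, j] + slope[rows, j] * (z[rows] - z_edges[rows, j])


def _invert_cum(z_edges, cum, slope, target):
    """z at which a piecewise-linear cumulative reaches ``target``.
    Rows whose total is below target return +inf."""
    n, ne = z_edges.shape
    reach = cum[:, 1:] >= target[:, None]
    has = reach.any(axis=1)
    j = np.where(has, reach.argmax(axis=1), ne - 2)
    rows = np.arange(n)
    s = slope[rows, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        dz = np.where(s > 0, (target - cum[rows, j]) / s, np.inf)
    z = z_edges[rows, j] + dz
    return np.where(has, z, np.inf)


@dataclass
class IonTransport:
    """Per-ion transport results (arrays over simulated ions)."""

    x0: np.ndarray          # lateral intercepts at z = 0 (beam frame)
    y0: np.ndarray
    ax: float
    ay: float
    offsets: np.ndarray
    times: np.ndarray
    z_stop: np.ndarray      # ion stopping z (inf if shoot-through)
    has_vertex: np.ndarray  # bool
    z_vtx: np.ndarray
    x_vtx: np.ndarray
    y_vtx: np.ndarray
    wepl_vtx: np.ndarray    # WEPL accumulated at the vertex
    range_wepl: float       # ion water range


def _transport_ions(geom: PhantomGeometry, range_model: RangeModel,
                    spot: BeamSpot, scanner: ScannerGeometry,
                    times: np.ndarray, offsets: np.ndarray,
                    cfg: SimConfig, rng: np.random.Generator) -> IonTransport:
    n = times.shape[0]
    ax, ay = spot_slopes(spot, scanner)
    bx = rng.normal(0.0, cfg.beam_sigma_mm, n) if cfg.beam_sigma_mm > 0 \
        else np.zeros(n)
    by = rng.normal(0.0, cfg.beam_sigma_mm, n) if cfg.beam_sigma_mm > 0 \
        else np.zeros(n)
    x0 = spot.x_v - ax * spot.z_v + bx
    y0 = spot.y_v - ay * spot.z_v + by

    tr = trace_axial(geom, x0, y0, ax, ay, 0.0, offsets)
    dz = np.diff(tr.z_edges, axis=1)
    wepl_slope = tr.wer * tr.ds_dz[:, None]
    dens_slope = tr.density * tr.ds_dz[:, None]
    wepl_cum = np.concatenate([np.zeros((n, 1)),
                               np.cumsum(wepl_slope * dz, axis=1)], axis=1)
    dens_cum = np.concatenate([np.zeros((n, 1)),
                               np.cumsum(dens_slope * dz, axis=1)], axis=1)

    r_ion = float(range_model.energy_to_range(spot.energy))
    z_stop = _invert_cum(tr.z_edges, wepl_cum, wepl_slope,
                         np.full(n, r_ion))
    d_stop = _interp_cum(tr.z_edges, dens_cum, dens_slope,
                         np.minimum(z_stop, tr.z_edges[:, -1]))

    u_exp = rng.exponential(cfg.lambda_w_mm, n)
    has_vertex = u_exp < d_stop
    z_vtx = _invert_cum(tr.z_edges, dens_cum, dens_slope, u_exp)
    z_vtx = np.where(has_vertex, z_vtx, np.nan)
    x_vtx = x0 + ax * z_vtx
    y_vtx = y0 + ay * z_vtx
    wepl_vtx = np.where(
        has_vertex,
        _interp_cum(tr.z_edges, wepl_cum, wepl_slope,
                    np.where(has_vertex, z_vtx, tr.z_edges[:, 0])),
        np.nan)
    return IonTransport(x0, y0, ax, ay, offsets, times, z_stop, has_vertex,
                        z_vtx, x_vtx, y_vtx, wepl_vtx, r_ion)


def emit_fragments(vertex_xyz: np.ndarray, parent_slopes: tuple[float, float],
                   residual_range: np.ndarray, cfg: SimConfig,
                   rng: np.random.Generator,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Emit ``fragments_per_vertex`` fragments per vertex.

    Directions are the parent slopes plus Gaussian transverse-slope kicks of
    sigma ``frag_angle_sigma`` per axis (a forward-peaked, Rayleigh-polar
    model); fragment water range is ``frag_range_multiplier`` times the
    residual parent range.  Returns (vertex_id, sx, sy, frag_range) arrays.
    """
    nv = vertex_xyz.shape[0]
    k = cfg.fragments_per_vertex
    vid = np.repeat(np.arange(nv), k)
    ax, ay = parent_slopes
    sx = ax + rng.normal(0.0, cfg.frag_angle_sigma, nv * k)
    sy = ay + rng.normal(0.0, cfg.frag_angle_sigma, nv * k)
    frange = np.repeat(np.asarray(residual_range, dtype=float), k) \
        * cfg.frag_range_multiplier
    return vid, sx, sy, frange


def propagate_to_trackers(geom: PhantomGeometry, tracker: TrackerGeometry,
                          start_xyz: np.ndarray, sx: np.ndarray,
                          sy: np.ndarray, frag_range: np.ndarray,
                          offsets: np.ndarray, cfg: SimConfig,
                          rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                     np.ndarray]:
    """Transport fragments from their vertices to the tracker arms.

    Fragments travel straight within each traversed material segment; at
    every segment boundary a Highland angular kick for the material just
    crossed is applied (thin-lens convention).  A fragment is detected iff
    its water range exceeds the water-equivalent exit path and the final
    straight ray crosses all three sensors of one arm.

    Returns (detected_index, us, vs, arm_id): indices into the input arrays
    plus the smeared per-sensor in-plane coordinates and arm of the detected
    fragments.
    """
    ns = tracker.sensors_per_arm
    empty = (np.empty(0, dtype=int), np.empty((0, ns)), np.empty((0, ns)),
             np.empty(0, dtype=int))
    m = start_xyz.shape[0]
    if m == 0:
        return empty
    x_v, y_v, z_v = start_xyz[:, 0], start_xyz[:, 1], start_xyz[:, 2]

    keep = np.ones(m, dtype=bool)
    if cfg.prefilter_margin_mm is not None:
        dirs = np.stack([sx, sy, np.ones(m)], axis=1)
        aid, _, _ = arm_acceptance(tracker, start_xyz, dirs,
                                   margin=cfg.prefilter_margin_mm)
        keep = aid >= 0
    idx = np.nonzero(keep)[0]
    if idx.size == 0:
        return empty

    xk, yk, zk = x_v[idx], y_v[idx], z_v[idx]
    sxk, syk = sx[idx].copy(), sy[idx].copy()
    frk = frag_range[idx]
    offk = np.broadcast_to(np.asarray(offsets, dtype=float), (m,))[idx]

    # material structure of the straight exit line (re-intersection after the
    # small Highland kicks is neglected)
    x0f = xk - sxk * zk
    y0f = yk - syk * zk
    tr = trace_axial(geom, x0f, y0f, sxk, syk, 0.0, offk)
    edges = np.maximum(tr.z_edges, zk[:, None])

    pbc = proton_pbc(proton_energy_from_range(frk))
    wepl_acc = np.zeros(idx.size)
    stopped = np.zeros(idx.size, dtype=bool)
    x_cur, y_cur = xk.copy(), yk.copy()
    z_cur = edges[:, 0]
    for j in range(edges.shape[1] - 1):
        dzj = edges[:, j + 1] - edges[:, j]
        g = np.sqrt(1.0 + sxk * sxk + syk * syk)
        ds = dzj * g
        wepl_j = tr.wer[:, j] * ds
        stopped |= (wepl_acc + wepl_j) > frk
        wepl_acc += wepl_j
        x_cur += sxk * dzj
        y_cur += syk * dzj
        z_cur = edges[:, j + 1]
        if cfg.scattering:
            theta = highland_sigma(pbc, 1.0, ds * tr.inv_x0[:, j])
            live = theta > 0
            if np.any(live):
                sxk = sxk + np.where(live, rng.normal(0.0, 1.0, idx.size)
                                     * theta, 0.0)
                syk = syk + np.where(live, rng.normal(0.0, 1.0, idx.size)
                                     * theta, 0.0)

    alive = ~stopped
    pts = np.stack([x_cur, y_cur, z_cur], axis=1)
    dirs = np.stack([sxk, syk, np.ones(idx.size)], axis=1)
    aid, us, vs = arm_acceptance(tracker, pts, dirs, margin=0.0)
    det = alive & (aid >= 0)
    if cfg.smearing and cfg.cluster_sigma_mm > 0:
        us = us + rng.normal(0.0, cfg.cluster_sigma_mm, us.shape)
        vs = vs + rng.normal(0.0, cfg.cluster_sigma_mm, vs.shape)
    det_idx = idx[det]
    return det_idx, us[det], vs[det], aid[det]


# ---------------------------------------------------------------------------
# Public per-spot and per-run simulation
# ---------------------------------------------------------------------------

def sample_fragmentation_vertices(geom: PhantomGeometry,
                                  range_model: RangeModel, spot: BeamSpot,
                                  scanner: ScannerGeometry,
                                  offset: float = 0.0,
                                  n_ions: int | None = None,
                                  seed: int | None = 0,
                                  cfg: SimConfig = SimConfig(),
                                  ) -> pd.DataFrame:
    """Fragmentation vertices of a single spot at a fixed phantom offset."""
    n = n_ions if n_ions is not None else spot.n_planned
    rng = np.random.default_rng(seed)
    times = np.zeros(n)
    tr = _transport_ions(geom, range_model, spot, scanner, times,
                         np.full(n, float(offset)), cfg, rng)
    sel = tr.has_vertex
    return pd.DataFrame({
        "spot_index": spot.spot_index,
        "x_mm": tr.x_vtx[sel], "y_mm": tr.y_vtx[sel], "z_mm": tr.z_vtx[sel],
        "wepl_mm": tr.wepl_vtx[sel],
        "residual_range_mm": tr.range_wepl - tr.wepl_vtx[sel],
    })


def simulate_spot(geom: PhantomGeometry, tracker: TrackerGeometry,
                  scanner: ScannerGeometry, range_model: RangeModel,
                  spot: BeamSpot, t_start: float, t_end: float,
                  offset_fn, cfg: SimConfig, rng: np.random.Generator,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate one spot: returns (clusters, truth_vertices, truth_summary)."""
    n = spot.n_planned
    scale = 1.0
    if cfg.max_ions_per_spot is not None and n > cfg.max_ions_per_spot:
        scale = n / cfg.max_ions_per_spot
        n = cfg.max_ions_per_spot
    times = rng.uniform(t_start, t_end, n)
    offsets = np.broadcast_to(np.asarray(offset_fn(times), dtype=float), (n,))
    tr = _transport_ions(geom, range_model, spot, scanner, times, offsets, cfg,
                         rng)

    sel = np.nonzero(tr.has_vertex)[0]
    vtx_xyz = np.stack([tr.x_vtx[sel], tr.y_vtx[sel], tr.z_vtx[sel]], axis=1)
    vtx_t = tr.times[sel]
    vtx_off = tr.offsets[sel]
    residual = tr.range_wepl - tr.wepl_vtx[sel]

    vid, sx, sy, frange = emit_fragments(vtx_xyz, (tr.ax, tr.ay), residual,
                                         cfg, rng)
    det, us, vs, arms = propagate_to_trackers(
        geom, tracker, vtx_xyz[vid], sx, sy, frange, vtx_off[vid], cfg, rng)

    frames = np.floor(vtx_t[vid[det]] / tracker.frame_time_s).astype(np.int64)
    ns = tracker.sensors_per_arm
    nd = det.size
    clusters = pd.DataFrame({
        "arm": np.repeat(arms, ns),
        "sensor": np.tile(np.arange(ns), nd),
        "frame": np.repeat(frames, ns),
        "u_mm": us.reshape(-1),
        "v_mm": vs.reshape(-1),
        "truth_vertex": np.repeat(sel[vid[det]], ns),
    })

    if cfg.noise_cluster_rate > 0:
        f0 = int(np.floor(t_start / tracker.frame_time_s))
        f1 = int(np.floor(t_end / tracker.frame_time_s))
        n_slots = (f1 - f0 + 1) * tracker.n_arms * ns
        n_noise = rng.poisson(cfg.noise_cluster_rate * n_slots)
        if n_noise > 0:
            noise = pd.DataFrame({
                "arm": rng.integers(0, tracker.n_arms, n_noise),
                "sensor": rng.integers(0, ns, n_noise),
                "frame": rng.integers(f0, f1 + 1, n_noise),
                "u_mm": rng.uniform(-tracker.half_u, tracker.half_u, n_noise),
                "v_mm": rng.uniform(-tracker.half_v, tracker.half_v, n_noise),
                "truth_vertex": -1,
            })
            clusters = pd.concat([clusters, noise], ignore_index=True)

    truth_vertices = pd.DataFrame({
        "spot_index": spot.spot_index,
        "ion": sel,
        "x_mm": vtx_xyz[:, 0], "y_mm": vtx_xyz[:, 1], "z_mm": vtx_xyz[:, 2],
        "t_s": vtx_t,
        "offset_mm": vtx_off,
    })
    t_mid = 0.5 * (t_start + t_end)
    z_stop = tr.z_stop[np.isfinite(tr.z_stop)]
    summary = {
        "spot_index": spot.spot_index,
        "n_ions": n,
        "ion_scale": scale,
        "n_vertices": int(sel.size),
        "n_detected": int(nd),
        "t_mid": t_mid,
        "offset_mid": float(np.asarray(offset_fn(np.array([t_mid])),
                                       dtype=float).reshape(-1)[0]),
        "mean_stop_z": float(z_stop.mean()) if z_stop.size else np.nan,
    }
    return clusters, truth_vertices, summary


@dataclass
class RunBundle:
    """All artefacts of one simulated delivery."""

    case: str
    seed: int
    plan: pd.DataFrame
    spot_log: pd.DataFrame
    fpga: FpgaLog
    motor: motion_mod.MotorLog
    clusters: pd.DataFrame
    truth_vertices: pd.DataFrame
    truth_spots: pd.DataFrame
    meta: dict = field(default_factory=dict)


def simulate_delivery(geom: PhantomGeometry, tracker: TrackerGeometry,
                      scanner: ScannerGeometry, range_model: RangeModel,
                      plan: list[BeamSpot],
                      timeline: list[tuple[int, float, float]],
                      case: str, lujan: LujanParams, cfg: SimConfig,
                      seed: int,
                      beam_sigma_recorded: float | None = None,
                      motor_dt: float = 1e-4,
                      motor_drift_um: float = 0.0,
                      ) -> RunBundle:
    """Simulate a full delivery for one experimental case.

    ``static_in`` keeps the phantom at offset 0, ``static_out`` at the motion
    amplitude, and ``moving`` evaluates the Lujan trace at each ion's time.
    """
    if case == "static_in":
        offset_fn = lambda t: np.zeros_like(np.asarray(t, dtype=float))
    elif case == "static_out":
        offset_fn = lambda t: np.full_like(np.asarray(t, dtype=float),
                                           lujan.amplitude)
    elif case == "moving":
        offset_fn = lambda t: motion_mod.position(t, lujan)
    else:
        raise ValueError(f"unknown case {case!r}")

    duration = timeline[-1][2] + 0.5
    if case == "moving":
        motor = motion_mod.generate_motor_log(lujan, duration, dt=motor_dt,
                                              drift_um=motor_drift_um,
                                              seed=seed)
    else:
        t = np.round(lujan.start_time + motor_dt
                     * np.arange(int(duration / motor_dt) + 1), 6)
        val = 0.0 if case == "static_in" else lujan.amplitude
        motor = motion_mod.MotorLog(t, np.full(t.shape, val),
                                    lujan.start_time)

    by_idx = {s.spot_index: s for s in plan}
    clusters_l, truths_l, summaries = [], [], []
    for spot_index, t0, t1 in timeline:
        rng = np.random.default_rng([seed, spot_index])
        cl, tv, summ = simulate_spot(geom, tracker, scanner, range_model,
                                     by_idx[spot_index], t0, t1, offset_fn,
                                     cfg, rng)
        cl.insert(0, "spot_index", spot_index)
        clusters_l.append(cl)
        truths_l.append(tv)
        summaries.append(summ)

    spot_log = make_spot_log(plan, timeline, scanner,
                             beam_sigma=(beam_sigma_recorded
                                         if beam_sigma_recorded is not None
                                         else max(cfg.beam_sigma_mm, 1e-6)),
                             seed=[seed, 1 << 20])
    fpga = make_fpga_log(timeline,
                         motion_trigger_time=lujan.start_time,
                         frame_time=tracker.frame_time_s,
                         run_end=duration)
    clusters = pd.concat(clusters_l, ignore_index=True) if clusters_l \
        else pd.DataFrame(columns=["spot_index", *CLUSTER_COLS])
    truth_vertices = pd.concat(truths_l, ignore_index=True) if truths_l \
        else pd.DataFrame()
    truth_spots = pd.DataFrame(summaries)
    return RunBundle(case, seed, plan_to_frame(plan), spot_log, fpga, motor,
                     clusters, truth_vertices, truth_spots,
                     meta={"case": case, "seed": seed})


def simulate_alignment_run(tracker: TrackerGeometry, n_tracks: int,
                           injected_offsets: dict | None = None,
                           cluster_sigma_mm: float = 0.010,
                           seed: int | None = 0) -> pd.DataFrame:
    """No-target low-intensity run: straight reference tracks through the
    arms, one per frame, with optional injected per-sensor rigid (du, dv)
    offsets.  ``injected_offsets`` maps (arm, sensor) -> (du, dv)."""
    rng = np.random.default_rng(seed)
    injected_offsets = injected_offsets or {}
    rows = []
    ns = tracker.sensors_per_arm
    for i in range(n_tracks):
        arm = int(rng.integers(0, tracker.n_arms))
        uh, vh, w = tracker.basis(arm)
        # source point near the isocenter, aimed at the middle sensor
        src = rng.normal(0.0, 5.0, 3)
        tgt_u = rng.uniform(-tracker.half_u * 0.8, tracker.half_u * 0.8)
        tgt_v = rng.uniform(-tracker.half_v * 0.8, tracker.half_v * 0.8)
        tgt = tracker.to_global(arm, 1, tgt_u, tgt_v).reshape(3)
        d = tgt - src
        d = d / np.linalg.norm(d)
        wd = float(d @ w)
        if wd <= 0:
            continue
        ok = True
        uvs = []
        for k in range(ns):
            t = (tracker.sensor_distance(k) - float(src @ w)) / wd
            q = src + t * d
            u, v = float(q @ uh), float(q @ vh)
            if abs(u) > tracker.half_u or abs(v) > tracker.half_v:
                ok = False
                break
            du, dv = injected_offsets.get((arm, k), (0.0, 0.0))
            u += du + rng.normal(0.0, cluster_sigma_mm)
            v += dv + rng.normal(0.0, cluster_sigma_mm)
            uvs.append((u, v))
        if not ok:
            continue
        for k, (u, v) in enumerate(uvs):
            rows.append({"arm": arm, "sensor": k, "frame": i,
                         "u_mm": u, "v_mm": v, "truth_vertex": i})
    return pd.DataFrame(rows, columns=CLUSTER_COLS)


# ---------------------------------------------------------------------------
# Run-bundle I/O (plain-text CSV + JSON manifest)
# ---------------------------------------------------------------------------

def write_run(bundle: RunBundle, run_dir) -> None:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    # %.17g keeps float64 values bit-exact through the CSV round trip
    bundle.plan.to_csv(run_dir / "plan.csv", index=False,
                       float_format="%.17g")
    write_spot_log(bundle.spot_log, run_dir / "spot_log.csv")
    write_fpga_log(bundle.fpga, run_dir / "fpga_log.csv")
    motion_mod.write_motor_log(bundle.motor, run_dir / "motor_log.csv")
    bundle.clusters.to_csv(run_dir / "clusters.csv", index=False,
                           float_format="%.17g")
    bundle.truth_vertices.to_csv(run_dir / "truth_vertices.csv", index=False,
                                 float_format="%.17g")
    bundle.truth_spots.to_csv(run_dir / "truth_spots.csv", index=False,
                              float_format="%.17g")
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump({"case": bundle.case, "seed": bundle.seed,
                   **bundle.meta}, fh, indent=2, sort_keys=True)


def read_run(run_dir) -> RunBundle:
    run_dir = Path(run_dir)
    with open(run_dir / "manifest.json") as fh:
        meta = json.load(fh)
    rt = {"float_precision": "round_trip"}  # exact float64 round trip
    return RunBundle(
        case=meta["case"], seed=meta["seed"],
        plan=pd.read_csv(run_dir / "plan.csv", **rt),
        spot_log=read_spot_log(run_dir / "spot_log.csv"),
        fpga=read_fpga_log(run_dir / "fpga_log.csv"),
        motor=motion_mod.read_motor_log(run_dir / "motor_log.csv"),
        clusters=pd.read_csv(run_dir / "clusters.csv", **rt),
        truth_vertices=pd.read_csv(run_dir / "truth_vertices.csv", **rt),
        truth_spots=pd.read_csv(run_dir / "truth_spots.csv", **rt),
        meta=meta,
    )
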