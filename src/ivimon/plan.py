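"""Simplified spherical-target scanned plan, delivery timeline and logfiles.

The treatment-planning surrogate covers a margin-shrunk sphere with a regular
lateral spot grid per iso-energy layer; layer energies come from a two-point
power-law range model.  Spot logfiles mimic the nozzle records (scanner
settings, MWPC centroid/width, particle count, energy, timestamps) and an
FPGA log carries the 100 kHz-timestamped synchronization signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import PhantomGeometry

__all__ = [
    "RangeModel",
    "ScannerGeometry",
    "BeamSpot",
    "generate_spherical_plan",
    "delivery_timeline",
    "plan_to_frame",
    "frame_to_plan",
    "make_spot_log",
    "write_spot_log",
    "read_spot_log",
    "FpgaLog",
    "make_fpga_log",
    "write_fpga_log",
    "read_fpga_log",
    "FPGA_TICK_HZ",
]

FPGA_TICK_HZ = 100_000.0


@dataclass(frozen=True)
class RangeModel:
    """Power-law range-energy relation R = alpha * E^p (mm water, MeV/u).

    Calibrated from two anchor points; the anchors are reproduced exactly.
    """

    alpha: float
    p: float
    e_min: float = 80.0
    e_max: float = 430.0

    @classmethod
    def from_anchors(cls, e1: float, r1: float, e2: float, r2: float,
                     e_min: float = 80.0, e_max: float = 430.0) -> "RangeModel":
        if e1 <= 0 or e2 <= 0 or r1 <= 0 or r2 <= 0 or e1 == e2:
            raise ValueError("invalid anchors")
        p = np.log(r2 / r1) / np.log(e2 / e1)
        alpha = r1 / e1 ** p
        return cls(alpha=float(alpha), p=float(p), e_min=e_min, e_max=e_max)

    def energy_to_range(self, energy):
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise ValueError(
                f"energy outside calibrated domain [{self.e_min}, {self.e_max}]")
        r = self.alpha * e ** self.p
        return float(r) if r.ndim == 0 else r

    def range_to_energy(self, rng_mm):
        r = np.asarray(rng_mm, dtype=float)
        e = (r / self.alpha) ** (1.0 / self.p)
        if np.any(e < self.e_min - 1e-9) or np.any(e > self.e_max + 1e-9):
            raise ValueError("range outside calibrated domain")
        return float(e) if e.ndim == 0 else e


# Carbon-ion water-range anchors (mm at MeV/u); configurable, not a claim of
# measured base data.
DEFAULT_RANGE_MODEL = RangeModel.from_anchors(200.0, 86.0, 400.0, 275.0)


@dataclass(frozen=True)
class ScannerGeometry:
    """z positions (mm, isocenter frame, beam travels +z) of the scanner
    magnets and the two nozzle MWPCs."""

    z_xm: float = -7534.0
    z_ym: float = -8234.0
    z_mwpc1: float = -1100.0
    z_mwpc2: float = -900.0

    def __post_init__(self) -> None:
        if abs(self.z_xm) == abs(self.z_ym):
            raise ValueError("scanner magnets must sit at distinct z")
        for z in (self.z_mwpc1, self.z_mwpc2):
            if not (min(self.z_xm, self.z_ym) < z < 0):
                raise ValueError("MWPCs must lie between the scanners and the phantom")


@dataclass(frozen=True)
class BeamSpot:
    """One planned raster spot."""

    spot_index: int
    layer_index: int
    energy: float          # MeV/u
    x_v: float             # planned voxel position, mm
    y_v: float
    z_v: float
    n_planned: int

    def __post_init__(self) -> None:
        if self.n_planned <= 0:
            raise ValueError("n_planned must be > 0")


def _axis_ray(geom: PhantomGeometry):
    oh = geom.outer_half
    return np.array([0.0, 0.0, -(oh + 50.0)]), np.array([0.0, 0.0, 1.0])


def generate_spherical_plan(geom: PhantomGeometry,
                            range_model: RangeModel = DEFAULT_RANGE_MODEL,
                            sphere_radius: float | None = None,
                            inner_margin: float = 3.0,
                            spot_spacing: float = 2.0,
                            layer_spacing_wepl: float = 3.0,
                            n_particles: int = 10_000,
                            distal_boost: float = 1.0,
                            serpentine: bool = True) -> list[BeamSpot]:
    """Uniform-fluence plan covering the margin-shrunk target sphere.

    Layers are placed at water-equivalent depth steps of
    ``layer_spacing_wepl`` along the central axis, shallow to deep; layer
    energy is the beam energy whose water range equals the layer's WEPL.
    Within a layer, spots sit on a ``spot_spacing`` grid limited to the
    sphere cross-section at that depth, ordered serpentine.  Spots are
    emitted grouped by layer in increasing energy.
    """
    if sphere_radius is None:
        sphere_radius = geom.sphere_radius
    if not (sphere_radius > inner_margin >= 0):
        raise ValueError("require sphere_radius > inner_margin >= 0")
    r_t = sphere_radius - inner_margin
    if spot_spacing > 2 * sphere_radius:
        raise ValueError("spot spacing larger than the sphere")
    cx, cy, cz = geom.sphere_center

    origin, direction = _axis_ray(geom)
    w_lo = geom.wepl_to_depth(origin, direction, cz - r_t)
    w_hi = geom.wepl_to_depth(origin, direction, cz + r_t)
    n_layers = max(1, int(np.floor((w_hi - w_lo) / layer_spacing_wepl)) + 1)
    wepls = w_lo + layer_spacing_wepl * np.arange(n_layers)
    if r_t <= spot_spacing / 2.0:
        wepls = np.array([0.5 * (w_lo + w_hi)])

    spots: list[BeamSpot] = []
    idx = 0
    for li, w in enumerate(wepls):
        z_v = geom.depth_for_wepl(origin, direction, w)
        if not np.isfinite(z_v):
            raise ValueError("layer WEPL beyond the phantom")
        energy = range_model.range_to_energy(w)
        dz = z_v - cz
        r_layer2 = r_t ** 2 - dz ** 2
        if r_layer2 < 0:
            r_layer2 = 0.0
        r_layer = np.sqrt(r_layer2)
        kmax = int(np.floor(r_layer / spot_spacing))
        ys = cy + spot_spacing * np.arange(-kmax, kmax + 1)
        n_boost = n_particles
        if li == len(wepls) - 1:
            n_boost = max(1, int(round(n_particles * distal_boost)))
        layer_spots: list[BeamSpot] = []
        for row, y in enumerate(ys):
            lat2 = r_layer2 - (y - cy) ** 2
            if lat2 < 0:
                continue
            xmax = int(np.floor(np.sqrt(lat2) / spot_spacing))
            xs = cx + spot_spacing * np.arange(-xmax, xmax + 1)
            if serpentine and row % 2 == 1:
                xs = xs[::-1]
            for x in xs:
                layer_spots.append(BeamSpot(idx, li, float(energy), float(x),
                                            float(y), float(z_v), n_boost))
                idx += 1
        if not layer_spots:  # always cover the layer centre
            layer_spots.append(BeamSpot(idx, li, float(energy), float(cx),
                                        float(cy), float(z_v), n_boost))
            idx += 1
        spots.extend(layer_spots)
    return spots


def delivery_timeline(plan: list[BeamSpot], intensity: float,
                      inter_spot_gap: float = 0.0,
                      inter_layer_gap: float = 0.0,
                      t0: float = 0.0,
                      gap_jitter_frac: float = 0.0,
                      seed: int | None = None,
                      ) -> list[tuple[int, float, float]]:
    """(spot_index, t_start, t_end) tuples, ordered by delivery order.

    Spot duration is n_planned / intensity.  ``gap_jitter_frac`` scales a
    uniform multiplicative jitter on the inter-spot gaps (models accelerator
    timing variability between repeats); 0 keeps the timeline deterministic.
    """
    if intensity <= 0:
        raise ValueError("intensity must be > 0")
    rng = np.random.default_rng(seed)
    ordered = sorted(plan, key=lambda s: s.spot_index)
    out: list[tuple[int, float, float]] = []
    t = t0
    prev_layer: int | None = None
    for spot in ordered:
        if prev_layer is not None and spot.layer_index != prev_layer:
            t += inter_layer_gap
        elif prev_layer is not None:
            gap = inter_spot_gap
            if gap_jitter_frac > 0:
                gap *= 1.0 + gap_jitter_frac * rng.uniform(-1.0, 1.0)
            t += gap
        dur = spot.n_planned / intensity
        out.append((spot.spot_index, t, t + dur))
        t += dur
        prev_layer = spot.layer_index
    return out


# ---------------------------------------------------------------------------
# Plan / spot-log / FPGA-log file formats (CSV).
# ---------------------------------------------------------------------------

_PLAN_COLS = ["spot_index", "layer_index", "energy", "x_v", "y_v", "z_v",
              "n_planned"]


def plan_to_frame(plan: list[BeamSpot]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(s, {"energy": "energy"}.get(c, c))
                          for c in _PLAN_COLS} for s in plan])


def frame_to_plan(df: pd.DataFrame) -> list[BeamSpot]:
    missing = [c for c in _PLAN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"plan file missing column(s): {', '.join(missing)}")
    return [BeamSpot(int(r.spot_index), int(r.layer_index), float(r.energy),
                     float(r.x_v), float(r.y_v), float(r.z_v),
                     int(r.n_planned)) for r in df.itertuples()]


_SPOTLOG_COLS = ["spot_index", "scanner_x", "scanner_y", "x_i", "y_i",
                 "sigma_x_i", "sigma_y_i", "z_i", "n_delivered", "energy",
                 "t_start", "t_end"]


def spot_slopes(spot: BeamSpot, scanner: ScannerGeometry) -> tuple[float, float]:
    """Slopes of the nominal beam line: pivot at the scanner magnet (lateral
    position zero there) through the planned voxel."""
    a_x = spot.x_v / (spot.z_v - scanner.z_xm)
    a_y = spot.y_v / (spot.z_v - scanner.z_ym)
    return a_x, a_y


def nominal_lateral(spot: BeamSpot, scanner: ScannerGeometry, z: float,
                    ) -> tuple[float, float]:
    a_x, a_y = spot_slopes(spot, scanner)
    return (spot.x_v + a_x * (z - spot.z_v), spot.y_v + a_y * (z - spot.z_v))


def make_spot_log(plan: list[BeamSpot],
                  timeline: list[tuple[int, float, float]],
                  scanner: ScannerGeometry,
                  beam_sigma: float = 3.0,
                  positioning_noise: float = 0.0,
                  delivered_fluctuation: float = 0.0,
                  seed: int | None = None) -> pd.DataFrame:
    """Nozzle-style per-spot log.

    ``x_i``/``y_i`` is the MWPC-averaged beam centroid: the nominal beam line
    evaluated at the two MWPC planes and averaged, plus Gaussian positioning
    noise.  ``sigma_*`` is the recorded beam width.  ``z_i`` is the MWPC 1
    plane.
    """
    rng = np.random.default_rng(seed)
    by_idx = {s.spot_index: s for s in plan}
    rows = []
    for spot_index, t_start, t_end in timeline:
        s = by_idx[spot_index]
        x1, y1 = nominal_lateral(s, scanner, scanner.z_mwpc1)
        x2, y2 = nominal_lateral(s, scanner, scanner.z_mwpc2)
        xi, yi = 0.5 * (x1 + x2), 0.5 * (y1 + y2)
        if positioning_noise > 0:
            xi += rng.normal(0.0, positioning_noise)
            yi += rng.normal(0.0, positioning_noise)
        n_del = s.n_planned
        if delivered_fluctuation > 0:
            n_del = max(1, int(round(s.n_planned
                                     * (1.0 + delivered_fluctuation
                                        * rng.uniform(-1.0, 1.0)))))
        rows.append({
            "spot_index": spot_index,
            "scanner_x": s.x_v, "scanner_y": s.y_v,
            "x_i": xi, "y_i": yi,
            "sigma_x_i": beam_sigma, "sigma_y_i": beam_sigma,
            "z_i": scanner.z_mwpc1,
            "n_delivered": n_del,
            "energy": s.energy,
            "t_start": t_start, "t_end": t_end,
        })
    df = pd.DataFrame(rows, columns=_SPOTLOG_COLS)
    return df.sort_values("t_start", kind="stable").reset_index(drop=True)


def write_spot_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_spot_log(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SPOTLOG_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"spot log missing column(s): {', '.join(missing)}")
    for col in _SPOTLOG_COLS:
        if col not in ("spot_index", "n_delivered"):
            df[col] = df[col].astype(float)
    return df


@dataclass
class FpgaLog:
    """Timestamped synchronization events at 100 kHz tick resolution."""

    ticks: np.ndarray
    signals: np.ndarray  # str array

    def __post_init__(self) -> None:
        self.ticks = np.asarray(self.ticks, dtype=np.int64)
        self.signals = np.asarray(self.signals, dtype=object)
        if np.any(np.diff(self.ticks) < 0):
            raise ValueError("FPGA ticks must be non-decreasing")

    def count(self, signal: str) -> int:
        return int(np.sum(self.signals == signal))

    def times(self, signal: str) -> np.ndarray:
        return self.ticks[self.signals == signal] / FPGA_TICK_HZ


def make_fpga_log(timeline: list[tuple[int, float, float]],
                  motion_trigger_time: float | None = 0.0,
                  frame_time: float | None = None,
                  run_end: float | None = None) -> FpgaLog:
    """Build the FPGA event stream: a motion trigger, one ``next_spot`` per
    delivered spot, and (optionally) the two DAQ frame clocks."""
    events: list[tuple[int, str]] = []
    if motion_trigger_time is not None:
        events.append((int(round(motion_trigger_time * FPGA_TICK_HZ)),
                       "motion_trigger"))
    for _, t_start, _ in timeline:
        events.append((int(round(t_start * FPGA_TICK_HZ)), "next_spot"))
    if frame_time is not None:
        t_end = run_end if run_end is not None else (timeline[-1][2] + frame_time)
        n_frames = int(np.ceil(t_end / frame_time))
        for sys in ("frame_clock_sys1", "frame_clock_sys2"):
            for k in range(n_frames + 1):
                events.append((int(round(k * frame_time * FPGA_TICK_HZ)), sys))
    events.sort(key=lambda e: e[0])
    return FpgaLog(np.array([e[0] for e in events], dtype=np.int64),
                   np.array([e[1] for e in events], dtype=object))


def write_fpga_log(log: FpgaLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("tick,signal_name\n")
        for t, s in zip(log.ticks, log.signals):
            fh.write(f"{t},{s}\n")


def read_fpga_log(path) -> FpgaLog:
    df = pd.read_csv(path)
    for col in ("tick", "signal_name"):
        if col not in df.columns:
            raise ValueError(f"FPGA log missing column: {col}")
    return FpgaLog(df["tick"].to_numpy(np.int64),
                   df["signal_name"].to_numpy(object))
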