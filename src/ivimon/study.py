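"""End-to-end study orchestration: configuration, simulation, reconstruction
and analysis of the static_in / static_out / moving cases with repeats.

The single :class:`StudyConfig` block drives everything; every random
operation is seeded deterministically from the master seed so re-running a
study reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import monitor as monitor_mod
from . import motion as motion_mod
from .fragsim import (RunBundle, SimConfig, TrackerGeometry,
                      simulate_delivery, write_run)
from .motion import LujanParams, PhaseBins
from .phantom import PhantomGeometry
from .plan import (BeamSpot, RangeModel, ScannerGeometry, delivery_timeline,
                   frame_to_plan, generate_spherical_plan, plan_to_frame)
from .trackrec import associate_frames_to_spots, build_tracks
from .vertexrec import (VertexDistribution, choose_q, computed_vertex,
                        primary_track_a, primary_track_b,
                        reconstruct_vertices, vertices_to_frame)

__all__ = [
    "StudyConfig",
    "load_config",
    "save_config",
    "build_objects",
    "make_plan",
    "simulate_case",
    "reconstruct_run",
    "analyze_study",
    "run_study",
    "CASES",
]

CASES = ("static_in", "static_out", "moving")


def _from_dict(cls, data: dict, ctx: str):
    """Strictly construct a dataclass from a mapping, naming bad fields."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config section {ctx!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config field {ctx}.{sorted(unknown)[0]}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class PhantomConfig:
    aquarium_outer: float = 260.0
    foam_dims: tuple[float, float, float] = (240.0, 250.0, 250.0)
    cylinder_diameter: float = 50.0
    cylinder_length: float = 100.0


@dataclass(frozen=True)
class MotionConfig:
    amplitude: float = 20.0
    period: float = 3.0
    n: int = 2
    phase_edges: tuple[float, ...] = (0.0, 3.0, 17.0, 20.0)
    motor_dt: float = 1e-4
    motor_drift_um: float = 0.0


@dataclass(frozen=True)
class PlanConfig:
    inner_margin: float = 3.0
    spot_spacing: float = 4.0
    layer_spacing_wepl: float = 6.0
    n_particles: int = 12000
    intensity: float = 1.0e6
    inter_spot_gap: float = 0.020
    inter_layer_gap: float = 0.5
    gap_jitter_frac: float = 0.5
    range_anchors: tuple[float, float, float, float] = (200.0, 86.0, 400.0,
                                                        275.0)


@dataclass(frozen=True)
class ScannerConfig:
    z_xm: float = -7534.0
    z_ym: float = -8234.0
    z_mwpc1: float = -1100.0
    z_mwpc2: float = -900.0


@dataclass(frozen=True)
class TrackerConfig:
    angles_deg: tuple[float, ...] = (-21.0, -10.5, 10.5, 21.0)
    radial_mm: float = 248.0
    sensor_spacing_mm: float = 20.0
    frame_time_s: float = 186.5e-6


@dataclass(frozen=True)
class SimulatorConfig:
    lambda_w_mm: float = 150.0
    fragments_per_vertex: int = 10
    frag_range_multiplier: float = 3.0
    frag_angle_sigma: float = 0.12
    cluster_sigma_mm: float = 0.010
    beam_sigma_mm: float = 1.0
    scattering: bool = True
    smearing: bool = True
    noise_cluster_rate: float = 0.0
    max_ions_per_spot: int | None = None


@dataclass(frozen=True)
class ReconConfig:
    method: str = "a"
    dca_cut: float = 25.0
    residual_cut: float = 0.050
    min_vertices: int = 50
    # grid capped at 0.95: the sample maximum (q = 1.0) is a degenerate
    # quantile estimator whose noise inflates the repeat threshold
    q_grid: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.9501, 0.05),
                                               2))


@dataclass(frozen=True)
class MonitorConfig:
    pos_m_grid: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)
    pos_m: float = 2.0
    edge_slice_thickness: float = 6.0
    edge_x_min: float = 5.0
    edge_y_max: float = 0.0
    zero_shift_tol: float = 0.5


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 1
    repeats: int = 5
    cases: tuple[str, ...] = CASES
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    motion: MotionConfig = field(default_factory=MotionConfig)
    plan: PlanConfig = field(default_factory=PlanConfig)
    scanner: ScannerConfig = field(default_factory=ScannerConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    sim: SimulatorConfig = field(default_factory=SimulatorConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    monitor: MonitorConfig = field(default_factory=MonitorConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "StudyConfig":
        data = dict(data or {})
        sections = {"phantom": PhantomConfig, "motion": MotionConfig,
                    "plan": PlanConfig, "scanner": ScannerConfig,
                    "tracker": TrackerConfig, "sim": SimulatorConfig,
                    "recon": ReconConfig, "monitor": MonitorConfig}
        kwargs = {}
        for key, sub in sections.items():
            if key in data:
                kwargs[key] = _from_dict(sub, data.pop(key), key)
        top = _from_dict(_TopLevel, data, "study")
        kwargs.update({f.name: getattr(top, f.name)
                       for f in dataclasses.fields(_TopLevel)})
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {f.name: conv(getattr(o, f.name))
                        for f in dataclasses.fields(o)}
            if isinstance(o, tuple):
                return [conv(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o
        return conv(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class _TopLevel:
    seed: int = 1
    repeats: int = 5
    cases: tuple[str, ...] = CASES


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return StudyConfig.from_dict(data)


def save_config(cfg: StudyConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Object construction
# ---------------------------------------------------------------------------

def build_objects(cfg: StudyConfig):
    geom = PhantomGeometry(aquarium_outer=cfg.phantom.aquarium_outer,
                           foam_dims=cfg.phantom.foam_dims,
                           cylinder_diameter=cfg.phantom.cylinder_diameter,
                           cylinder_length=cfg.phantom.cylinder_length)
    tracker = TrackerGeometry(angles_deg=cfg.tracker.angles_deg,
                              radial_mm=cfg.tracker.radial_mm,
                              sensor_spacing_mm=cfg.tracker.sensor_spacing_mm,
                              frame_time_s=cfg.tracker.frame_time_s)
    scanner = ScannerGeometry(z_xm=cfg.scanner.z_xm, z_ym=cfg.scanner.z_ym,
                              z_mwpc1=cfg.scanner.z_mwpc1,
                              z_mwpc2=cfg.scanner.z_mwpc2)
    e1, r1, e2, r2 = cfg.plan.range_anchors
    range_model = RangeModel.from_anchors(e1, r1, e2, r2)
    lujan = LujanParams(amplitude=cfg.motion.amplitude,
                        period=cfg.motion.period, n=cfg.motion.n)
    bins = PhaseBins(cfg.motion.phase_edges)
    sim = SimConfig(lambda_w_mm=cfg.sim.lambda_w_mm,
                    fragments_per_vertex=cfg.sim.fragments_per_vertex,
                    frag_range_multiplier=cfg.sim.frag_range_multiplier,
                    frag_angle_sigma=cfg.sim.frag_angle_sigma,
                    cluster_sigma_mm=cfg.sim.cluster_sigma_mm,
                    beam_sigma_mm=cfg.sim.beam_sigma_mm,
                    scattering=cfg.sim.scattering,
                    smearing=cfg.sim.smearing,
                    noise_cluster_rate=cfg.sim.noise_cluster_rate,
                    max_ions_per_spot=cfg.sim.max_ions_per_spot)
    return geom, tracker, scanner, range_model, lujan, bins, sim


def make_plan(cfg: StudyConfig, geom: PhantomGeometry,
              range_model: RangeModel,
              plan_filter: str = "sphere") -> list[BeamSpot]:
    """Full spherical plan, or a single iso-energy layer via ``layer:<E>``."""
    plan = generate_spherical_plan(
        geom, range_model,
        inner_margin=cfg.plan.inner_margin,
        spot_spacing=cfg.plan.spot_spacing,
        layer_spacing_wepl=cfg.plan.layer_spacing_wepl,
        n_particles=cfg.plan.n_particles)
    if plan_filter == "sphere":
        return plan
    if plan_filter.startswith("layer:"):
        e_want = float(plan_filter.split(":", 1)[1])
        energies = sorted({s.energy for s in plan})
        e_sel = min(energies, key=lambda e: abs(e - e_want))
        return [s for s in plan if s.energy == e_sel]
    raise ValueError(f"unknown plan filter {plan_filter!r}")


# ---------------------------------------------------------------------------
# Simulation / reconstruction / analysis stages
# ---------------------------------------------------------------------------

def _case_seed(cfg: StudyConfig, case: str, repeat: int) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{case}:{repeat}".encode()).digest()
    return int.from_bytes(h[:6], "big")


def simulate_case(cfg: StudyConfig, plan: list[BeamSpot], case: str,
                  repeat: int, objects=None) -> RunBundle:
    if objects is None:
        objects = build_objects(cfg)
    geom, tracker, scanner, range_model, lujan, bins, sim = objects
    seed = _case_seed(cfg, case, repeat)
    timeline = delivery_timeline(plan, cfg.plan.intensity,
                                 inter_spot_gap=cfg.plan.inter_spot_gap,
                                 inter_layer_gap=cfg.plan.inter_layer_gap,
                                 t0=0.05,
                                 gap_jitter_frac=cfg.plan.gap_jitter_frac,
                                 seed=[seed, 7])
    bundle = simulate_delivery(geom, tracker, scanner, range_model, plan,
                               timeline, case, lujan, sim, seed,
                               motor_dt=cfg.motion.motor_dt,
                               motor_drift_um=cfg.motion.motor_drift_um)
    bundle.meta.update({"repeat": repeat, "config_hash": cfg.config_hash()})
    return bundle


def reconstruct_run(bundle: RunBundle, cfg: StudyConfig, objects=None,
                    method: str | None = None,
                    ) -> tuple[dict[int, VertexDistribution], pd.DataFrame]:
    """Tracks -> frame/spot association -> vertices, for one run bundle."""
    if objects is None:
        objects = build_objects(cfg)
    geom, tracker, scanner, _range_model, _lujan, _bins, _sim = objects
    method = method or cfg.recon.method
    plan = frame_to_plan(bundle.plan)
    by_idx = {s.spot_index: s for s in plan}

    clusters = bundle.clusters
    tracks = build_tracks(clusters, tracker,
                          residual_cut=cfg.recon.residual_cut)
    timeline = [(int(r.spot_index), float(r.t_start), float(r.t_end))
                for r in bundle.spot_log.itertuples()]
    frame_map = associate_frames_to_spots(timeline,
                                          {t.frame for t in tracks},
                                          tracker.frame_time_s)
    by_spot: dict[int, list] = {}
    for t in tracks:
        spot = frame_map.get(t.frame)
        t.spot_index = spot
        if spot is not None:
            by_spot.setdefault(spot, []).append(t)

    rng_master = np.random.default_rng([bundle.seed, 0xB])
    vdists: dict[int, VertexDistribution] = {}
    for rec in bundle.spot_log.itertuples():
        spot = by_idx[int(rec.spot_index)]
        if method == "a":
            primary = primary_track_a(rec, spot, scanner)
        else:
            rng = np.random.default_rng([bundle.seed, 0xB, spot.spot_index])
            primary = primary_track_b(rec, spot, scanner, rng, geom=geom,
                                      scattering=True)
        vdists[spot.spot_index] = reconstruct_vertices(
            primary, by_spot.get(spot.spot_index, []), geom,
            dca_cut=cfg.recon.dca_cut)
    del rng_master
    vert_df = vertices_to_frame(list(vdists.values()))
    return vdists, vert_df


def _planned_overshoot_spots(plan: list[BeamSpot], geom: PhantomGeometry,
                             scanner: ScannerGeometry) -> set[int]:
    """Spots whose planned line never crosses the PMMA insert at offset 0."""
    from .plan import spot_slopes
    out = set()
    for s in plan:
        ax, ay = spot_slopes(s, scanner)
        z0 = -geom.outer_half - 50.0
        origin = (s.x_v + ax * (z0 - s.z_v), s.y_v + ay * (z0 - s.z_v), z0)
        segs = geom.path_segments(origin, (ax, ay, 1.0), 0.0)
        if not any(m.name == geom.insert_material.name and L > 0
                   for m, L in segs):
            out.add(s.spot_index)
    return out


def analyze_study(cfg: StudyConfig,
                  vdists_by: dict[tuple[str, int], dict[int, VertexDistribution]],
                  truth_by: dict[tuple[str, int], pd.DataFrame],
                  plan: list[BeamSpot], objects=None) -> dict:
    """Decision-layer analysis over reconstructed runs.

    ``vdists_by`` maps (case, repeat) -> {spot: VertexDistribution};
    ``truth_by`` maps (case, repeat) -> truth_spots table (used only for the
    motor-position ground truth, as the experiment's motor logfile was).
    """
    if objects is None:
        objects = build_objects(cfg)
    geom, tracker, scanner, range_model, lujan, bins, sim = objects
    repeats = cfg.repeats
    spots = sorted({s.spot_index for s in plan})
    spot_pos = {s.spot_index: s for s in plan}
    n_spots = len(spots)
    min_v = cfg.recon.min_vertices

    def z_samples(case, rep):
        return {sp: vd.z for sp, vd in vdists_by[(case, rep)].items()}

    # -- quantile selection from the pooled static repeats ------------------
    pool_in: dict[int, np.ndarray] = {}
    pool_out: dict[int, np.ndarray] = {}
    for rep in range(repeats):
        for sp, z in z_samples("static_in", rep).items():
            pool_in[sp] = np.concatenate([pool_in.get(sp, np.empty(0)), z])
        for sp, z in z_samples("static_out", rep).items():
            pool_out[sp] = np.concatenate([pool_out.get(sp, np.empty(0)), z])
    q_star = choose_q(pool_in, pool_out, grid=cfg.recon.q_grid,
                      min_vertices=min_v)

    # -- computed vertices per case/repeat ----------------------------------
    def vz_matrix(case):
        m = np.full((repeats, n_spots), np.nan)
        nv = np.zeros((repeats, n_spots), dtype=int)
        for rep in range(repeats):
            vd = vdists_by[(case, rep)]
            for j, sp in enumerate(spots):
                if sp in vd:
                    cv = computed_vertex(vd[sp], q_star, min_vertices=min_v)
                    nv[rep, j] = cv.n_vertices
                    if cv.valid:
                        m[rep, j] = cv.v_z
        return m, nv

    vz = {}
    nvert = {}
    for case in cfg.cases:
        vz[case], nvert[case] = vz_matrix(case)

    import warnings
    thr_pooled, thr_spot = monitor_mod.thr_from_repeats(vz["static_in"],
                                                        vz["static_out"])
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN spots
        ref_in = np.nanmean(vz["static_in"], axis=0)
        ref_out = np.nanmean(vz["static_out"], axis=0)
        unc_in = np.sqrt(np.nanmean((vz["static_in"] - ref_in) ** 2, axis=0))
        unc_out = np.sqrt(np.nanmean((vz["static_out"] - ref_out) ** 2,
                                     axis=0))
    uncertainty = np.sqrt(unc_in ** 2 + unc_out ** 2)

    result: dict = {
        "q_star": q_star,
        "thr_diff": thr_pooled,
        "n_spots": n_spots,
        "valid_fraction": {
            case: float(np.mean(np.isfinite(vz[case]))) for case in cfg.cases
        },
    }

    if "moving" not in cfg.cases:
        return {"summary": result, "per_spot": None, "vz": vz,
                "thr_per_spot": thr_spot}

    # -- moving-case differences, calls, truth -------------------------------
    overshoot = _planned_overshoot_spots(plan, geom, scanner)
    edge = set(monitor_mod.select_edge_spots(
        plan, sphere_center=geom.sphere_center,
        sphere_radius=geom.sphere_radius,
        slice_thickness=cfg.monitor.edge_slice_thickness,
        x_min=cfg.monitor.edge_x_min, y_max=cfg.monitor.edge_y_max))

    rows = []
    for rep in range(repeats):
        truth = truth_by[("moving", rep)].set_index("spot_index")
        truth_in = truth_by[("static_in", rep)].set_index("spot_index")
        for j, sp in enumerate(spots):
            v_mov = vz["moving"][rep, j]
            if not np.isfinite(v_mov) or not np.isfinite(ref_in[j]) \
                    or not np.isfinite(ref_out[j]):
                continue
            sin = v_mov - ref_in[j]
            sout = v_mov - ref_out[j]
            din, dout = abs(sin), abs(sout)
            motor = float(truth.loc[sp, "offset_mid"])
            stop_mov = float(truth.loc[sp, "mean_stop_z"])
            stop_in = float(truth_in.loc[sp, "mean_stop_z"])
            rows.append({
                "repeat": rep, "spot_index": sp,
                "difference_in": din, "difference_out": dout,
                "signed_in": sin, "signed_out": sout,
                "planned_call": bool(monitor_mod.classify_delivery(
                    din, thr_pooled)),
                "phase_call": int(monitor_mod.assign_phase(din, dout,
                                                           thr_pooled)),
                "motor_mm": motor,
                "truth_phase": int(motion_mod.phase_of(motor, bins)),
                "true_shift_mm": abs(stop_mov - stop_in),
                "edge": sp in edge,
                "overshoot": sp in overshoot,
                "x_v": spot_pos[sp].x_v, "y_v": spot_pos[sp].y_v,
                "z_v": spot_pos[sp].z_v, "energy": spot_pos[sp].energy,
            })
    per_spot = pd.DataFrame(rows)

    # -- efficiency vs pos_m --------------------------------------------------
    eff_rows = []
    for pos_m in cfg.monitor.pos_m_grid:
        per_rep = []
        for rep in range(repeats):
            d = per_spot[(per_spot["repeat"] == rep) & per_spot["edge"]]
            if len(d) == 0:
                continue
            per_rep.append(monitor_mod.total_efficiency(
                d["planned_call"].to_numpy(), d["motor_mm"].to_numpy(),
                pos_m))
        if per_rep:
            eff_rows.append({"pos_m": pos_m,
                             "efficiency_mean": float(np.mean(per_rep)),
                             "efficiency_rms": float(np.std(per_rep)),
                             "n_repeats": len(per_rep)})
    efficiency = pd.DataFrame(eff_rows)

    excl = per_spot["overshoot"].to_numpy()
    confusion_all = monitor_mod.phase_confusion(
        per_spot["phase_call"].to_numpy(), per_spot["truth_phase"].to_numpy(),
        exclude=excl)
    d_edge = per_spot[per_spot["edge"]]
    confusion_edge = monitor_mod.phase_confusion(
        d_edge["phase_call"].to_numpy(), d_edge["truth_phase"].to_numpy(),
        exclude=d_edge["overshoot"].to_numpy()) if len(d_edge) else None

    result.update({
        "n_edge_spots": len(edge),
        "n_overshoot_spots": len(overshoot),
        "efficiency": {str(r["pos_m"]): [r["efficiency_mean"],
                                         r["efficiency_rms"]]
                       for r in eff_rows},
        "confusion_all": confusion_all.round(6).to_dict(),
        "confusion_edge": (confusion_edge.round(6).to_dict()
                           if confusion_edge is not None else None),
        "phase_truth_fractions": {
            str(p): float(np.mean(per_spot["truth_phase"] == p))
            for p in (1, 2, 3)},
    })
    return {"summary": result, "per_spot": per_spot, "efficiency": efficiency,
            "confusion_all": confusion_all, "confusion_edge": confusion_edge,
            "vz": vz, "thr_per_spot": thr_spot, "uncertainty": uncertainty}


# ---------------------------------------------------------------------------
# Full pipeline with on-disk layout
# ---------------------------------------------------------------------------

def run_study(cfg: StudyConfig, out_dir, plan_filter: str = "sphere",
              keep_bundles: bool = True, progress=None) -> dict:
    """Simulate, reconstruct and analyze a full study under ``out_dir``.

    Layout: ``runs/<case>/rep<k>/`` (simulation bundles), ``recon/<case>/
    rep<k>/vertices.csv``, ``analysis/`` (per-spot calls, efficiencies,
    summary.json).  Returns the analysis dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    objects = build_objects(cfg)
    geom, tracker, scanner, range_model, lujan, bins, sim = objects
    plan = make_plan(cfg, geom, range_model, plan_filter)
    plan_to_frame(plan).to_csv(out / "plan.csv", index=False,
                               float_format="%.17g")
    save_config(cfg, out / "config.yaml")

    vdists_by = {}
    truth_by = {}
    for case in cfg.cases:
        for rep in range(cfg.repeats):
            if progress:
                progress(f"simulate {case} repeat {rep}")
            bundle = simulate_case(cfg, plan, case, rep, objects)
            if keep_bundles:
                write_run(bundle, out / "runs" / case / f"rep{rep}")
            if progress:
                progress(f"reconstruct {case} repeat {rep}")
            vdists, vert_df = reconstruct_run(bundle, cfg, objects)
            rdir = out / "recon" / case / f"rep{rep}"
            rdir.mkdir(parents=True, exist_ok=True)
            vert_df.to_csv(rdir / "vertices.csv", index=False)
            vdists_by[(case, rep)] = vdists
            truth_by[(case, rep)] = bundle.truth_spots

    if progress:
        progress("analyze")
    res = analyze_study(cfg, vdists_by, truth_by, plan, objects)
    adir = out / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    if res.get("per_spot") is not None:
        res["per_spot"].to_csv(adir / "per_spot.csv", index=False)
    if res.get("efficiency") is not None:
        res["efficiency"].to_csv(adir / "efficiency.csv", index=False)
    if res.get("confusion_all") is not None:
        res["confusion_all"].to_csv(adir / "confusion_all.csv")
    if res.get("confusion_edge") is not None:
        res["confusion_edge"].to_csv(adir / "confusion_edge.csv")
    summary = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
               **res["summary"]}
    with open(adir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"config_hash": cfg.config_hash(),
                   "cases": list(cfg.cases), "repeats": cfg.repeats},
                  fh, indent=2, sort_keys=True)
    return res
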