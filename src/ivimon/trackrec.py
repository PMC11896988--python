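"""Straight secondary-track reconstruction, alignment, and frame-spot maps.

Tracks are least-squares 3D lines through one cluster per sensor plane of an
arm; candidate triplets within a frame are matched greedily by fit residual.
Alignment is restricted to rigid in-plane offsets with the gauge fixed to the
outer sensors of each arm (only the middle sensors are adjusted).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fragsim import TrackerGeometry

__all__ = [
    "SecondaryTrack",
    "AlignmentSet",
    "fit_track",
    "build_tracks",
    "tracks_to_frame",
    "estimate_alignment",
    "apply_alignment",
    "associate_frames_to_spots",
]


@dataclass
class SecondaryTrack:
    """Back-projected straight track from one tracker arm."""

    arm: int
    frame: int
    point: np.ndarray       # centroid of the fitted clusters (mm)
    direction: np.ndarray   # unit vector, oriented outward (away from target)
    residual_rms: float     # perpendicular rms of clusters about the line
    cluster_ids: tuple[int, ...] = ()
    spot_index: int | None = None


@dataclass
class AlignmentSet:
    """Per-sensor rigid in-plane offsets (du, dv); rotations unsupported."""

    offsets: dict[tuple[int, int], tuple[float, float]] = field(
        default_factory=dict)
    provenance: str = "estimated"

    def get(self, arm: int, sensor: int) -> tuple[float, float]:
        return self.offsets.get((arm, sensor), (0.0, 0.0))


def _fit_lines(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched least-squares 3D line fits.

    ``points`` has shape (m, k, 3).  Returns (centroids (m, 3), unit
    directions (m, 3), perpendicular residual rms (m,)).
    """
    c = points.mean(axis=1, keepdims=True)
    d = points - c
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    direction = vt[:, 0, :]
    k = points.shape[1]
    along = np.einsum("mkj,mj->mk", d, direction)
    perp = d - along[:, :, None] * direction[:, None, :]
    resid2 = np.sum(perp * perp, axis=(1, 2)) / k
    return c[:, 0, :], direction, np.sqrt(resid2)


def fit_track(points, arm: int = -1, frame: int = -1,
              cluster_ids: tuple[int, ...] = ()) -> SecondaryTrack:
    """Least-squares 3D line through one cluster point per sensor plane.

    Raises if fewer than three points are supplied (no track can be built
    from fewer planes).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 3:
        raise ValueError("fit_track needs >= 3 points of shape (k, 3)")
    c, d, r = _fit_lines(pts[None])
    direction = d[0]
    if direction @ c[0] < 0:  # orient outward from the target region
        direction = -direction
    return SecondaryTrack(arm, frame, c[0], direction, float(r[0]),
                          tuple(cluster_ids))


def build_tracks(clusters: pd.DataFrame, tracker: TrackerGeometry,
                 residual_cut: float = 0.050,
                 max_clusters_per_plane: int = 100,
                 alignment: AlignmentSet | None = None,
                 ) -> list[SecondaryTrack]:
    """Greedy combinatorial track finding.

    Clusters are grouped by (arm, frame); every one-cluster-per-plane triplet
    is fitted and candidates are accepted in order of increasing residual
    rms, each cluster used at most once, discarding candidates above
    ``residual_cut``.  ``cluster_ids`` refer to the input DataFrame index.
    """
    if clusters.empty:
        return []
    df = clusters
    if alignment is not None:
        df = apply_alignment(df, alignment)
    ns = tracker.sensors_per_arm
    arm_v = df["arm"].to_numpy()
    frame_v = df["frame"].to_numpy()
    sensor_v = df["sensor"].to_numpy()
    u_v = df["u_mm"].to_numpy(float)
    v_v = df["v_mm"].to_numpy(float)
    index_v = df.index.to_numpy()

    order = np.lexsort((sensor_v, frame_v, arm_v))
    key = np.stack([arm_v[order], frame_v[order]], axis=1)
    bounds = np.nonzero(np.any(np.diff(key, axis=0) != 0, axis=1))[0] + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [order.size]])

    basis = {a: tracker.basis(a) for a in range(tracker.n_arms)}
    centers = {a: np.stack([tracker.sensor_center(a, k) for k in range(ns)])
               for a in range(tracker.n_arms)}

    # enumerate every one-cluster-per-plane candidate triplet of every
    # (arm, frame) group, then fit them all in one batched call
    combo_rows: list[np.ndarray] = []
    group_meta: list[tuple[int, int, int, int]] = []  # arm, frame, lo, hi
    n_combos = 0
    for g in range(starts.size):
        rows = order[starts[g]:ends[g]]
        arm = int(arm_v[rows[0]])
        frame = int(frame_v[rows[0]])
        per_plane: list[np.ndarray] = []
        complete = True
        for k in range(ns):
            pk = rows[sensor_v[rows] == k]
            if pk.size == 0 or pk.size > max_clusters_per_plane:
                complete = False
                break
            per_plane.append(pk)
        if not complete:
            continue
        if all(p.size == 1 for p in per_plane):
            combos = rows[None, :] if np.array_equal(
                sensor_v[rows], np.arange(ns)) else np.array(
                    [[p[0] for p in per_plane]])
        elif ns == 3:
            # collinearity prefilter: a straight track's middle cluster must
            # sit on the interpolation of the outer two within a few times
            # the residual cut, killing the combinatorial blow-up early
            d0, d1, d2 = (tracker.sensor_distance(k) for k in range(3))
            f = (d1 - d0) / (d2 - d0)
            tol = 6.0 * residual_cut
            p0, p1, p2 = per_plane
            du = np.abs(u_v[p1][None, :, None]
                        - ((1 - f) * u_v[p0][:, None, None]
                           + f * u_v[p2][None, None, :]))
            dv = np.abs(v_v[p1][None, :, None]
                        - ((1 - f) * v_v[p0][:, None, None]
                           + f * v_v[p2][None, None, :]))
            i0, i1, i2 = np.nonzero((du <= tol) & (dv <= tol))
            if i0.size == 0:
                continue
            combos = np.stack([p0[i0], p1[i1], p2[i2]], axis=1)
        else:
            combos = np.array(list(itertools.product(*per_plane)))
        combo_rows.append(combos)
        group_meta.append((arm, frame, n_combos, n_combos + combos.shape[0]))
        n_combos += combos.shape[0]
    if n_combos == 0:
        return []
    combos_all = np.concatenate(combo_rows, axis=0)
    arm_of_combo = np.concatenate(
        [np.full(hi - lo, a) for a, _, lo, hi in group_meta])

    pts = np.empty((n_combos, ns, 3))
    for a in range(tracker.n_arms):
        sel = arm_of_combo == a
        if not np.any(sel):
            continue
        uh, vh, _ = basis[a]
        rows_a = combos_all[sel]
        pts[sel] = (centers[a][None, :, :]
                    + u_v[rows_a][:, :, None] * uh[None, None, :]
                    + v_v[rows_a][:, :, None] * vh[None, None, :])
    cents, dirs, resids = _fit_lines(pts)

    tracks: list[SecondaryTrack] = []
    for arm, frame, lo, hi in group_meta:
        w = basis[arm][2]
        if hi - lo == 1:
            r = float(resids[lo])
            if r > residual_cut:
                continue
            direction = dirs[lo]
            if direction @ w < 0:
                direction = -direction
            tracks.append(SecondaryTrack(
                arm, frame, cents[lo], direction, r,
                tuple(int(index_v[i]) for i in combos_all[lo])))
            continue
        used: set[int] = set()
        for ci in lo + np.argsort(resids[lo:hi], kind="stable"):
            r = float(resids[ci])
            if r > residual_cut:
                break
            ids = tuple(int(i) for i in combos_all[ci])
            if any(i in used for i in ids):
                continue
            used.update(ids)
            direction = dirs[ci]
            if direction @ w < 0:
                direction = -direction
            tracks.append(SecondaryTrack(
                arm, frame, cents[ci], direction, r,
                tuple(int(index_v[i]) for i in ids)))
    return tracks


def tracks_to_frame(tracks: list[SecondaryTrack]) -> pd.DataFrame:
    """Tabular view: ``arm,frame,spot,px,py,pz,dx,dy,dz,residual_mm``."""
    rows = [{
        "arm": t.arm, "frame": t.frame,
        "spot": -1 if t.spot_index is None else t.spot_index,
        "px": t.point[0], "py": t.point[1], "pz": t.point[2],
        "dx": t.direction[0], "dy": t.direction[1], "dz": t.direction[2],
        "residual_mm": t.residual_rms,
    } for t in tracks]
    return pd.DataFrame(rows, columns=["arm", "frame", "spot", "px", "py",
                                       "pz", "dx", "dy", "dz", "residual_mm"])


def apply_alignment(clusters: pd.DataFrame, alignment: AlignmentSet,
                    ) -> pd.DataFrame:
    """Subtract the per-sensor rigid offsets from the cluster coordinates."""
    if not alignment.offsets:
        return clusters
    df = clusters.copy()
    for (arm, sensor), (du, dv) in alignment.offsets.items():
        sel = (df["arm"] == arm) & (df["sensor"] == sensor)
        df.loc[sel, "u_mm"] -= du
        df.loc[sel, "v_mm"] -= dv
    return df


def estimate_alignment(clusters: pd.DataFrame, tracker: TrackerGeometry,
                       min_tracks: int = 100) -> AlignmentSet:
    """Estimate rigid in-plane sensor offsets from a no-target run.

    The gauge is fixed to the outer sensors of each arm: for every frame with
    exactly one cluster per plane, the middle-sensor position predicted by
    the line through the outer clusters is compared to the measured one; the
    mean (measured - predicted) over tracks is that sensor's offset.
    Only middle sensors receive non-zero estimates.
    """
    ns = tracker.sensors_per_arm
    offsets: dict[tuple[int, int], tuple[float, float]] = {}
    n_used_total = 0
    for arm, arm_df in clusters.groupby("arm"):
        uh, vh, w = tracker.basis(int(arm))
        d = np.array([tracker.sensor_distance(k) for k in range(ns)])
        by_frame = arm_df.groupby("frame")
        du_acc = {k: [] for k in range(1, ns - 1)}
        dv_acc = {k: [] for k in range(1, ns - 1)}
        for _, g in by_frame:
            if len(g) != ns or set(g["sensor"]) != set(range(ns)):
                continue
            g = g.sort_values("sensor")
            u = g["u_mm"].to_numpy(float)
            v = g["v_mm"].to_numpy(float)
            for k in range(1, ns - 1):
                f = (d[k] - d[0]) / (d[-1] - d[0])
                du_acc[k].append(u[k] - (u[0] + f * (u[-1] - u[0])))
                dv_acc[k].append(v[k] - (v[0] + f * (v[-1] - v[0])))
        for k in range(1, ns - 1):
            if du_acc[k]:
                n_used_total += len(du_acc[k])
                offsets[(int(arm), k)] = (float(np.mean(du_acc[k])),
                                          float(np.mean(dv_acc[k])))
        for k in (0, ns - 1):
            offsets[(int(arm), k)] = (0.0, 0.0)
    if n_used_total < min_tracks:
        raise ValueError(
            f"insufficient alignment tracks: {n_used_total} < {min_tracks}")
    return AlignmentSet(offsets=offsets, provenance="estimated")


def associate_frames_to_spots(timeline: list[tuple[int, float, float]],
                              frames, frame_time: float,
                              ) -> dict[int, int | None]:
    """Map readout frames to beam spots by the frame-midpoint rule.

    Each frame maps to the spot whose delivery interval contains the frame's
    midpoint time; frames outside every interval map to None.  Overlapping
    spot intervals raise.
    """
    tl = sorted(timeline, key=lambda x: x[1])
    for (_, a0, a1), (_, b0, b1) in zip(tl[:-1], tl[1:]):
        if b0 < a1 - 1e-12:
            raise ValueError("overlapping spot intervals")
    starts = np.array([t[1] for t in tl])
    ends = np.array([t[2] for t in tl])
    idxs = np.array([t[0] for t in tl])
    frames = np.asarray(list(frames), dtype=np.int64)
    mid = (frames + 0.5) * frame_time
    pos = np.searchsorted(starts, mid, side="right") - 1
    out: dict[int, int | None] = {}
    for f, m, p in zip(frames, mid, pos):
        if p >= 0 and starts[p] <= m <= ends[p]:
            out[int(f)] = int(idxs[p])
        else:
            out[int(f)] = None
    return out
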