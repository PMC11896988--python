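"""4D-monitoring decision layer.

Per-spot computed-vertex-z differences of the moving case against the two
static references (``difference_in``/``difference_out``) are compared to a
repeat-variability threshold (2x the RMS of the static_in-vs-static_out
differences across repeated runs).  From the comparisons follow the
delivered-as-planned classification (with efficiency scored against the
motor-logfile truth), and the per-spot motion-phase call:

===============  ==============  =========
difference_in    difference_out  call
===============  ==============  =========
<= thr           >  thr          Phase 1
>  thr           >  thr          Phase 2
>  thr           <= thr          Phase 3
<= thr           <= thr          undefined
===============  ==============  =========

Thresholds treat boundary equality as "below".  Differences are thresholded
in absolute value; signed values are preserved in the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plan import BeamSpot

__all__ = [
    "UNDEFINED",
    "PHASE1",
    "PHASE2",
    "PHASE3",
    "DiffRecord",
    "thr_from_repeats",
    "classify_delivery",
    "select_edge_spots",
    "total_efficiency",
    "assign_phase",
    "phase_confusion",
]

UNDEFINED, PHASE1, PHASE2, PHASE3 = 0, 1, 2, 3
PHASE_LABELS = {UNDEFINED: "undefined", PHASE1: "phase1", PHASE2: "phase2",
                PHASE3: "phase3"}


@dataclass(frozen=True)
class DiffRecord:
    """Per-spot differences of the moving case against the static references."""

    spot_index: int
    difference_in: float      # |v_z(moving) - v_z(static_in)|
    difference_out: float
    signed_in: float
    signed_out: float
    thr_diff: float
    uncertainty: float        # quadrature-summed repeat RMS


def thr_from_repeats(vz_in: np.ndarray, vz_out: np.ndarray,
                     ) -> tuple[float, np.ndarray]:
    """Threshold from repeat variability of the static comparison.

    ``vz_in``/``vz_out`` are (n_repeats, n_spots) computed-vertex-z arrays
    (NaN marks spots invalid in a repeat).  For each spot the per-repeat
    in-out differences are taken; the RMS of their scatter about the per-spot
    mean quantifies repeat variability.  Returns ``(thr_pooled,
    thr_per_spot)``, each 2 x RMS.
    """
    vz_in = np.asarray(vz_in, dtype=float)
    vz_out = np.asarray(vz_out, dtype=float)
    if vz_in.ndim != 2 or vz_in.shape != vz_out.shape:
        raise ValueError("need matching (n_repeats, n_spots) arrays")
    if vz_in.shape[0] < 2:
        raise ValueError("need >= 2 repeats per case")
    d = vz_in - vz_out
    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN spots
        mean_s = np.nanmean(d, axis=0)
        dev = d - mean_s[None, :]
        rms_spot = np.sqrt(np.nanmean(dev ** 2, axis=0))
        rms_pooled = np.sqrt(np.nanmean(dev ** 2))
    return 2.0 * float(rms_pooled), 2.0 * rms_spot


def classify_delivery(difference_in, thr_diff):
    """True for delivered as planned (|difference_in| <= thr_diff)."""
    d = np.abs(np.asarray(difference_in, dtype=float))
    out = d <= thr_diff
    return bool(out) if out.ndim == 0 else out


def select_edge_spots(plan: list[BeamSpot], sphere_center=(0.0, 0.0, 0.0),
                      sphere_radius: float = 25.0,
                      slice_thickness: float = 6.0,
                      x_min: float = 5.0, y_max: float = 0.0) -> list[int]:
    """Spots probing the spherical edge: planned position in the shell of
    ``slice_thickness`` inside the sphere surface, with x_v > x_min and
    y_v < y_max."""
    cx, cy, cz = sphere_center
    out = []
    for s in plan:
        r = np.sqrt((s.x_v - cx) ** 2 + (s.y_v - cy) ** 2 + (s.z_v - cz) ** 2)
        if (s.x_v > x_min and s.y_v < y_max
                and sphere_radius - slice_thickness <= r <= sphere_radius):
            out.append(s.spot_index)
    return out


def total_efficiency(planned_calls, motor_positions, pos_m: float) -> float:
    """Percentage of spots whose planned/not-planned call matches the truth.

    Truth category: a spot is expected delivered-as-planned when the motor
    position magnitude at its delivery time is below ``pos_m``.
    """
    calls = np.asarray(planned_calls, dtype=bool)
    pos = np.abs(np.asarray(motor_positions, dtype=float))
    if calls.shape != pos.shape:
        raise ValueError("calls and truth must align")
    if calls.size == 0:
        raise ValueError("empty category: efficiency undefined")
    expected = pos < pos_m
    return 100.0 * float(np.mean(calls == expected))


def assign_phase(difference_in, difference_out, thr_diff):
    """Motion-phase call from the two static-reference differences."""
    din = np.abs(np.asarray(difference_in, dtype=float))
    dout = np.abs(np.asarray(difference_out, dtype=float))
    below_in = din <= thr_diff
    below_out = dout <= thr_diff
    call = np.full(din.shape, PHASE2, dtype=int)
    call[below_in & ~below_out] = PHASE1
    call[~below_in & below_out] = PHASE3
    call[below_in & below_out] = UNDEFINED
    return int(call) if call.ndim == 0 else call


def phase_confusion(calls, truth_phases, exclude=None) -> pd.DataFrame:
    """Row-normalised confusion matrix (%) of phase calls vs motor truth.

    Rows are the true phases 1..3, columns the calls
    (undefined, 1, 2, 3); ``exclude`` flags spots (e.g. planned overshoot)
    removed before normalisation.  Rows with no spots are NaN.
    """
    calls = np.asarray(calls, dtype=int)
    truth = np.asarray(truth_phases, dtype=int)
    if calls.shape != truth.shape:
        raise ValueError("calls and truth must align")
    keep = np.ones(calls.shape, dtype=bool)
    if exclude is not None:
        keep &= ~np.asarray(exclude, dtype=bool)
    mat = np.full((3, 4), np.nan)
    for i, tp in enumerate((PHASE1, PHASE2, PHASE3)):
        sel = keep & (truth == tp)
        n = int(sel.sum())
        if n == 0:
            continue
        for j, cp in enumerate((UNDEFINED, PHASE1, PHASE2, PHASE3)):
            mat[i, j] = 100.0 * float(np.sum(calls[sel] == cp)) / n
    return pd.DataFrame(mat,
                        index=["phase1", "phase2", "phase3"],
                        columns=["undefined", "phase1", "phase2", "phase3"])
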