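"""Lujan-type 1D respiratory motion, phase binning, and motor logfiles.

The motion trace is x(t) = A * sin^(2n)(pi (t - t0) / tau): it starts at the
in-position (0 mm) on the trigger, peaks at the amplitude at half period, and
is tau-periodic.  Positions are binned into three motion phases by amplitude
intervals (defaults [0, 3), [3, 17), [17, 20] mm, half-open with the top edge
closed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LujanParams",
    "PhaseBins",
    "MotorLog",
    "position",
    "phase_of",
    "phase_time_fractions",
    "phase_time_fractions_exact",
    "generate_motor_log",
    "write_motor_log",
    "read_motor_log",
]


@dataclass(frozen=True)
class LujanParams:
    """Amplitude (mm), period (s), half-exponent n (power is 2n), trigger."""

    amplitude: float = 20.0
    period: float = 3.0
    n: int = 2
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("n must be a positive integer")


@dataclass(frozen=True)
class PhaseBins:
    """Strictly increasing amplitude edges [0, a, b, A] defining Phase 1/2/3."""

    edges: tuple[float, ...] = (0.0, 3.0, 17.0, 20.0)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or e[0] != 0.0:
            raise ValueError("edges must start at 0")
        if any(b <= a for a, b in zip(e[:-1], e[1:])):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_phases(self) -> int:
        return len(self.edges) - 1


def position(t, params: LujanParams):
    """Motor position (mm) at time(s) ``t`` (s).  Raises for t < trigger."""
    t = np.asarray(t, dtype=float)
    if np.any(t < params.start_time - 1e-12):
        raise ValueError("motion not yet triggered (t < start_time)")
    s = np.sin(np.pi * (t - params.start_time) / params.period)
    out = params.amplitude * s ** (2 * params.n)
    return float(out) if out.ndim == 0 else out


def phase_of(x, bins: PhaseBins = PhaseBins()):
    """Phase index (1-based) of position(s) ``x`` mm; half-open bins, the top
    edge closed; values outside [0, A] are clamped."""
    x = np.asarray(x, dtype=float)
    e = np.asarray(bins.edges)
    xc = np.clip(x, e[0], e[-1])
    idx = np.searchsorted(e[1:-1], xc, side="right") + 1
    return int(idx) if idx.ndim == 0 else idx


def phase_time_fractions(params: LujanParams, bins: PhaseBins = PhaseBins(),
                         n_samples: int = 100_000, seed: int | None = 0,
                         n_periods: int = 100) -> tuple[float, ...]:
    """Monte-Carlo time-occupancy fraction of each phase: sample times
    uniformly over ``n_periods`` periods and bin the positions."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    t = params.start_time + rng.uniform(0.0, n_periods * params.period, n_samples)
    ph = phase_of(position(t, params), bins)
    counts = np.bincount(ph, minlength=bins.n_phases + 1)[1:]
    return tuple(counts / n_samples)


def phase_time_fractions_exact(params: LujanParams,
                               bins: PhaseBins = PhaseBins()) -> tuple[float, ...]:
    """Closed-form time-occupancy fractions of A sin^(2n): the fraction of a
    quarter period with position below x is (2/pi) arcsin((x/A)^(1/2n))."""
    a = params.amplitude

    def cdf(x: float) -> float:
        if a == 0:
            return 1.0 if x > 0 else 0.0
        u = min(max(x / a, 0.0), 1.0)
        return 2.0 / np.pi * np.arcsin(u ** (1.0 / (2 * params.n)))

    e = bins.edges
    fracs = []
    for lo, hi in zip(e[:-1], e[1:]):
        f = cdf(hi) - cdf(lo)
        fracs.append(f)
    # closed top edge: position == A occupies zero measure, and A == 0 sits
    # entirely in the first bin
    if a == 0:
        fracs = [1.0] + [0.0] * (len(fracs) - 1)
    return tuple(fracs)


@dataclass
class MotorLog:
    """Time/position samples of the motorized table."""

    times: np.ndarray
    positions: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.shape != self.positions.shape:
            raise ValueError("times and positions must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def interp(self, t):
        """Linear interpolation of position at time(s) t."""
        return np.interp(t, self.times, self.positions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.times, "position_mm": self.positions})

    def __eq__(self, other: object) -> bool:  # round-trip identity checks
        if not isinstance(other, MotorLog):
            return NotImplemented
        return (np.array_equal(self.times, other.times)
                and np.array_equal(self.positions, other.positions))


def generate_motor_log(params: LujanParams, duration: float, dt: float = 1e-4,
                       drift_um: float = 0.0, seed: int | None = None,
                       ) -> MotorLog:
    """Sample the motion model at interval ``dt`` over ``duration`` seconds.

    A linear drift ramping from 0 to ``drift_um`` micrometres over the run is
    added to the model positions (sign drawn from ``seed`` when given).
    Values are rounded to the 6-decimal file precision so that a write/read
    round trip is the identity.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = int(np.floor(duration / dt)) + 1
    t = params.start_time + dt * np.arange(n)
    x = position(t, params)
    if drift_um != 0.0:
        sign = 1.0
        if seed is not None:
            sign = 1.0 if np.random.default_rng(seed).random() < 0.5 else -1.0
        ramp = (t - t[0]) / (t[-1] - t[0]) if n > 1 else np.zeros(n)
        x = x + sign * (drift_um * 1e-3) * ramp
    return MotorLog(np.round(t, 6), np.round(x, 6), params.start_time)


def write_motor_log(log: MotorLog, path) -> None:
    """CSV with header ``time_s,position_mm`` and fixed 6-decimal fields."""
    with open(path, "w") as fh:
        fh.write("time_s,position_mm\n")
        for t, x in zip(log.times, log.positions):
            fh.write(f"{t:.6f},{x:.6f}\n")


def read_motor_log(path) -> MotorLog:
    """Parse a motor logfile; malformed rows raise with the line number."""
    times: list[float] = []
    positions: list[float] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "time_s,position_mm":
            raise ValueError(f"{path}: line 1: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 fields")
            try:
                times.append(float(parts[0]))
                positions.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return MotorLog(np.array(times), np.array(positions),
                    times[0] if times else 0.0)
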