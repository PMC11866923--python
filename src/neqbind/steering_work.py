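"""Steering schedules, restraints and Jarzynski-work accumulation.

Steered dynamics add a time-dependent harmonic restraint to the system
Hamiltonian,

    R(x, t) = (k/2)·(S(x) − Ŝ(t))²,

where Ŝ(t) moves at constant speed from the initial to the final value of
the progress coordinate, plus a one-sided ("flat-bottom") harmonic wall on
the orthogonal coordinate Z that confines the system near the reference
path. The Jarzynski work is the path integral of the explicit time
derivative of the Hamiltonian,

    W(t) = ∫₀ᵗ ∂H/∂t' dt' = ∫₀ᵗ −k·(S − Ŝ(t'))·Ŝ'(t') dt',

so only the moving restraint contributes; the wall is time-independent
and does no work in this sense.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid


class SteeringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteeringSchedule:
    """Constant-speed schedule Ŝ(t) = s_start + v·t over [0, duration]."""

    s_start: float
    s_end: float
    duration: float  # ps

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise SteeringError("duration must be positive")
        # s_end == s_start (zero speed) is allowed: a static restraint does
        # no work, which is itself a useful identity check

    @property
    def speed(self) -> float:
        return (self.s_end - self.s_start) / self.duration

    @property
    def is_forward(self) -> bool:
        return self.s_end > self.s_start

    def reversed(self) -> "SteeringSchedule":
        return SteeringSchedule(self.s_end, self.s_start, self.duration)


@dataclass(frozen=True)
class RestraintParams:
    """Spring on S and flat-bottom upper wall on Z.

    k_spring in kJ/mol per (progress unit)²; z_wall_at in nm²; k_wall in
    kJ/mol/nm⁴. ``k_wall=0`` disables the wall.
    """

    k_spring: float
    z_wall_at: float = 0.05
    k_wall: float = 0.0

    def __post_init__(self) -> None:
        if not self.k_spring > 0:
            raise SteeringError("k_spring must be positive")
        if self.z_wall_at < 0 or self.k_wall < 0:
            raise SteeringError("wall parameters must be non-negative")


@dataclass
class TrajectoryRecord:
    """Time series logged along one steered trajectory."""

    times: np.ndarray        # ps, strictly increasing, starting at 0
    s_values: np.ndarray
    z_values: np.ndarray     # nm²
    schedule_values: np.ndarray  # Ŝ(t)
    cumulative_work: np.ndarray  # kJ/mol, W[0] = 0
    direction: str           # "forward" | "backward"

    def __post_init__(self) -> None:
        arrays = [self.times, self.s_values, self.z_values,
                  self.schedule_values, self.cumulative_work]
        n = len(self.times)
        if any(len(a) != n for a in arrays):
            raise SteeringError("trajectory arrays must share one length")
        if np.any(np.diff(self.times) <= 0):
            raise SteeringError("times must be strictly increasing")
        if abs(self.cumulative_work[0]) > 1e-12:
            raise SteeringError("cumulative_work must start at 0")
        if self.direction not in ("forward", "backward"):
            raise SteeringError("direction must be 'forward' or 'backward'")

    @property
    def final_work(self) -> float:
        return float(self.cumulative_work[-1])


# ---------------------------------------------------------------------------
# Energies
# ---------------------------------------------------------------------------

def schedule_value(sch: SteeringSchedule, t: float | np.ndarray) -> float | np.ndarray:
    """Restraint centre Ŝ(t); defined only on [0, duration]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -1e-12) or np.any(t_arr > sch.duration * (1 + 1e-12)):
        raise SteeringError(f"t outside [0, {sch.duration}]")
    out = sch.s_start + sch.speed * t_arr
    return float(out) if np.isscalar(t) else out


def restraint_energy(s: float, s_center: float, k_spring: float) -> float:
    """Harmonic steering energy (k/2)(S − Ŝ)², kJ/mol."""
    return 0.5 * k_spring * (s - s_center) ** 2


def wall_energy(z: float | np.ndarray, params: RestraintParams) -> float | np.ndarray:
    """Flat-bottom upper wall on Z: zero below the threshold, harmonic above.

    Continuous with continuous first derivative at ``z_wall_at``.
    """
    excess = np.maximum(np.asarray(z, dtype=float) - params.z_wall_at, 0.0)
    out = 0.5 * params.k_wall * excess**2
    return float(out) if np.isscalar(z) else out


# ---------------------------------------------------------------------------
# Work accumulation and segmentation
# ---------------------------------------------------------------------------

def accumulate_work(
    s_series: np.ndarray,
    sch: SteeringSchedule,
    k_spring: float,
    dt: float,
) -> np.ndarray:
    """Cumulative Jarzynski work W(t) along a logged S(x) series.

    ``s_series`` must be sampled on the uniform schedule grid
    t = 0, dt, ..., duration. Trapezoidal quadrature of the integrand
    −k·(S − Ŝ(t))·v; W(0) = 0.

    Works for a 2-D input of shape (n_replicas, n_times) as well, in
    which case the result has the same shape.
    """
    s = np.atleast_2d(np.asarray(s_series, dtype=float))
    n = s.shape[-1]
    expected = int(round(sch.duration / dt)) + 1
    if n != expected:
        raise SteeringError(
            f"s_series length {n} does not match schedule grid ({expected})"
        )
    t = np.arange(n) * dt
    centers = sch.s_start + sch.speed * t
    integrand = -k_spring * (s - centers[None, :]) * sch.speed
    w = cumulative_trapezoid(integrand, dx=dt, axis=-1, initial=0.0)
    return w[0] if np.asarray(s_series).ndim == 1 else w


def segment_work(
    traj: TrajectoryRecord, node_s_values: np.ndarray
) -> np.ndarray:
    """Work increments over the intervals of a node grid on S.

    The trajectory is chunked at the times when the *schedule* Ŝ(t)
    crosses each node value (not when the fluctuating S(x) does, which
    would double-count back-and-forth recrossings). Cumulative work is
    linearly interpolated at the crossing times and differenced.

    For a backward trajectory the grid is traversed in reverse; the
    returned increments are ordered along the traversal, so they always
    telescope to W(t_last) − W(t_first).
    """
    nodes = np.asarray(node_s_values, dtype=float)
    if nodes.ndim != 1 or nodes.size < 2:
        raise SteeringError("need an ordered grid of >= 2 node values")
    if np.any(np.diff(nodes) <= 0) and np.any(np.diff(nodes) >= 0):
        raise SteeringError("node grid must be strictly monotone")
    sch_vals = traj.schedule_values
    v = (sch_vals[-1] - sch_vals[0]) / (traj.times[-1] - traj.times[0])
    if v == 0:
        raise SteeringError("schedule is not monotone (zero net speed)")
    traversal = nodes if (v > 0) == (nodes[1] > nodes[0]) else nodes[::-1]
    lo, hi = min(sch_vals[0], sch_vals[-1]), max(sch_vals[0], sch_vals[-1])
    eps = 1e-9 * max(1.0, abs(hi - lo))
    if traversal.min() < lo - eps or traversal.max() > hi + eps:
        raise SteeringError("node grid extends outside the schedule range")
    t_cross = traj.times[0] + (traversal - sch_vals[0]) / v
    w_at = np.interp(t_cross, traj.times, traj.cumulative_work)
    return np.diff(w_at)
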