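"""Dissipated-work diagnostics and steering quality control.

The dissipated work W_diss = ⟨W⟩ − ΔF (forward; ⟨W⟩ + ΔF backward, with
ΔF always the A→B free-energy difference) measures how far a pulling
protocol is from reversibility. It is non-negative in expectation (second
law) and is the single quantity that governs how many replicas the
estimators need: convergence deteriorates exponentially with dissipation.
By default W_diss is referenced to the converged Crooks estimate.

Diagnostics provided:

* dissipation accumulated along the pull (per node of the segment grid);
* dissipation as a function of total pull duration, with finite-difference
  derivatives — slower pulls must dissipate less, and the derivative
  indicates how much slower is still worth simulating;
* a stiff-spring tracking check flagging replicas whose S(x) lags the
  moving restraint centre for too long (e.g. a ligand trapped off-path),
  which invalidates the interpretation of the schedule as the reaction
  progress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import PMFProfile, WorkSet
from .steering_work import TrajectoryRecord


class DissipationError(ValueError):
    pass


@dataclass
class StiffSpringCheck:
    """Tracking summary for one steered replica."""

    flagged: bool
    max_lag: float
    max_lag_s: float          # schedule position where the worst lag occurred
    fraction_exceeding: float
    lag_tol: float
    fraction_tol: float
    exceeded_s_range: tuple[float, float] | None  # schedule span where lag > tol

    def to_dict(self) -> dict:
        return {
            "flagged": self.flagged,
            "max_lag": self.max_lag,
            "max_lag_s": self.max_lag_s,
            "fraction_exceeding": self.fraction_exceeding,
            "lag_tol": self.lag_tol,
            "fraction_tol": self.fraction_tol,
            "exceeded_s_range": self.exceeded_s_range,
        }


@dataclass
class DissipationVsTime:
    durations: np.ndarray
    w_diss: np.ndarray
    derivative: np.ndarray     # dW_diss/d(duration), finite differences
    monotonicity_violations: list[int]  # indices where W_diss increased


@dataclass
class DissipationReport:
    w_diss_forward: float
    w_diss_backward: float
    profile_forward: np.ndarray | None = None
    profile_backward: np.ndarray | None = None
    node_s: np.ndarray | None = None
    vs_time: DissipationVsTime | None = None
    stiff_spring: list[StiffSpringCheck] = field(default_factory=list)


# ---------------------------------------------------------------------------

def dissipated_work(
    works: np.ndarray, delta_f_ref: float, direction: str = "forward"
) -> float:
    """⟨W⟩ − ΔF_ref (forward) or ⟨W⟩ + ΔF_ref (backward), kJ/mol.

    ``delta_f_ref`` is the A→B free-energy difference in both cases; the
    backward pull B→A works against −ΔF.
    """
    w = np.asarray(works, dtype=float)
    if w.size == 0:
        raise DissipationError("no work samples")
    if direction == "forward":
        return float(w.mean() - delta_f_ref)
    if direction == "backward":
        return float(w.mean() + delta_f_ref)
    raise DissipationError("direction must be 'forward' or 'backward'")


def dissipation_profile(
    ws: WorkSet, pmf: PMFProfile, direction: str = "forward"
) -> np.ndarray:
    """Dissipation accumulated up to each node of the segment grid.

    Cumulative mean segment work minus the free-energy change covered so
    far, along the pull's own traversal direction. Starts at 0; the final
    value equals :func:`dissipated_work` of the whole-run works against
    the profile's endpoint ΔF.
    """
    if ws.forward_segments is None or ws.backward_segments is None:
        raise DissipationError("segment matrices required")
    f = pmf.f_values
    if direction == "forward":
        cum_w = np.concatenate([[0.0], np.cumsum(ws.forward_segments.mean(axis=0))])
        return cum_w - (f - f[0])
    if direction == "backward":
        cum_w = np.concatenate([[0.0], np.cumsum(ws.backward_segments.mean(axis=0))])
        f_rev = f[::-1]
        return cum_w - (f_rev - f_rev[0])
    raise DissipationError("direction must be 'forward' or 'backward'")


def dissipation_vs_time(
    sets: dict[float, WorkSet],
    delta_f_ref: float,
    direction: str = "forward",
) -> DissipationVsTime:
    """W_diss per pull duration plus finite-difference derivatives.

    Central differences on the interior points and one-sided at the ends
    (durations need not be uniformly spaced). Violations of the expected
    monotone decrease are flagged in the result, never hidden.
    """
    if len(sets) < 2:
        raise DissipationError("need WorkSets for at least 2 durations")
    durations = np.array(sorted(sets))
    if np.any(durations <= 0):
        raise DissipationError("durations must be positive")
    works = [
        sets[d].forward_works if direction == "forward" else sets[d].backward_works
        for d in durations
    ]
    w_diss = np.array(
        [dissipated_work(w, delta_f_ref, direction) for w in works]
    )
    deriv = np.gradient(w_diss, durations)
    violations = [int(i) for i in np.nonzero(np.diff(w_diss) > 0)[0] + 1]
    return DissipationVsTime(
        durations=durations,
        w_diss=w_diss,
        derivative=deriv,
        monotonicity_violations=violations,
    )


def stiff_spring_check(
    traj: TrajectoryRecord, lag_tol: float = 0.1, fraction_tol: float = 0.2
) -> StiffSpringCheck:
    """Flag a replica whose S(x) fails to track the moving restraint.

    The replica is flagged when |S(t) − Ŝ(t)| exceeds ``lag_tol`` for more
    than ``fraction_tol`` of the pull. Reports the worst lag, the schedule
    position where it occurred, and the schedule span over which the lag
    stayed above tolerance — a persistent excursion localises where the
    system is trapped off the reference path.
    """
    if lag_tol <= 0 or not 0 < fraction_tol <= 1:
        raise DissipationError("lag_tol > 0 and 0 < fraction_tol <= 1 required")
    lag = np.abs(traj.s_values - traj.schedule_values)
    exceeding = lag > lag_tol
    fraction = float(np.mean(exceeding))
    i_max = int(np.argmax(lag))
    exceeded_range = None
    if np.any(exceeding):
        s_exc = traj.schedule_values[exceeding]
        exceeded_range = (float(s_exc.min()), float(s_exc.max()))
    return StiffSpringCheck(
        flagged=fraction > fraction_tol,
        max_lag=float(lag[i_max]),
        max_lag_s=float(traj.schedule_values[i_max]),
        fraction_exceeding=fraction,
        lag_tol=lag_tol,
        fraction_tol=fraction_tol,
        exceeded_s_range=exceeded_range,
    )
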