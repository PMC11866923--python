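"""Standard-state binding free energy from a PMF along the path progress.

The binding free energy splits into a partition-ratio term and a
standard-state volume correction,

    ΔF° = ΔF_b + ΔF_v,
    ΔF_b = −k_B·T·ln(Q_site / Q_bulk),   Q = ∫ e^(−βF(S)) dS,
    ΔF_v = −k_B·T·ln(V_bulk / V°),       V° = 1661 Å³ (1 M),

where the Q integrals run over the bound-site region [S₀, S_cut] and the
bulk region [S_cut, S_end] of the profile. The cut separating site from
bulk is taken where the PMF flattens (the ligand no longer feels the
protein); :func:`suggest_cut_index` locates that plateau but the choice
should be confirmed by trajectory inspection. V_bulk, the unbound volume
effectively sampled in the simulations, is an input here (in production
it comes from a molecular-surface computation); the sign convention makes
binding more favourable when the sampled bulk volume exceeds V°.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import PMFProfile
from .toysim import ThermoState
from .units import KJ_PER_KCAL, V_STANDARD_A3, kt

logger = logging.getLogger(__name__)


class BindingError(ValueError):
    pass


class PlateauNotFoundError(BindingError):
    """No flat region found in the PMF tail."""


@dataclass(frozen=True)
class BindingResult:
    """ΔF° decomposition with bootstrap CI. Energies in kJ/mol."""

    delta_f_b: float
    delta_f_v: float
    delta_f_standard: float
    cut_index: int
    v_bulk: float  # Å³
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_boot: int = 0

    def __post_init__(self) -> None:
        if abs(self.delta_f_standard - (self.delta_f_b + self.delta_f_v)) > 1e-9:
            raise BindingError("delta_f_standard must equal delta_f_b + delta_f_v")

    @property
    def delta_f_standard_kcal(self) -> float:
        return self.delta_f_standard / KJ_PER_KCAL

    def to_dict(self) -> dict:
        return {
            "delta_f_b": self.delta_f_b,
            "delta_f_v": self.delta_f_v,
            "delta_f_standard": self.delta_f_standard,
            "delta_f_standard_kcal": self.delta_f_standard_kcal,
            "units": "kJ/mol",
            "cut_index": self.cut_index,
            "v_bulk_A3": self.v_bulk,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_boot": self.n_boot,
        }


def partition_ratio_delta_f(pmf: PMFProfile, cut_index: int, beta: float) -> float:
    """ΔF_b = −(1/β)·ln(Q_site/Q_bulk) by trapezoid quadrature on the grid.

    Invariant under adding a constant to the whole profile (the constant
    cancels in the ratio).
    """
    n = pmf.node_s.size
    if not 0 < cut_index < n - 1:
        raise BindingError(f"cut_index must be interior to (0, {n - 1})")
    if not np.all(np.isfinite(pmf.f_values)):
        raise BindingError("PMF contains non-finite values")
    # shift by the minimum before exponentiating; cancels in the ratio
    f = pmf.f_values - pmf.f_values.min()
    w = np.exp(-beta * f)
    q_site = np.trapezoid(w[: cut_index + 1], pmf.node_s[: cut_index + 1])
    q_bulk = np.trapezoid(w[cut_index:], pmf.node_s[cut_index:])
    if q_site <= 0 or q_bulk <= 0:
        raise BindingError("empty region on one side of the cut")
    return float(-np.log(q_site / q_bulk) / beta)


def volume_correction(
    v_bulk: float, temperature: float, v_standard: float = V_STANDARD_A3
) -> float:
    """ΔF_v = −k_B·T·ln(V_bulk/V°) in kJ/mol; strictly decreasing in V_bulk."""
    if v_bulk <= 0:
        raise BindingError("v_bulk must be positive")
    return float(-kt(temperature) * np.log(v_bulk / v_standard))


def standard_binding_free_energy(
    pmf: PMFProfile,
    cut_index: int,
    v_bulk: float,
    thermo: ThermoState,
    n_boot: int = 500,
    seed: int | None = 0,
) -> BindingResult:
    """ΔF° = ΔF_b + ΔF_v with CI propagated from the PMF uncertainty.

    The profile's pointwise stderr is propagated through the partition
    ratio by Gaussian perturbation of the node values (node errors taken
    as independent — a simplification; segment correlations would
    require the full bootstrap profiles). The volume term is exact.
    """
    beta = thermo.beta
    df_b = partition_ratio_delta_f(pmf, cut_index, beta)
    df_v = volume_correction(v_bulk, thermo.temperature)
    ci_low = ci_high = float("nan")
    used_boot = 0
    if n_boot and pmf.stderr is not None and np.any(pmf.stderr > 0):
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
        draws = np.empty(n_boot)
        for b in range(n_boot):
            perturbed = PMFProfile(
                node_s=pmf.node_s,
                f_values=np.concatenate(
                    [[0.0], pmf.f_values[1:] + rng.normal(0, pmf.stderr[1:])]
                ),
                estimator=pmf.estimator,
            )
            draws[b] = partition_ratio_delta_f(perturbed, cut_index, beta) + df_v
        ci_low, ci_high = (float(x) for x in np.percentile(draws, [2.5, 97.5]))
        used_boot = n_boot
    return BindingResult(
        delta_f_b=df_b,
        delta_f_v=df_v,
        delta_f_standard=df_b + df_v,
        cut_index=int(cut_index),
        v_bulk=float(v_bulk),
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=used_boot,
    )


def suggest_cut_index(
    pmf: PMFProfile, window: int = 4, slope_tol: float = 1.0
) -> int:
    """Smallest index after the global minimum where the PMF plateaus.

    A sliding-window least-squares slope is computed from each candidate
    index; the suggestion is the earliest index from which *every* window
    through to the end of the profile is flat, |slope| below
    ``slope_tol`` times the noise-slope scale (mean pointwise stderr over
    the window span; absolute kJ/mol per S unit when the profile carries
    no errors).

    This is a suggestion only — confirm by inspecting the trajectories
    around the proposed cut. Raises :class:`PlateauNotFoundError` rather
    than silently defaulting.
    """
    if window < 2:
        raise BindingError("window must be >= 2 nodes")
    s, f = pmf.node_s, pmf.f_values
    n = s.size
    if n < window + 1:
        raise BindingError("profile too short for the requested window")
    start = int(np.argmin(f))

    def window_flat(i: int) -> bool:
        j = min(i + window, n)
        if j - i < 2:
            return True
        slope = np.polyfit(s[i:j], f[i:j], 1)[0]
        span = s[j - 1] - s[i]
        if pmf.stderr is not None and np.any(pmf.stderr[i:j] > 0):
            scale = float(np.mean(pmf.stderr[i:j])) / span
        else:
            scale = 1.0  # absolute tolerance, kJ/mol per S unit
        return abs(slope) < slope_tol * scale

    for i in range(start, n - 1):
        if i + window > n:
            break
        if all(window_flat(j) for j in range(i, n - window + 1)):
            if not 0 < i < n - 1:
                continue
            logger.info(
                "cut index %d is a suggestion — confirm by trajectory "
                "inspection around S = %.3f", i, s[i],
            )
            return i
    raise PlateauNotFoundError(
        "no plateau found in the PMF tail; the profile may not reach the "
        "unbound state — extend the path or pick the cut manually"
    )


def slab_volume(lx: float, ly: float, lz: float) -> float:
    """Rectangular-slab estimate of V_bulk (Å³) for toy geometries."""
    if min(lx, ly, lz) <= 0:
        raise BindingError("slab dimensions must be positive")
    return float(lx * ly * lz)
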