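"""Nonequilibrium free-energy estimators and PMF reconstruction.

Two estimators consume the Jarzynski work samples:

* **Jarzynski** (unidirectional): ΔF = −(1/β)·ln⟨e^(−βW)⟩, an exponential
  average dominated by rarely sampled low-work tails; implemented with
  exponent shifting so |βW| of several hundred does not overflow.
* **Crooks / Bennett** (bidirectional): the Crooks fluctuation theorem
  places ΔF at the intersection of the forward work density P_f(W) and the
  reflected backward density P_b(−W). The estimate is computed as the
  Bennett acceptance-ratio (BAR) self-consistent solution

      Σᵢ 1/(1 + exp(M + β(W_i^f − ΔF))) =
      Σⱼ 1/(1 + exp(−M + β(W_j^b + ΔF))),   M = ln(n_f/n_b),

  with backward works W^b stored as the work measured along the B→A pull.
  For equal-variance Gaussian work densities this reduces to the
  intersection point (⟨W_f⟩ − ⟨W_b⟩)/2.

The PMF along the progress coordinate is reconstructed segment-wise: the
work accumulated over each inter-node interval [Sᵢ, Sᵢ₊₁] forms its own
forward/backward sample pair, each solved independently and summed,
F(Sᵢ₊₁) = F(Sᵢ) + ΔFᵢ with F(S₀) = 0. Errors come from bootstrap
resampling of replicas (500 resamples by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logsumexp

from .toysim import ThermoState


class EstimatorError(ValueError):
    pass


class OverlapError(EstimatorError):
    """Forward and backward work distributions do not overlap."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class WorkSet:
    """Forward/backward Jarzynski work samples, whole-run and per-segment.

    ``backward_works`` are the works measured along the B→A pull (not
    negated). Segment matrices are (replica × segment); backward segment
    columns are ordered along the B→A traversal, i.e. column j covers the
    interval between forward-grid nodes (n−1−j, n−2−j).
    """

    forward_works: np.ndarray
    backward_works: np.ndarray
    forward_segments: np.ndarray | None = None
    backward_segments: np.ndarray | None = None
    node_s: np.ndarray | None = None
    thermo: ThermoState = field(default_factory=ThermoState)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.forward_works = np.asarray(self.forward_works, dtype=float)
        self.backward_works = np.asarray(self.backward_works, dtype=float)
        if self.forward_works.size == 0 and self.backward_works.size == 0:
            raise EstimatorError("at least one direction must be non-empty")
        for name, seg, whole in (
            ("forward", self.forward_segments, self.forward_works),
            ("backward", self.backward_segments, self.backward_works),
        ):
            if seg is not None:
                seg = np.asarray(seg, dtype=float)
                if seg.shape[0] != whole.size:
                    raise EstimatorError(f"{name} segment rows != replica count")
                if not np.allclose(seg.sum(axis=1), whole, atol=1e-6):
                    raise EstimatorError(
                        f"{name} segment works do not sum to whole-run works"
                    )
        if self.node_s is not None:
            self.node_s = np.asarray(self.node_s, dtype=float)

    @property
    def beta(self) -> float:
        return self.thermo.beta

    def resample(self, rng: np.random.Generator) -> "WorkSet":
        """Bootstrap resample: replicas drawn with replacement per direction."""
        i_f = rng.integers(0, self.forward_works.size, self.forward_works.size)
        i_b = rng.integers(0, self.backward_works.size, self.backward_works.size)
        return WorkSet(
            forward_works=self.forward_works[i_f],
            backward_works=self.backward_works[i_b],
            forward_segments=(
                None if self.forward_segments is None else self.forward_segments[i_f]
            ),
            backward_segments=(
                None if self.backward_segments is None else self.backward_segments[i_b]
            ),
            node_s=self.node_s,
            thermo=self.thermo,
            metadata=self.metadata,
        )


@dataclass
class PMFProfile:
    """Free energy F(Sᵢ) along the node grid, anchored at F(S₀) = 0."""

    node_s: np.ndarray
    f_values: np.ndarray       # kJ/mol
    stderr: np.ndarray | None = None
    estimator: str = "crooks"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_s = np.asarray(self.node_s, dtype=float)
        self.f_values = np.asarray(self.f_values, dtype=float)
        if self.node_s.shape != self.f_values.shape:
            raise EstimatorError("node_s and f_values must align")
        if np.any(np.diff(self.node_s) <= 0):
            raise EstimatorError("node_s must be strictly increasing")
        if abs(self.f_values[0]) > 1e-10:
            raise EstimatorError("profile must be anchored at F(S0) = 0")
        if not np.all(np.isfinite(self.f_values)):
            raise EstimatorError("profile contains non-finite values")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)


@dataclass(frozen=True)
class BootstrapResult:
    stderr: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_failures: int = 0


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def jarzynski_estimate(works: np.ndarray, beta: float) -> float:
    """ΔF = −(1/β)·ln⟨e^(−βW)⟩ with overflow-safe log-sum-exp."""
    w = np.asarray(works, dtype=float)
    if w.size == 0:
        raise EstimatorError("no work samples")
    if not np.all(np.isfinite(w)):
        raise EstimatorError("work samples contain non-finite values")
    return float(-(logsumexp(-beta * w) - np.log(w.size)) / beta)


def _bar_delta_f(
    w_f: np.ndarray,
    w_b: np.ndarray,
    beta: float,
    bracket_pad_kt: float = 10.0,
    xtol_kt: float = 1e-10,
) -> float:
    """Bennett acceptance-ratio solve of the Crooks relation.

    Monotone root of
    g(x) = Σ σ(−(M + β(w_f − x))) − Σ σ(−(−M + β(w_b + x))),
    where σ is the logistic function and M = ln(n_f/n_b); bracketed in
    [min(−w_b) − pad, max(w_f) + pad].
    """
    w_f = np.asarray(w_f, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_f.size == 0 or w_b.size == 0:
        raise EstimatorError("both directions must have samples")
    m = np.log(w_f.size / w_b.size)
    kt = 1.0 / beta

    def g(x: float) -> float:
        return float(
            np.sum(expit(-(m + beta * (w_f - x))))
            - np.sum(expit(-(-m + beta * (w_b + x))))
        )

    lo = float(np.min(-w_b) - bracket_pad_kt * kt)
    hi = float(np.max(w_f) + bracket_pad_kt * kt)
    overlap_msg = (
        "forward and backward work distributions do not overlap; the "
        "Crooks/Bennett solution is undetermined — run slower pulls or "
        "more replicas (dissipation hinders estimator convergence)"
    )
    g_lo, g_hi = g(lo), g(hi)
    if g_lo > 0 or g_hi < 0:
        raise OverlapError(overlap_msg)
    root = lo if g_lo == 0.0 else hi if g_hi == 0.0 else float(
        brentq(g, lo, hi, xtol=xtol_kt * kt)
    )
    # with a wide gap both logistic sums saturate to ~0 across the whole
    # gap and brentq "finds" an arbitrary point; require that an
    # appreciable effective number of samples supports the solution
    support = float(np.sum(expit(-(m + beta * (w_f - root)))))
    if support < 1e-6 * min(w_f.size, w_b.size):
        raise OverlapError(overlap_msg)
    return root


def crooks_delta_f(ws: WorkSet) -> float:
    """Bidirectional ΔF(A→B) from whole-run works via the CFT/BAR solve."""
    return _bar_delta_f(ws.forward_works, ws.backward_works, ws.beta)


# ---------------------------------------------------------------------------
# Segment-wise PMF reconstruction
# ---------------------------------------------------------------------------

def _segment_pair(ws: WorkSet, i: int) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward (B→A-ordered) work columns for segment i."""
    n_seg = ws.forward_segments.shape[1]
    return ws.forward_segments[:, i], ws.backward_segments[:, n_seg - 1 - i]


def _require_segments(ws: WorkSet) -> None:
    if ws.forward_segments is None or ws.backward_segments is None:
        raise EstimatorError("segment matrices required in both directions")
    if ws.forward_segments.shape[1] != ws.backward_segments.shape[1]:
        raise EstimatorError("segment grids differ between directions")


def reconstruct_pmf_crooks(
    ws: WorkSet,
    node_s: np.ndarray | None = None,
    n_boot: int = 500,
    seed: int | None = 0,
) -> PMFProfile:
    """Segment-wise Crooks/BAR PMF along the node grid.

    Each inter-node ΔFᵢ is solved from the forward and backward work
    samples of that interval; the profile is their cumulative sum. A
    segment whose distributions do not overlap is flagged and the profile
    truncated there. Node stderr from bootstrap resampling of replicas
    (propagated through the cumulative sum); ``n_boot=0`` skips it.
    """
    _require_segments(ws)
    grid = np.asarray(node_s if node_s is not None else ws.node_s, dtype=float)
    n_seg = ws.forward_segments.shape[1]
    if grid is None or grid.size != n_seg + 1:
        raise EstimatorError("node grid must have one more entry than segments")

    def _profile(w: WorkSet) -> np.ndarray:
        df = np.empty(n_seg)
        for i in range(n_seg):
            wf, wb = _segment_pair(w, i)
            df[i] = _bar_delta_f(wf, wb, w.beta)
        return np.concatenate([[0.0], np.cumsum(df)])

    flagged: list[int] = []
    try:
        f = _profile(ws)
    except OverlapError:
        # locate the first failing segment and truncate
        df = []
        for i in range(n_seg):
            wf, wb = _segment_pair(ws, i)
            try:
                df.append(_bar_delta_f(wf, wb, ws.beta))
            except OverlapError:
                flagged.append(i)
                break
        f = np.concatenate([[0.0], np.cumsum(df)])
        grid = grid[: f.size]

    stderr = None
    if n_boot and not flagged:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
        boots = np.empty((n_boot, f.size))
        n_fail = 0
        for b in range(n_boot):
            try:
                boots[b] = _profile(ws.resample(rng))
            except OverlapError:
                boots[b] = np.nan
                n_fail += 1
        if n_fail > n_boot // 2:
            raise EstimatorError(
                f"bootstrap failed in {n_fail}/{n_boot} resamples (poor overlap)"
            )
        stderr = np.nanstd(boots, axis=0, ddof=1)

    return PMFProfile(
        node_s=grid,
        f_values=f,
        stderr=stderr,
        estimator="crooks",
        flags={"non_overlapping_segments": flagged} if flagged else {},
    )


def reconstruct_pmf_jarzynski(
    ws: WorkSet,
    node_s: np.ndarray | None = None,
    direction: str = "forward",
    n_boot: int = 500,
    seed: int | None = 0,
) -> PMFProfile:
    """Cumulative Jarzynski PMF from the segment works of one direction.

    The cumulative work of each replica up to node Sᵢ is exponentially
    averaged to give F(Sᵢ) directly. For the backward direction the
    reconstruction runs along B→A and is mapped back onto the forward
    grid (sign flipped, re-anchored at the first node).
    """
    _require_segments(ws)
    grid = np.asarray(node_s if node_s is not None else ws.node_s, dtype=float)
    if direction not in ("forward", "backward"):
        raise EstimatorError("direction must be 'forward' or 'backward'")
    beta = ws.beta

    def _profile(w: WorkSet) -> np.ndarray:
        seg = w.forward_segments if direction == "forward" else w.backward_segments
        cum = np.concatenate(
            [np.zeros((seg.shape[0], 1)), np.cumsum(seg, axis=1)], axis=1
        )
        g = np.array([jarzynski_estimate(cum[:, j], beta) for j in range(cum.shape[1])])
        if direction == "backward":
            # g[j] = F(S_{n-1-j}) − F(S_{n-1}); map to forward grid, re-anchor
            g = g[::-1]
            g = g - g[0]
        return g

    f = _profile(ws)
    stderr = None
    if n_boot:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
        boots = np.stack([_profile(ws.resample(rng)) for _ in range(n_boot)])
        stderr = boots.std(axis=0, ddof=1)
    return PMFProfile(
        node_s=grid, f_values=f, stderr=stderr, estimator="jarzynski"
    )


# ---------------------------------------------------------------------------
# Bootstrap errors
# ---------------------------------------------------------------------------

def bootstrap_error(
    ws: WorkSet,
    estimator: Callable[[WorkSet], float],
    n_boot: int = 500,
    seed: int | None = 0,
) -> BootstrapResult:
    """Stderr and 2.5/97.5 percentile CI of a scalar estimator.

    Replicas are resampled with replacement independently per direction;
    estimator failures (e.g. lost overlap in a resample) are tolerated up
    to half the resamples. Deterministic under a fixed seed.
    """
    if n_boot < 2:
        raise EstimatorError("n_boot must be >= 2")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    values = []
    n_fail = 0
    for _ in range(n_boot):
        try:
            values.append(estimator(ws.resample(rng)))
        except EstimatorError:
            n_fail += 1
    if n_fail > n_boot // 2:
        raise EstimatorError(
            f"estimator failed in {n_fail}/{n_boot} bootstrap resamples"
        )
    arr = np.asarray(values)
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return BootstrapResult(
        stderr=float(arr.std(ddof=1)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_failures=n_fail,
    )
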