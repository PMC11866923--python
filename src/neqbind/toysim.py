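"""Steered overdamped-Langevin toy simulator with analytic free energies.

The estimators in this package are validated end-to-end on a particle
diffusing on a simple potential while a harmonic trap drags it along.
The steered coordinate is identified with the particle position itself
(S(x) = x), so a moving-trap pull on a harmonic potential

    V(x) = (a/2)·x²,   R(x, t) = (k/2)·(x − Ŝ(t))²

has the exactly known end-state free-energy difference

    ΔF = [a·k / (2(a + k))]·(s₁² − s₀²),

since the combined Hamiltonian is Gaussian at every trap position with an
s-independent width. Dynamics are overdamped Euler–Maruyama,

    x_{n+1} = x_n − β·D·∇U(x_n)·dt + √(2·D·dt)·ξ_n,

which samples the Boltzmann distribution of U at equilibrium; the
estimators never use velocities, so inertia adds nothing here.

A 2-D variant carries an explicit orthogonal coordinate z (standing in
for the PCV Z, nm²) with an optional off-path trap — a Gaussian well at
z > 0 that captures the particle unless a flat-bottom wall on z keeps it
near the path. This reproduces, at desk scale, the mechanism by which
tightening the Z wall reduces dissipation in binding-direction pulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .path_geometry import Frame, ReferencePath
from .steering_work import (
    RestraintParams,
    SteeringError,
    SteeringSchedule,
    TrajectoryRecord,
    accumulate_work,
)
from .units import beta_from_temperature


class ToySimError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyPotential:
    """Analytic background potential V for the toy particle.

    kinds
    -----
    ``flat``         V = 0 (any dimension)
    ``harmonic``     V = (a/2)·x², params: ``a`` (kJ/mol per unit²)
    ``double_well``  V = h·((x/x0)² − 1)², params: ``h`` (barrier, kJ/mol),
                     ``x0`` (minima at ±x0)
    ``offpath_trap`` 2-D: (a/2)·x² − depth·G(x, z) with a Gaussian well G
                     centred at (trap_x, trap_z), widths (trap_sx, trap_sz)
    """

    kind: str
    params: dict = field(default_factory=dict)
    dimension: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "harmonic", "double_well", "offpath_trap"):
            raise ToySimError(f"unknown potential kind {self.kind!r}")
        if self.kind == "harmonic" and self.params.get("a", 0.0) < 0:
            raise ToySimError("harmonic stiffness must be >= 0")
        if self.kind == "offpath_trap" and self.dimension != 2:
            raise ToySimError("offpath_trap is a 2-D potential")

    def force_s(self, s: np.ndarray, z: np.ndarray | None = None) -> np.ndarray:
        """−∂V/∂s."""
        if self.kind == "flat":
            return np.zeros_like(s)
        if self.kind == "harmonic":
            return -self.params["a"] * s
        if self.kind == "double_well":
            h, x0 = self.params["h"], self.params["x0"]
            u = (s / x0) ** 2 - 1.0
            return -4.0 * h * u * s / x0**2
        # offpath_trap
        a = self.params.get("a", 0.0)
        d, xc, zc, sx, sz = (
            self.params["depth"], self.params["trap_x"], self.params["trap_z"],
            self.params["trap_sx"], self.params["trap_sz"],
        )
        g = np.exp(-((s - xc) ** 2) / (2 * sx**2) - ((z - zc) ** 2) / (2 * sz**2))
        return -a * s - d * g * (s - xc) / sx**2

    def force_z(self, s: np.ndarray, z: np.ndarray) -> np.ndarray:
        """−∂V/∂z (2-D kinds only)."""
        if self.kind != "offpath_trap":
            return np.zeros_like(z)
        d, xc, zc, sx, sz = (
            self.params["depth"], self.params["trap_x"], self.params["trap_z"],
            self.params["trap_sx"], self.params["trap_sz"],
        )
        g = np.exp(-((s - xc) ** 2) / (2 * sx**2) - ((z - zc) ** 2) / (2 * sz**2))
        return -d * g * (z - zc) / sz**2

    def energy(self, s: np.ndarray, z: np.ndarray | None = None) -> np.ndarray:
        if self.kind == "flat":
            return np.zeros_like(np.asarray(s, dtype=float))
        if self.kind == "harmonic":
            return 0.5 * self.params["a"] * np.asarray(s) ** 2
        if self.kind == "double_well":
            h, x0 = self.params["h"], self.params["x0"]
            return h * ((np.asarray(s) / x0) ** 2 - 1.0) ** 2
        a = self.params.get("a", 0.0)
        d, xc, zc, sx, sz = (
            self.params["depth"], self.params["trap_x"], self.params["trap_z"],
            self.params["trap_sx"], self.params["trap_sz"],
        )
        g = np.exp(-((s - xc) ** 2) / (2 * sx**2) - ((z - zc) ** 2) / (2 * sz**2))
        return 0.5 * a * np.asarray(s) ** 2 - d * g

    def max_curvature(self, k_spring: float, k_wall: float = 0.0) -> float:
        """Rough bound on ∂²U/∂x² used for the timestep stability check."""
        if self.kind == "flat":
            base = 0.0
        elif self.kind == "harmonic":
            base = self.params["a"]
        elif self.kind == "double_well":
            base = 8.0 * self.params["h"] / self.params["x0"] ** 2
        else:
            a = self.params.get("a", 0.0)
            d = self.params["depth"]
            s_min = min(self.params["trap_sx"], self.params["trap_sz"])
            base = a + d / s_min**2
        return base + k_spring + k_wall


@dataclass(frozen=True)
class ThermoState:
    """Temperature, diffusion coefficient, timestep and master seed."""

    temperature: float = 300.0   # K
    diffusion: float = 1.0       # unit²/ps
    dt: float = 0.005            # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.dt <= 0 or self.diffusion <= 0:
            raise ToySimError("temperature, diffusion and dt must be positive")

    @property
    def beta(self) -> float:
        return beta_from_temperature(self.temperature)

    @property
    def kt(self) -> float:
        return 1.0 / self.beta


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

def _check_stability(pot: ToyPotential, rp: RestraintParams, th: ThermoState) -> None:
    kappa = pot.max_curvature(rp.k_spring, rp.k_wall)
    if th.dt * th.beta * th.diffusion * kappa > 0.5:
        raise ToySimError(
            f"unstable timestep: dt*beta*D*curvature = "
            f"{th.dt * th.beta * th.diffusion * kappa:.3g} > 0.5; reduce dt"
        )


def _wall_force(z: np.ndarray, rp: RestraintParams) -> np.ndarray:
    """Upper flat-bottom wall on z plus a matching lower wall at z = 0.

    z stands in for the MSD-like PCV Z which is non-negative; the lower
    wall enforces that in the toy model.
    """
    f = -rp.k_wall * np.maximum(z - rp.z_wall_at, 0.0)
    f += -rp.k_wall * np.minimum(z, 0.0)
    return f


def _propagate_ensemble(
    pot: ToyPotential,
    sch: SteeringSchedule,
    rp: RestraintParams,
    th: ThermoState,
    x0: np.ndarray,
    rngs: list[np.random.Generator],
    z0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Steered Euler–Maruyama for a replica ensemble, lockstep in time.

    Returns (s_series, z_series) of shape (n_replicas, n_steps+1). Each
    replica consumes noise from its own generator so that single-replica
    and ensemble runs are bit-identical.
    """
    n_steps = int(round(sch.duration / th.dt))
    if abs(n_steps * th.dt - sch.duration) > 1e-9 * sch.duration:
        raise ToySimError("duration must be an integer multiple of dt")
    n_rep = len(x0)
    noise_s = np.stack([r.standard_normal(n_steps) for r in rngs])
    two_d = pot.dimension == 2
    noise_z = (
        np.stack([r.standard_normal(n_steps) for r in rngs]) if two_d else None
    )
    s = np.empty((n_rep, n_steps + 1))
    s[:, 0] = x0
    z = np.zeros((n_rep, n_steps + 1))
    if two_d and z0 is not None:
        z[:, 0] = z0
    amp = np.sqrt(2.0 * th.diffusion * th.dt)
    mob = th.beta * th.diffusion * th.dt
    centers = sch.s_start + sch.speed * np.arange(n_steps + 1) * th.dt
    cur_s = s[:, 0].copy()
    cur_z = z[:, 0].copy()
    for i in range(n_steps):
        f_s = pot.force_s(cur_s, cur_z if two_d else None)
        f_s = f_s - rp.k_spring * (cur_s - centers[i])
        cur_s = cur_s + mob * f_s + amp * noise_s[:, i]
        if two_d:
            f_z = pot.force_z(s[:, i], cur_z) + _wall_force(cur_z, rp)
            cur_z = cur_z + mob * f_z + amp * noise_z[:, i]
            z[:, i + 1] = cur_z
        s[:, i + 1] = cur_s
    return s, z


def _equilibrate(
    pot: ToyPotential,
    rp: RestraintParams,
    th: ThermoState,
    center: float,
    x0: np.ndarray,
    rngs: list[np.random.Generator],
    n_steps: int,
    z0: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Burn-in at a fixed trap centre; returns final (s, z) per replica."""
    n_rep = len(x0)
    two_d = pot.dimension == 2
    amp = np.sqrt(2.0 * th.diffusion * th.dt)
    mob = th.beta * th.diffusion * th.dt
    cur_s = np.asarray(x0, dtype=float).copy()
    cur_z = np.zeros(n_rep) if z0 is None else np.asarray(z0, dtype=float).copy()
    noise_s = np.stack([r.standard_normal(n_steps) for r in rngs])
    noise_z = (
        np.stack([r.standard_normal(n_steps) for r in rngs]) if two_d else None
    )
    for i in range(n_steps):
        f_s = pot.force_s(cur_s, cur_z if two_d else None)
        f_s = f_s - rp.k_spring * (cur_s - center)
        new_s = cur_s + mob * f_s + amp * noise_s[:, i]
        if two_d:
            f_z = pot.force_z(cur_s, cur_z) + _wall_force(cur_z, rp)
            cur_z = cur_z + mob * f_z + amp * noise_z[:, i]
        cur_s = new_s
    return cur_s, cur_z


def default_burn_in_steps(pot: ToyPotential, rp: RestraintParams, th: ThermoState) -> int:
    """10 relaxation times of the stiffest harmonic scale, in steps."""
    kappa = max(pot.max_curvature(rp.k_spring, rp.k_wall), 1e-12)
    tau = 1.0 / (th.beta * th.diffusion * kappa)
    return max(int(round(10.0 * tau / th.dt)), 10)


def run_steered_langevin(
    pot: ToyPotential,
    sch: SteeringSchedule,
    rp: RestraintParams,
    th: ThermoState,
    x0: float,
    z0: float = 0.0,
) -> TrajectoryRecord:
    """One steered trajectory; deterministic for a fixed ``th.seed``."""
    _check_stability(pot, rp, th)
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(th.seed)))
    s, z = _propagate_ensemble(
        pot, sch, rp, th, np.array([x0]), [rng],
        z0=np.array([z0]) if pot.dimension == 2 else None,
    )
    n = s.shape[1]
    times = np.arange(n) * th.dt
    work = accumulate_work(s[0], sch, rp.k_spring, th.dt)
    return TrajectoryRecord(
        times=times,
        s_values=s[0],
        z_values=z[0],
        schedule_values=sch.s_start + sch.speed * times,
        cumulative_work=work,
        direction="forward" if sch.is_forward else "backward",
    )


# ---------------------------------------------------------------------------
# Analytic oracle
# ---------------------------------------------------------------------------

def analytic_trap_delta_f(
    pot: ToyPotential, k_spring: float, s0: float, s1: float, th: ThermoState
) -> float:
    """Exact end-state ΔF (kJ/mol) for the trapped flat/harmonic system.

    For V = (a/2)x² plus trap (k/2)(x − s)², completing the square gives
    F(s) = [a·k/(2(a+k))]·s² up to an s-independent constant, hence
    ΔF = [a·k/(2(a+k))]·(s1² − s0²). A flat potential (a = 0) gives 0 by
    translation invariance.
    """
    if pot.kind == "flat":
        return 0.0
    if pot.kind != "harmonic":
        raise ToySimError("analytic ΔF available for flat/harmonic only")
    a = pot.params["a"]
    return a * k_spring / (2.0 * (a + k_spring)) * (s1**2 - s0**2)


# ---------------------------------------------------------------------------
# Bidirectional work generation
# ---------------------------------------------------------------------------

def _replica_rngs(master_seed: int, n: int, stream_offset: int = 0):
    children = np.random.SeedSequence(master_seed).spawn(stream_offset + n)
    return [np.random.Generator(np.random.Philox(c)) for c in children[stream_offset:]]


def generate_bidirectional_works(
    pot: ToyPotential,
    sch: SteeringSchedule,
    rp: RestraintParams,
    th: ThermoState,
    n_fwd: int,
    n_bwd: int,
    node_s: np.ndarray | None = None,
    burn_in_steps: int | None = None,
):
    """Forward and backward steered ensembles → a :class:`WorkSet`.

    Forward replicas start from end-state-A equilibrium (burn-in with the
    trap fixed at ``sch.s_start``), backward replicas from end-state-B
    equilibrium (trap at ``sch.s_end``); burn-in rather than exact Gaussian
    sampling so the generator also works on the double well. Backward
    works are recorded along the B→A pull. Per-replica seeds derive from
    ``th.seed`` through a spawned seed ladder, so a fixed master seed gives
    a bit-identical result; forward replica i uses ladder stream i,
    backward replica j uses stream n_fwd + j.

    When ``node_s`` is given, per-replica work increments over each
    [Sᵢ, Sᵢ₊₁] interval are recorded as well (backward increments in B→A
    traversal order), enabling segment-wise PMF reconstruction.
    """
    from .estimators import WorkSet  # local import to avoid a cycle

    if n_fwd < 1 or n_bwd < 1:
        raise ToySimError("need at least one replica in each direction")
    _check_stability(pot, rp, th)
    if burn_in_steps is None:
        burn_in_steps = default_burn_in_steps(pot, rp, th)

    sch_b = sch.reversed()
    two_d = pot.dimension == 2

    def _run(schedule, n_rep, offset):
        rngs = _replica_rngs(th.seed, n_rep, stream_offset=offset)
        x_init = np.full(n_rep, schedule.s_start, dtype=float)
        z_init = np.zeros(n_rep) if two_d else None
        x_eq, z_eq = _equilibrate(
            pot, rp, th, schedule.s_start, x_init, rngs, burn_in_steps, z0=z_init
        )
        s, z = _propagate_ensemble(
            pot, schedule, rp, th, x_eq, rngs, z0=z_eq if two_d else None
        )
        w = accumulate_work(s, schedule, rp.k_spring, th.dt)
        return s, z, w

    s_f, z_f, w_f = _run(sch, n_fwd, 0)
    s_b, z_b, w_b = _run(sch_b, n_bwd, n_fwd)

    fwd_seg = bwd_seg = None
    grid = None
    if node_s is not None:
        grid = np.asarray(node_s, dtype=float)
        times = np.arange(s_f.shape[1]) * th.dt
        # schedule-crossing times are replica-independent; interpolate W there
        def _segments(w, schedule):
            traversal = grid if schedule.is_forward else grid[::-1]
            t_cross = (traversal - schedule.s_start) / schedule.speed
            w_at = np.stack([np.interp(t_cross, times, wi) for wi in w])
            return np.diff(w_at, axis=1)

        fwd_seg = _segments(w_f, sch)
        bwd_seg = _segments(w_b, sch_b)

    return WorkSet(
        forward_works=w_f[:, -1],
        backward_works=w_b[:, -1],
        forward_segments=fwd_seg,
        backward_segments=bwd_seg,
        node_s=grid,
        thermo=th,
        metadata={
            "schedule": (sch.s_start, sch.s_end, sch.duration),
            "k_spring": rp.k_spring,
            "z_wall_at": rp.z_wall_at,
            "k_wall": rp.k_wall,
            "master_seed": th.seed,
            "n_fwd": n_fwd,
            "n_bwd": n_bwd,
            "burn_in_steps": burn_in_steps,
            "mean_final_z_fwd": float(z_f[:, -1].mean()) if two_d else 0.0,
        },
    )


def make_offpath_trap_system(
    seed: int = 0,
) -> tuple[ToyPotential, SteeringSchedule, ThermoState]:
    """Constructed 2-D system for the wall-tightening experiment.

    A particle pulled in the binding direction (s: 1 → 0, 20 time units)
    past a deep (16 kT), narrow Gaussian trap sitting off the path at
    (s, z) = (0.5, 0.05) — just at the loose wall threshold. With the
    upper wall on z at 0.05 nm² every replica falls into the trap and
    escapes by stick-slip, dissipating extra work; tightening the wall to
    0.005 nm² keeps z below the trap's reach and the extra dissipation
    disappears. Pair with ``RestraintParams(k_spring=10 kT,
    z_wall_at=0.05 or 0.005, k_wall=1.6e5)``.

    The timestep (4e-5) and diffusion coefficient (0.1) satisfy the
    overdamped stability bound for the trap's curvature; the wall is
    stiff enough that its restoring force exceeds the trap's maximum
    z-pull, which is what makes the tight threshold actually exclusive.
    """
    th = ThermoState(temperature=300.0, diffusion=0.1, dt=4e-5, seed=seed)
    kt_val = th.kt
    pot = ToyPotential(
        "offpath_trap",
        {
            "a": kt_val,
            "depth": 16.0 * kt_val,
            "trap_x": 0.5,
            "trap_z": 0.05,
            "trap_sx": 0.12,
            "trap_sz": 0.02,
        },
        dimension=2,
    )
    sch = SteeringSchedule(1.0, 0.0, 20.0)
    return pot, sch, th


# ---------------------------------------------------------------------------
# Toy molecular paths
# ---------------------------------------------------------------------------

def make_toy_molecular_path(
    n_nodes: int,
    geometry: str = "line",
    n_atoms: int = 3,
    step: float = 0.3,
    radius: float | None = None,
) -> ReferencePath:
    """Synthetic ligand-like reference path with known consecutive MSDs.

    A rigid cluster of ``n_atoms`` atoms translates along a line (equal
    steps ``step`` nm, consecutive MSD = step² exactly) or along a
    circular arc of the given ``radius`` (equal chord steps). No
    superposition set is attached (align_idx=None) — frames share one
    coordinate frame by construction, mirroring how ligand PCV distances
    are taken after alignment on the pocket.
    """
    if n_nodes < 2:
        raise ToySimError("a path needs >= 2 nodes")
    if geometry not in ("line", "arc"):
        raise ToySimError("geometry must be 'line' or 'arc'")
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(1234)))
    base = rng.normal(scale=0.05, size=(n_atoms, 3))  # small rigid cluster
    base -= base.mean(axis=0)
    ids = tuple(f"C{i+1}" for i in range(n_atoms))
    frames = []
    if geometry == "line":
        for i in range(n_nodes):
            offset = np.array([i * step, 0.0, 0.0])
            frames.append(Frame(base + offset, ids))
    else:
        r = radius if radius is not None else step * n_nodes
        # equal chord length `step` → equal consecutive MSD = step²
        dphi = 2.0 * np.arcsin(min(step / (2.0 * r), 1.0))
        for i in range(n_nodes):
            phi = i * dphi
            offset = np.array([r * np.sin(phi), r * (1.0 - np.cos(phi)), 0.0])
            frames.append(Frame(base + offset, ids))
    return ReferencePath(frames=frames, align_idx=None, cv_idx=tuple(range(n_atoms)))
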