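# Methods

This note documents the models implemented in `neqbind`, their
assumptions, the parameters that matter, the synthetic study conditions,
and the numerical and design choices made where the design was open.

## Path collective variables

A reference path is an ordered sequence of `p ≥ 2` molecular
configurations. The metric is the **mean square deviation** (MSD, nm²)
over a CV atom subset after optimal rigid superposition (Kabsch, proper
rotations only) on an alignment subset — typically pocket heavy atoms for
alignment and ligand (optionally plus pocket) heavy atoms for the CV.
Using MSD rather than RMSD makes the orthogonal variable `Z` carry nm²,
so wall thresholds are quoted in nm². `align_idx = None` declares that
frames already share a coordinate frame and skips superposition; this is
how single-particle toy paths are handled (a 1-atom frame cannot be
superposed — a unique rotation needs ≥ 3 non-collinear atoms, which is
enforced).

`S(x)` uses `(i−1)/(p−1)` weights so the bound end maps to 0 and the
unbound end to 1. Both `S` and `Z` are computed with exponent shifting by
the minimum node distance, so arbitrarily large `λ·d` cannot overflow.
`Z` is a softmin: `min_i d_i − ln(p)/λ ≤ Z ≤ min_i d_i`.

The smoothness parameter defaults to `λ = 2.3 / mean(consecutive MSD)`.
The constant 2.3 makes the node weights decay by roughly an order of
magnitude per inter-node spacing, which keeps `S` a smooth, near-linear
map of progress; it is exposed as an argument because the appropriate
value is heuristic, not derived.

**Path conditioning.** Equidistant reparametrization is a string-method
style iteration: nodes are progressively aligned, arc length is measured
as √MSD between consecutive nodes, and new nodes are placed by
piecewise-linear interpolation at uniform arc length until the
coefficient of variation of consecutive MSDs falls below `tol` (default
1e-3). Endpoints are pinned bit-for-bit. Failure to converge warns and
returns the best result with `meta["converged"] = False`, never silently.
End-point padding extrapolates the terminal segment linearly at the
terminal step size — a deterministic, engine-free way to push PCV
boundary artifacts outside the physical range (padded nodes are steered
targets only in the sense that they extend the `S` scale; they are never
visited). `smooth_path` is a plain moving average with fixed endpoints
for de-jittering guess paths; it deliberately implements no
machine-learned path optimisation.

## Steering and work

The steered Hamiltonian adds `(k/2)(S(x) − Ŝ(t))²` with `Ŝ(t)` moving at
constant speed, plus a one-sided harmonic wall on `Z` active above a
threshold (default 0.05 nm²; energy and first derivative continuous at
the threshold). The **Jarzynski work** is the time integral of the
explicit time derivative of the Hamiltonian; only the moving restraint
contributes — the wall is time-independent and does no work by this
definition. Quadrature is trapezoidal on the logging grid (second-order;
halving the timestep changes toy work values below 1e-6 kJ/mol).

**Segmentation.** Work increments per path interval `[S_i, S_{i+1}]` are
taken by differencing cumulative work at the times the *schedule* crosses
the node values, not the fluctuating `S(x)`: crossing times of the
monotone schedule are unique, so increments telescope exactly to the
total and nothing is double-counted when the system recrosses nodes.
Backward trajectories are segmented against the reversed grid.

## Estimators

* **Jarzynski**: `ΔF = −(1/β)·ln⟨e^(−βW)⟩` via log-sum-exp (safe for
  |βW| in the hundreds). The estimate is permutation-invariant and can
  only decrease when a smaller work sample is appended.
* **Crooks/Bennett**: backward works are stored as measured along the
  B→A pull. The estimate solves the Bennett acceptance-ratio equation
  with sample-size weighting `M = ln(n_f/n_b)` by bracketed Brent root
  finding on `[min(−W_b) − 10 kT, max(W_f) + 10 kT]` (tolerance 1e-10 kT).
  For equal-variance Gaussian work densities this is the intersection
  point `(⟨W_f⟩ − ⟨W_b⟩)/2` of the forward and reflected backward
  densities. Two failure modes raise an explicit overlap error rather
  than returning a number: no sign change in the bracket, and a root
  supported by a vanishing effective number of samples (both logistic
  sums saturating to ~0 across a wide gap lets the root finder settle
  anywhere in the gap; the effective-sample check, threshold
  1e-6·min(n_f, n_b), catches this).
* **PMF reconstruction**: each interval's forward/backward work columns
  are solved independently and summed, `F(S_{i+1}) = F(S_i) + ΔF_i`,
  `F(S_0) = 0`. A non-overlapping segment truncates the profile there and
  is reported in `flags`. The analogous Jarzynski reconstruction
  exponent-averages each replica's cumulative work up to every node, in
  either direction (the backward profile is mapped back to the forward
  grid and re-anchored).
* **Errors**: bootstrap over replicas, resampled with replacement
  independently per direction, 500 resamples by default, deterministic
  under a fixed seed; standard deviation plus 2.5/97.5 percentiles.
  Estimator failures are tolerated in up to half the resamples.

The choice of the acceptance-ratio form over intersecting kernel-density
estimates of the two work densities is deliberate: it is the
minimum-variance solution of the same relation, has no bandwidth
parameter, and degrades gracefully at small n.

## Binding thermodynamics

`ΔF_b = −(1/β)·ln(Q_site/Q_bulk)` with `Q` integrals of `e^(−βF(S))` by
trapezoid on the node grid (no interpolation onto finer grids — sparse
profiles would inherit interpolation artifacts). The profile minimum is
subtracted before exponentiating; the shift cancels in the ratio, making
the result gauge-invariant to 1e-10.

`ΔF_v = −k_B T·ln(V_bulk/V°)`, `V° = 1661 Å³` (the printed convention for
1 M; the exact Avogadro value 1e27/N_A = 1660.54 Å³ is available as
`standard_state_volume()`). The sign convention follows the
Doudou-et-al. composition: sampling a bulk volume larger than V° makes
binding more favourable. `V_bulk` is a required input — molecular-surface
volume computation is out of scope; a rectangular-slab helper covers toy
geometries.

The cut between site and bulk defaults to the first index after the
global PMF minimum from which every sliding-window slope through the end
is below `slope_tol` times a noise-slope scale (mean pointwise stderr
over the window span; absolute kJ/mol per S unit when the profile has no
errors). It raises a "no plateau" error rather than guessing, and the
returned index is logged as a suggestion to be confirmed by trajectory
inspection. CI propagation through `ΔF_b` perturbs the node values with
independent Gaussians of the node stderr — a simplification that ignores
inter-node correlations from the cumulative reconstruction; the full
bootstrap profiles would be needed to do better.

## Dissipation diagnostics

`W_diss = ⟨W⟩ − ΔF` (forward) or `⟨W⟩ + ΔF` (backward), with ΔF always
the A→B difference, referenced by default to the converged Crooks
estimate. The per-node profile is the cumulative mean segment work minus
the free-energy change covered so far, and telescopes exactly to the
whole-run value. The duration scan reports finite-difference derivatives
(central in the interior, one-sided at the ends, correct for non-uniform
duration grids) and flags — rather than hides — violations of the
expected monotone decrease. The stiff-spring check flags a replica when
`|S(t) − Ŝ(t)|` exceeds `lag_tol` (default 0.1 progress units) for more
than `fraction_tol` (default 20 %) of the pull, and localises the worst
excursion on the schedule. The defaults are package choices — the
underlying criterion is visual in practice — and are exposed in the CLI.

## The toy simulator and study conditions

Overdamped Euler–Maruyama dynamics,
`x' = x − βD·∇U·dt + √(2D dt)·ξ`, on analytic potentials, identifying the
steered coordinate with the particle position (`S(x) = x`). Overdamped
because the estimators never use velocities and the stationary
distribution is exactly Boltzmann, giving closed-form oracles. A
stability guard refuses `dt·βD·κ > 0.5` for the stiffest curvature κ in
play. Replica seeds derive from the master seed through a spawned
`SeedSequence` ladder (forward replica i = stream i, backward replica j =
stream n_fwd + j), making every WorkSet bit-reproducible. Backward
initial conditions come from burn-in at the end state (default ten
relaxation times) rather than exact Gaussian sampling so the same code
path works on anharmonic potentials.

**Moving-trap conditions** (used throughout the tests): `a = k = 1 kT`
per unit² at 300 K, `s: 0 → 1`, duration 5 time units = ten relaxation
times of the combined trap (`τ = 1/(βD(a+k)) = 0.5` at `D = 1`),
`dt = 0.005`. Analytic result: `ΔF = a·k/(2(a+k))·(s₁² − s₀²)`, i.e.
0.25 kT for the standard pull, with the whole quadratic profile known
node-wise. Typical dissipation at these conditions is ≈ 0.04 kT per
pull.

**Wall-tightening system** (`make_offpath_trap_system`): a 2-D particle
(s along the path, z the off-path coordinate standing in for the PCV Z)
pulled in the binding direction (1 → 0 over 20 time units, `D = 0.1`,
`dt = 4e-5`, `k = 10 kT`) past a 16 kT Gaussian trap at
`(s, z) = (0.5, 0.05)` with widths (0.12, 0.02). With the upper wall at
`Z = 0.05 nm²` the trap is inside the allowed region: every replica falls
in and escapes by stick-slip, adding ≈ 0.3–0.4 kT of mean dissipation.
At `Z = 0.005 nm²` the wall (stiffness 1.6e5 kJ/mol/nm⁴, chosen so its
restoring force exceeds the trap's maximum z-pull) keeps the system out
of reach and the extra dissipation disappears. This reproduces, at toy
scale, the mechanism by which tightening the Z wall suppresses off-path
trapping and its work penalty.

**What the toys do and do not show.** They exercise the estimators, the
segmentation, the bootstrap, the second-law and fluctuation–dissipation
behaviour, and the wall mechanism under exactly known conditions. They do
not emulate solvent kinetics, multidimensional molecular ruggedness, or
the water-model dependence of dissipation in real systems — those effects
enter real analyses through the work tables this package consumes, not
through anything it simulates. Passing toy tests therefore validates the
analysis chain, not any particular molecular system.

## File formats and configuration

Work tables are TSV (`time_ps, s, z_nm2, s_center, work_kjmol`), one per
replica, direction in the filename suffix (`.fwd.tsv`/`.bwd.tsv`) and in
`#` metadata lines together with the config hash and replica seed. Paths
are multi-model PDB or multi-frame XYZ via MDAnalysis; coordinates are nm
internally, Å converted at the I/O boundary (PDB is always Å; XYZ honours
a declared unit). Run configuration is a YAML-serialised dataclass whose
SHA-256 prefix stamps every output. The water-model registry packages the
force-field constants of TIP3P, TIP3P/Fw, OPC3, TIP4P, TIP4P/Fw and OPC
exactly as printed (σ_O, ε_O, charges, geometry, dummy-site distance for
4-point models, flexibility constants), with per-molecule charge
neutrality asserted in tests.

## Known limitations

* No weighted-histogram/MBAR multi-state analysis and no alchemical
  schedules; the estimators are strictly the bidirectional-work pair.
* The cut-index plateau detector assumes the profile actually reaches a
  flat bulk regime; profiles truncated before the unbound state need a
  manual cut.
* Binding CI propagation treats node errors as independent (see above).
* The toy simulator is single-particle and overdamped by design; it is a
  validation harness, not a sampling engine.
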