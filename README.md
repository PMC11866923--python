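# neqbind

Nonequilibrium binding free energies from steered simulations along path
collective variables.

`neqbind` implements the full desk-side analysis chain for estimating
protein–ligand binding free energies from bidirectional steered
(non-equilibrium) simulations: path collective variables over a reference
path of molecular configurations, steered-work accumulation, Jarzynski and
Crooks/Bennett free-energy estimation with segment-wise reconstruction of
the potential of mean force (PMF), the standard-state volume correction,
and dissipated-work diagnostics. A built-in overdamped-Langevin toy
simulator with analytically known free energies validates every stage
end-to-end, so the whole pipeline is testable without a molecular dynamics
engine.

It is written for computational chemists and structural bioinformaticians
who run steered MD (e.g. through PLUMED-style path CVs) and want an
engine-agnostic, reproducible analysis of the resulting work tables.

## The method

**Path collective variables.** Given an ordered reference path of `p`
molecular configurations `x_i` and the mean square deviation
`d_i = MSD(x, x_i)` after optimal rigid superposition on an alignment atom
set, progress along the path and deviation from it are

```
S(x) = Σ_i (i−1)·e^(−λ d_i) / [(p−1)·Σ_i e^(−λ d_i)]        ∈ [0, 1]
Z(x) = −(1/λ)·ln Σ_i e^(−λ d_i)                              [nm²]
```

with `S = 0` the bound and `S = 1` the unbound state, and
`λ ≈ 2.3 / ⟨MSD(x_i, x_{i+1})⟩`. Well-behaved PCVs need consecutive nodes
equidistant in the MSD metric; `reparametrize_equidistant` enforces this
and `pad_endpoints` adds fictitious terminal nodes against boundary
artifacts.

**Steered work.** A harmonic restraint `(k/2)(S(x) − Ŝ(t))²` with centre
`Ŝ(t)` moving at constant speed, plus a flat-bottom upper wall on `Z`,
drives (un)binding. The Jarzynski work is `W(t) = ∫ ∂H/∂t dt`
(the moving restraint term only).

**Estimators.** From forward (A→B) and backward (B→A) work samples:

```
Jarzynski:  ΔF = −(1/β)·ln⟨e^(−βW)⟩                (unidirectional)
Crooks:     P_f(W)/P_b(−W) = e^(β(W−ΔF))           (bidirectional)
```

The Crooks estimate is solved in the Bennett acceptance-ratio form; the
PMF along `S` is reconstructed segment-wise from per-interval work
increments, `F(S_{i+1}) = F(S_i) + ΔF_i`. Errors come from bootstrap
resampling of replicas (500 resamples).

**Binding free energy.** `ΔF° = ΔF_b + ΔF_v` with
`ΔF_b = −k_B T·ln(Q_site/Q_bulk)`, `Q = ∫ e^(−βF(S)) dS`, and the
standard-state correction `ΔF_v = −k_B T·ln(V_bulk/V°)`, `V° = 1661 Å³`
(1 M). Dissipation diagnostics (`W_diss = ⟨W⟩ ∓ ΔF`, its evolution along
the pull and with total pull duration, and a stiff-spring tracking check)
tell you whether the protocol is converging and where the system leaves
the reference path.

## Worked example

The demo runs 50+50 bidirectional steered-Langevin pulls on the analytic
moving-trap system (`a = k = 1 kT/unit²`, trap dragged 0→1), for which
`ΔF = a·k/(2(a+k)) = 0.25 kT ≈ 0.62 kJ/mol` exactly:

```
$ neqbind estimate --demo --seed 1 --out demo.json
{
  "delta_f_crooks_kjmol": 0.6840925241827038,
  "delta_f_jarzynski_kjmol": 0.749682775992672,
  "stderr_kjmol": 0.07800981938169159,
  "ci_low_kjmol": 0.5245927273385382,
  "ci_high_kjmol": 0.8359500032353984,
  "n_f": 50,
  "n_b": 50,
  "n_boot": 500,
  "seed": 1,
  "config_hash": "017c05a6eb74",
  "pmf_file": "demo.json.pmf.tsv",
  "flags": {},
  "delta_f_analytic_kjmol": 0.6235846574999999
}
```

The Crooks estimate (0.684 ± 0.078 kJ/mol) brackets the analytic value
0.624 within its 95 % bootstrap CI; the unidirectional Jarzynski estimate
is biased slightly high, as expected for finite sampling of an exponential
average. `demo.json.pmf.tsv` holds the reconstructed 10-segment PMF with
per-node errors. The other subcommands — `path-prep`, `simulate`, `bind`,
`dissipation` — cover path conditioning, work-table generation, the
standard-state binding free energy from a PMF, and dissipation QC; all
accept `--demo` and embed the config hash and seeds in their outputs.

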