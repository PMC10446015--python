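# Methods

## Model potentials and the exact-coupling oracle

All dynamics runs on analytic diabatic models: a symmetric matrix `V(R)` of
multivariate polynomials (hartree, bohr) with per-coordinate masses.
Diagonalizing `V(R)` gives adiabatic energies `E_J`; gradients are
Hellmann-Feynman expectation values `⟨J|∇V|J⟩` (analytic, so energy-conservation
checks carry no finite-difference noise); exact coupling vectors are
`h_JL = ⟨J|∇V|L⟩ / (E_L − E_J)`. Eigenvector signs are pinned by requiring a
non-negative overlap with the previous geometry's eigenvectors, which keeps
exact coupling time series smooth along a trajectory. Below an adiabatic gap
of 1e−10 hartree the oracle refuses (raises) rather than returning divergent
couplings; trajectories never sit exactly on a seam, and the refusal is
handled gracefully inside the propagator (the point is returned without
coupling vectors).

Two constructors cover the validation studies:

- `ba_model_1d(κ, Δc, Qc)`: diabats `∓κ(Q − Qc)` coupled by the constant
  `Δc/2`. Its adiabatic gap is `sqrt(4κ²(Q−Qc)² + Δc²)` (equal to `Δc` — twice
  the diabatic coupling — at the crossing) and its exact coupling is a
  Lorentzian of height `κ/Δc` and half-width `Δc/2κ`. This is the model for
  which the spatial Baeck-An expression is *exactly* the true coupling, which
  makes it the natural oracle for the estimator.
- `lvc_model(ω, g, λ, E⁰)`: linear vibronic coupling — harmonic diagonal
  `E⁰_J + Σ ½ω_i²Q_i² + Σ g_{J,i}Q_i`, linear off-diagonal `Σ λ_iQ_i`, in
  mass-weighted coordinates (unit masses by default).

Internally everything is in Hartree atomic units; femtoseconds, eV and
angstrom appear only at I/O boundaries (1 fs = 41.341374575751 au of time).

## The TD-BA estimator

Along a trajectory the only inputs are the signed gaps
`ΔE_JL(t) = E_J − E_L` sampled at the classical timestep. The estimator is

    σ_JL = sgn(ΔE) · ½ · sqrt( (1/ΔE) · ΔE'' )   if (1/ΔE)·ΔE'' > 0, else 0,

with `ΔE''` the second *time* derivative. The positive-argument restriction
screens for approaches to a gap minimum; it is the time-domain residue of the
original spatial model's validity region.

Three interchangeable second-derivative schemes:

- `fd_first_order` — backward O(Δt) stencil `[ΔE(t) − 2ΔE(t−Δt) + ΔE(t−2Δt)]/Δt²`;
- `fd_second_order` — backward O(Δt²) stencil
  `[2ΔE(t) − 5ΔE(t−Δt) + 4ΔE(t−2Δt) − ΔE(t−3Δt)]/Δt²`, automatically falling
  back to the three-point stencil at the first step where only three gaps
  exist;
- `quadratic_regression` — `2a` from an ordinary least-squares fit of
  `ΔE ≈ at² + bt + c` over the last `N_p = ΔT/Δt` points. The window's time
  origin is shifted to its newest point for conditioning; `2a` is
  origin-invariant. While the buffer is still filling, the fit uses whatever
  points exist once at least three are available.

**Warmup.** The gap buffer starts empty and is cleared at every accepted hop:
the coupling is defined to be null during the first two classical steps of a
trajectory (and after any hop) and is first computed at the third step. The
initial (t = 0) geometry does not seed the buffer — gaps accumulate from the
first propagation step — so "the third step" uses the gaps of steps 1–3.
During warmup the hopping probability is automatically zero (σ = 0), which is
adopted as the de facto "no hops during warmup" behaviour.

**Cleaning conditions**, applied in this order (the first triggered wins; the
ordering follows their conventional presentation — no precedence is
physically implied, and in the default configuration only the first is
active):

1. *rate limit* δη (au): if `(|σ(t)| − |σ(t−Δt)|)/Δt > δη`, keep the previous
   coupling. "Previous" means the previous *cleaned* value — the value the
   dynamics actually consumed. The rate is formed in atomic units throughout.
2. *gap ceiling* δε (eV in config, converted internally): zero the coupling
   when `|ΔE| > δε`.
3. *product ceiling* δϖ (au): zero it when `|ΔE·ΔE''| > δϖ`.

The cleaned output is always one of {raw, previous, 0} — cleaning never flips
a sign. Per pair and step a provenance flag records which branch fired.
Defaults mirror the production protocol: quadratic regression with
ΔT = 0.4 fs, δη = 0.1 au enabled, δε and δϖ disabled (their documented
reference values, 12 eV and 0.01 au, are pre-filled for when they are
switched on). These conditions exist to damp artifacts of small energy
discontinuities in on-the-fly electronic structure; the analytic models here
are smooth, so the analytic-model tests exercise the conditions' *mechanics*,
not their curative effect on noisy surfaces.

A standalone post-processor (`bahop couple`, `couplings_from_table`) applies
the estimator to any logged `(time, E_0 … E_{n−1})` table. It cannot know hop
times, so only the start-of-series warmup applies there.

## DC-FSSH engine

Per classical step (velocity Verlet, Δt = 0.1 fs default): nuclear update on
the active surface, new electronic point, coupling evaluation, then
`Δt/Δτ` quantum substeps (Δτ = 0.005 fs default) in which the coefficients

    dc_J/dt = −Σ_K [ (i/ħ)E_J δ_JK + σ_JK ] c_K

are advanced with energies and couplings interpolated linearly to each
substep midpoint. Each substep applies the exact matrix exponential of the
frozen generator — anti-Hermitian by construction, so the propagation is
unitary to rounding (a closed form for two states, an eigendecomposition
otherwise). Norm is asserted to 1e−8 at every classical step.

**Hopping.** At every substep the active state L may hop to J with

    P_{L→J} = max[ 0, −(2Δτ/|c_L|²) · σ_JL · Re(c_J c_L*) ],

the standard fewest-switches flux form: under the propagation equation above,
`−2σ_JL Re(c_J c_L*)` is exactly the rate at which population leaves L toward
J, so P is the fraction of the active population departing during the substep.
(With the opposite index order the probability would vanish precisely when
population flows out of the active state, i.e. nothing would ever hop.) One
uniform draw per substep selects among targets by cumulative intervals in
ascending state index; summed probabilities above 1 are renormalized with a
warning.

**Velocity adjustment.** After an accepted hop the velocity is rescaled along
the linear momentum, `v' = γv` with `γ = sqrt(1 + 2(E_from − E_to)/Σmv²)` —
the only direction available when couplings come from TD-BA, which never
produces an **h** vector. The energies entering the rescale are those of the
surfaces at the *current geometry* (not the substep-interpolated values), so
total energy is conserved exactly across the switch. For exact-coupling
oracle runs, rescaling along **h** is available (`rescale_direction: h`),
solving the usual quadratic and taking the smaller-|γ| root. Hops without
sufficient kinetic energy are frustrated: state and velocity unchanged, the
attempt logged. Frustrated hops do not reverse the velocity (a deliberate,
logged simplest-convention choice).

**Decoherence.** Simplified decay of mixing, applied once per classical step
after the substep loop (the application point within the step is a
convention): inactive coefficients decay with
`τ_J = (ħ/|E_J − E_M|)(1 + α/E_kin)`, α = 0.1 hartree, and the active
coefficient is rescaled to restore the norm. Zero kinetic energy means no
decay (infinite τ, warned). Degenerate pairs never decay.

**Bookkeeping.** A total-energy drift beyond 1e−3 hartree between hops flags
the trajectory (it is reported, never silently kept). Identical (model,
initial conditions, settings, seed) give bit-identical logs; per-trajectory
RNG streams derive from `SeedSequence((master_seed, trajectory_index))`, so a
split ensemble reproduces a single larger run exactly.

## Initial conditions

Ground-state harmonic Wigner sampling: per mode, position and momentum are
independent zero-mean Gaussians with variances `ħ/(2μω)` and `ħμω/2` (the
minimum-uncertainty product `ħ/2`). Samples can be restricted to a
vertical-excitation window `|ΔE_{0,target} − E_c| ≤ ΔE_half` and started on
the target surface — emulating narrow-band excitation. Selection is by energy
window only; no oscillator-strength weighting (the analytic models define no
transition dipoles, which is also why no oscillator-strength observable is
produced). No thermal or anharmonic sampling.

## Ensemble analysis

- **Populations** are classical — the fraction of trajectories whose active
  surface is J — matching standard surface-hopping practice; mean `|c_J|²`
  curves are also available as the internal-consistency diagnostic.
- **Lifetimes**: least-squares fit of `p(t) = exp(−t/τ)` from t = 0 (a fitted
  amplitude is optional, off by default; no latency parameter). 95%
  confidence intervals by percentile bootstrap over trajectories (default
  10,000 repetitions; the validation scripts use 1,000, which converges the
  halfwidth to well within its own noise for the ensemble sizes used).
- **Coupling RMSD**: `sqrt[(1/N) Σ_traj Σ_t (|σ| − |σ̂|)²]` pooled over all
  timesteps of all trajectories.
- **Hop statistics**: accepted hops only, grouped by ordered (from, to) —
  upward and downward transitions are distinct rows — with count, mean |gap|
  and population standard deviation in eV.
- **Overlap score** λ between two observables given as (mean, 95% CI
  halfwidth): the overlap interval is the intersection of the two confidence
  intervals (full containment yields the smaller interval); each observable
  is a Gaussian whose σ makes its CI carry exactly the confidence level;
  λ is the product of the two Gaussian masses over the interval normalized by
  `confidence²` — the maximum the confidence level allows — so identical
  observables score exactly 1. A zero-halfwidth observable is a point mass:
  λ = 1 iff it lies inside the other's interval. Λ is the arithmetic mean of
  λ over observables.
- **Geometry**: mean torsion about an exocyclic C–CH₂ bond,
  `φ = ¼[|φ_cis1| + |φ_cis2| + |180° − φ_trans1| + |180° − φ_trans2|]` with
  every angle folded to (−180°, 180°], and the seam-region classification
  Planar (φ < 30°) / Twisted-stretched (φ ≥ 30°, d ≥ 1.55 Å) /
  Twisted-shrunk (φ ≥ 30°, d < 1.55 Å); boundary values fall on the
  twisted/stretched side by convention. XYZ files are read and dihedrals
  evaluated through MDAnalysis.

## Validation studies and problem sizes

All validation runs use the linear-crossing model with κ = 0.1 hartree/bohr
and Δc = 0.02 hartree; the mass is a free knob that sets the crossing speed.

- *Tracking* (mass 1e5, crossing kinetic energy 0.2 hartree → seam speed
  ≈ 0.002 bohr/au): at these speeds the gap evolves slowly relative to the
  0.4 fs regression window and the velocity is constant through the seam to
  ≪ 1%, the regime the estimator assumes; TD-BA matches v·h at the gap
  minimum to ≈ 1.3%.
- *Turning point* (mass 2e5, kinetic energy tuned so the trajectory turns
  where the gap is still sloped): the velocity vanishes exactly where the gap
  is minimal, so the exact projection v·h → 0 while TD-BA — blind to |v| —
  stays finite. This reproduces the estimator's known failure mode; the
  measured σ_exact/σ_TDBA at the turn is ≈ 1e−3.
- *Landau-Zener scattering* (mass 2000, launch kinetic energy 1.0 hartree,
  2000 trajectories, Δt = 0.02 fs with 10 substeps): the fraction
  transmitted on the upper adiabat is compared with
  `exp(−πΔc²/(4ħκv_c))`, with `v_c` the velocity *at the crossing* obtained
  from energy conservation (the launch velocity overstates the passage speed
  because the lower adiabat rises toward the seam). Decoherence is off for
  this study: Landau-Zener is a coherent single-passage result, and the
  decay-of-mixing correction deliberately suppresses the coherence it relies
  on (with the correction on, the transmitted fraction shifts by ≈ 0.05 —
  a real property of decoherence-corrected FSSH, not an integrator error).
  The finer-than-default timestep resolves the ≈ 0.08 fs coupling peak of
  this deliberately fast passage.
- *Energy conservation* (mass 1e6, 100 fs at Δt = 0.1 fs): drift
  < 1e−6 hartree between hops; every accepted rescale conserves total energy
  to machine precision by construction.
- *Lifetime recovery*: a synthetic 500-trajectory ensemble of step-decay
  trajectories with Exp(100 fs) lifetimes on a 2 fs grid to 400 fs; the
  fitted τ must land inside its own bootstrap CI.

## What the synthetic setups do and do not emulate

The analytic models provide exact oracles and complete control of the
crossing topography, which is what validating an estimator requires. They do
not emulate: multidimensional seams with varying coupling direction (the
TD-BA assumption of a fixed coupling direction is untested beyond 1–2
effective dimensions here), MCSCF-style energy discontinuities (so the
cleaning conditions are exercised mechanically, not curatively), anharmonic
initial-state distributions, or transition-dipole observables. Passing these
tests shows the estimator and engine are implemented correctly and behave as
designed in their regime of validity — not that TD-BA is accurate for any
particular molecule.

## Known limitations

- TD-BA under-resolves fast seam passages at the default Δt = 0.1 fs /
  ΔT = 0.4 fs (the regression window then spans the whole coupling peak);
  population transfer is underestimated there. This is a property of the
  estimator's parameters, visible directly in the worked examples, and the
  reason the scattering validation uses a finer step.
- At turning points TD-BA overestimates the coupling (it cannot see that
  |v| → 0); this is reproduced, not corrected.
- Only pairwise two-state interactions are modelled by the estimator; with
  three or more states each pair is treated independently.
- The hopping-probability flux form assumes the same σ drives both the
  coefficient propagation and the hop test; mixing coupling sources between
  the two would break that consistency and is not supported.
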