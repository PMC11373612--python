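# Methods

## Model and assumptions

The package treats a particle diffusing on a 1D potential W(z) as a minimal
two-state system.  States A and B are the two wells; the kinetics is
characterized by the equilibrium probabilities p_A, p_B, the net steady-state
reactive flux J_AB, the forward/backward rates k_AB = J_AB/p_A and
k_BA = J_AB/p_B, the global relaxation time τ* = 1/μ₂ = 1/(k_AB + k_BA), and
the mean transit time of a reactive crossing ⟨τ_r⟩ = ⟨q(1−q)⟩/J_AB.

Assumptions baked into the quadrature route: overdamped dynamics with
position-independent diffusion coefficient D, equilibrium (detailed balance),
and absorbing committor boundaries z₁ < z₂ inside the evaluation domain.
The committor is then

    q(z) = ∫_{z₁}^{z} e^{W/k_BT} dz′ / ∫_{z₁}^{z₂} e^{W/k_BT} dz′,

and the flux has the closed form J_AB = D/(Z_full·Z_barrier) with
Z_full = ∫ e^{−W/k_BT} dz and Z_barrier = ∫_{z₁}^{z₂} e^{W/k_BT} dz.  The
same quantity is exposed as the variational Dirichlet form
J[q] = ∫ (dq/dz)² D ρ_eq dz, which any trial committor can only overestimate;
this is checked by property tests with randomly perturbed trials.

The Langevin route relaxes the overdamped assumption: with m = 20 amu and
D = 1 Å²/ps the velocity relaxation time mD/k_BT is 0.08 ps, so on longer
time scales the inertial dynamics reduces to the same diffusion.  (The
velocity relaxation time is sometimes written k_BT/Dm; the dimensionally
consistent expression mD/k_BT is used here — with these parameters both
readings evaluate to 0.08 ps.)

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| k_BT | 0.5915 | kcal/mol | benchmark thermal energy (≈297.7 K) |
| D | 1.0 | Å²/ps | benchmark diffusion coefficient |
| m | 20 | amu | benchmark mass; γ = k_BT/mD ≈ 12.4 ps⁻¹ (high friction) |
| z₁, z₂ | −7, +7 | Å | committor boundaries for all three families |
| evaluation domain | [−14, 14] | Å | at z = ±14 the confinement term exceeds 27 k_BT, so the truncated Boltzmann tail is < 1e−10 of Z |
| grid spacing | 0.001 | Å | trapezoid quadrature; halving the spacing moves J_AB by < 0.1% (tested) |
| dt (Brownian) | 0.005 | ps | benchmark time step; dt-halving gives statistically indistinguishable fluxes |
| dt (Langevin) | 0.001 | ps | benchmark time step, ≪ 1/γ |
| unit bridge | 418.4 | amu·Å²/ps² per kcal/mol | converts energies to mechanical units |

Indicator convention everywhere: a point exactly at the dividing surface
belongs to state B (half-open intervals), so H_B = θ(z − z†).

## Estimators

**Correlation functions.**  C_BB, C_zz, C_qq and C_ABqq are multiple-time-
origin averages on stored trajectory frames.  C_BB and C_qq are evaluated via
the stationary identity ⟨vv⟩ − ⟨v(0)v(t)⟩ = ½⟨(v(t) − v(0))²⟩: the increments
of interest are ~1e−4 of the variance, and the squared-increment form avoids
that cancellation entirely (it also makes C_qq with a Heaviside committor
bit-for-bit identical to C_BB, a tested invariant).  C_zz uses the same
kernel through C_zz = p_A p_B·½MSD(t)/⟨δz²⟩.  Standard errors come from
block averaging: 20 contiguous time blocks for a single trajectory, or one
block per walker for ensembles, treated as independent samples.  The error
bars on C_zz do not propagate the uncertainty of the global variance and
p_A p_B normalization; for few-transition runs, per-walker estimates should
be compared instead (the test suite does this where it matters).

**Derivatives and plateaus.**  Derivatives use central differences (one-sided
at the ends).  Their error bars are computed from block-wise derivatives —
naive propagation of per-lag errors overestimates them by an order of
magnitude because C(t) errors are strongly correlated across lags, which
would mask real transients.  The plateau of a derivative series is the
earliest sliding window (default 20 points) whose spread is below
rel_tol·|mean| + err_mult·⟨stderr⟩ (defaults 5% and 4): the second term is
the statistical noise floor, so Monte-Carlo scatter alone cannot produce a
spurious "no plateau".  The reported flux is the error-weighted mean
derivative from the plateau to the last lag; its quoted error is the
between-block spread of the secant slope over that window.  The flux
estimator with no detectable plateau raises an explicit error rather than
returning a number — this is the expected behaviour of the indicator
correlator on a broad flat barrier when the lag range is too short.

Slope-agreement checks use lags up to 60 ps for the Brownian benchmarks.
Two reasons: the narrow-family wells are wide flat basins (the bump is only
0.6 Å wide), so intrawell diffusive modes relax over ~6 ps and the position
correlator approaches its limiting slope slowly; and after those modes decay
the C_zz slope carries a mode-overlap factor slightly below 1, so agreement
with the committor-based slope is expected only within statistical errors,
not exactly.

**Transmission coefficient.**  κ(t) = ⟨v(0)H_B(t)⟩_{z†}/⟨v(0)θ(v(0))⟩ over
Maxwell-distributed shots launched at the dividing surface.  The t → 0⁺
normalization uses the analytic half-Gaussian flux √(k_BT/2πm) instead of a
finite difference, avoiding dt-scale noise; κ(0⁺) = 1 by the half-open
indicator convention.

**Markov models.**  Transition counts at lag τ are symmetrized as
(C + Cᵀ)/2 before row normalization, enforcing detailed balance exactly (a
maximum-likelihood reversible estimator is out of scope; the symmetrized
estimator is adequate for equilibrium trajectories).  The eigenproblem is
solved on the π-symmetrized similarity transform, guaranteeing a real
spectrum in floating point.  Binning default: 120 uniform bins on
[−12, 12] Å; empty bins are dropped with an index map and disconnected
occupied bins are an error.  The generator is estimated as K = (T − I)/τ,
valid when μ₂τ ≪ 1 (true for all benchmarks by 3+ orders of magnitude);
a matrix logarithm is deliberately avoided.  The eigenvector committor uses
basin levels a, b of ψ₂L averaged over core bins (default: bins with
reference committor < 0.05 / > 0.95); averaging is a choice — the
eigenvector is not exactly constant over a basin — and the residuals of the
two-state identities a = −(b−a)p_B and (b−a)²(p_A p_B − ⟨q(1−q)⟩) = 1 are
reported as diagnostics.

**Chapman–Kolmogorov test.**  T(nτ) re-estimated from data is compared with
T(τ)ⁿ through the stationary-weighted mean total-variation distance of the
rows; the pass threshold is 0.1.  A per-entry multinomial z-score criterion
is unusable here: at microsecond statistics, the small systematic artifacts
of *any* binned projection become formally significant, so every case
"fails".  The TV norm instead measures how much probability the propagator
actually misplaces.  For the test to discriminate inertial memory the bin
width must resolve the rms displacement per lag; with matched bins,
Markovian cases (Brownian dynamics at lag = dt; Langevin at lag ≫ 0.08 ps)
give TV ≈ 0.01–0.08 and ballistic-memory cases (Langevin at lag < 0.08 ps)
give TV ≈ 0.13–0.27, so the threshold sits in a wide physical gap.  The
worst multinomial z-score is still reported as a diagnostic.

## Simulation engine and reproducibility

Euler–Maruyama (Brownian) and BAOAB (Langevin) steps run in numba kernels;
Gaussian noise is generated chunk-wise by a seeded numpy Generator outside
the kernels, so trajectories are bit-for-bit reproducible for a given seed
independent of numba's internal RNG.  Batched walkers share one kernel call.
First-passage and committor-shooting runs use numba's per-shot seeded RNG
(deterministic per seed).  Shots exceeding the step cap are counted as
censored and reported, never silently dropped.  Trajectories escaping the
evaluation domain raise an error naming the step index — the symptom of a
too-large time step.  Custom potentials (user-supplied analytic W and dW/dz)
are supported by the quadrature layer; the compiled integrators cover the
closed-form families.

## Scaled-down study sizes

The published benchmark protocol is 1 µs per system.  The test suite and the
acceptance script use: 200 ns of Brownian dynamics per family (5 walkers ×
40 ns, frames every 0.05 ps) for the correlator/MSM cross-checks, and a
0.5 µs aggregate (25 walkers × 20 ns, frames every 0.02 ps) for the
broad-barrier Langevin flux.  These sizes were chosen so that every
stochastic comparison has enough transitions (tens to hundreds) for 3σ
agreement tests to be meaningful while keeping the full suite to a few
minutes on one CPU.  Statistical tolerances in the tests scale with the
block/walker standard errors actually measured, not with fixed percentages.

## What the synthetic benchmarks do and do not show

The double-well families isolate the single feature under study — barrier
shape — under exactly known thermodynamics; passing tests demonstrate the
internal consistency of the three rate formalisms and the correctness of the
estimators on diffusive and inertial 1D dynamics.  They do not probe
multidimensional effects (committor gradients not aligned with a coordinate,
hyperplane dividing surfaces, position-dependent diffusion) or estimator
behaviour on non-equilibrium or poorly sampled data; real molecular data
also violates the exact detailed balance the symmetrized MSM assumes.

## Known limitations

- Committor machinery is strictly 1D; no regression/neural committor models.
- The restricted committor correlator C_ABqq is evaluated from unconstrained
  equilibrium trajectories restricted by indicators; a constrained-ensemble
  sampler launching from the q = q† isosurface would be the local-sampling
  variant and is not implemented.
- Flux extraction quality degrades gracefully but honestly on short runs:
  the plateau detector may legitimately report "no plateau" for C_BB on
  broad barriers at short lag ranges.
- The MSM stationary distribution inherits binning bias O(Δz²) near steep
  potential walls; bin widths below ~k_BT/|W′| avoid it.
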