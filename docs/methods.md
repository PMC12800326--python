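# Methods

## Model

The core is a planar Wilson–Cowan system on Ω = [0,1]², with sigmoidal
recruitment and a second-order decay. All quantities, including time, are
dimensionless; there is no unit-conversion layer. The baseline parameter set
(`ModelParameters.baseline()`: a_EE=10, a_EI=10, a_IE=12, a_II=1, θ_E=3,
μ_E=1.5, θ_I=5, μ_I=2.7, τ_E=τ_I=1, D_E=0.25, D_I=0, q_E=0.75, q_I=0.25) is
chosen so the sole attractor is a small normal-activity limit cycle around a
repelling fixed point. Setting q_E = q_I = 0 recovers the classic
Wilson–Cowan rates exactly (bit-for-bit, covered by test). The relatively
high excitatory sustenance encodes seizure propensity; inhibitory sustenance
is lower and driven by excitatory activity (the q_I·E cross-term), so
inhibitory persistence is slaved to excitation.

Forward invariance of Ω holds for q ∈ [0,1] and any σ_RS ≥ 0: recruitment
vanishes at the upper boundary and decay vanishes at the lower one, so the
flow never points outward. Integrators may probe marginally outside Ω;
accepted steps stay inside, and the public `vector_field` rejects states
outside the closed square beyond 1e-6.

### Dysfunction layers

* **Hyperexcitation** is not a separate code path: it is an elevated net
  drive D_E.
* **Depletion** substitutes the first-order closure I_eff = I(1 − ρI) for I
  in *both* perceived inputs. The windowed-average formulation from which
  this closure derives is not implemented as a delay system; only the
  closure is runtime code.
* **Depolarizing GABA** blends the perception of a chloride-loaded
  subpopulation p = κEI (which perceives GABA with positive sign through
  a_PI) with the standard perception: x_R = p·x_P + (1 − p)·x_E, replacing
  x_E in the excitatory activation only. The formula is used literally,
  without clamping p to [0,1]; when κEI exceeds 1 the convex-combination
  reading becomes an extrapolation, and the model logs a warning once per
  instance. On the orbits relevant to the κ sweeps reported here p stays
  below 1 (verified numerically; clamping does not change the localized
  homoclinic).
* Depletion and depolarizing GABA both redefine the excitatory perception
  and are mutually exclusive by validation; at their neutral settings
  (ρ=0, κ=0) every layer reduces to the base model bitwise.

### Intervention layers

* **GABAergic enhancement** multiplies the a_EI term of the excitatory
  activation argument by σ_GABA. Composed with depletion the amplified term
  is σ_GABA·a_EI·I_eff. Composed with depolarizing GABA, σ_GABA scales only
  the a_EI term inside the blend: benzodiazepines amplify the receptor
  effect, but the a_PI term represents that same receptor acting
  excitatorily on the chloride-loaded subpopulation, and the qualitative
  behaviour of interest (enhancement barely moves the nullclines in this
  regime) is insensitive to the choice; the unscaled-a_PI convention is the
  package's and is pinned by a unit test.
* **Rhythmic suppression** replaces (q_E, q_I) with (q_E − σ_RS, q_I − σ_RS).
  Negative effective coefficients are deliberate — a negative net
  second-order decay lowers firing during seizure — so the suppressed
  coefficients bypass the [0,1] validation that applies to stored q values.
  Per-population overrides (`q_E_suppression`, `q_I_suppression`) exist on
  the config for asymmetric studies; the scenario presets use the single
  scalar.

Composition order is fixed (dysfunction defines the perception, intervention
rescales within it), making every composed model deterministic.

## Numerical methods

**Equilibria.** Damped Newton (analytic Jacobian, step capped at 0.2,
iterates clipped to [−0.2, 1.2]²) from a uniform 50×50 multistart lattice;
converged roots (residual < 1e-11) are deduplicated within 1e-6 and
classified by Jacobian eigenvalues. Eigenvalue real parts within 1e-8 of
zero are labelled `degenerate` rather than forced into a class. The
multistart count is cross-checked against an independent 400×400
sign-change grid scan with local refinement (test oracle).

**Roles.** Activation below 0.05 is read as the lower asymptote, above 0.95
as the upper asymptote, else transition — a numerical reading of the
visually defined segments; 5% bands are the conventional choice. A seizure
is an attractor with both activations in the upper band; normal activity is
the minimal-activity attractor with both in the transition band; limit
cycles are classified by the time-mean of their activations along the orbit
(the activation at the orbit's mean state is not representative for the
strongly non-sinusoidal normal cycle). Two consequences worth knowing: an
attractor born at a fold may briefly sit below the 0.95 band before the
seizure label attaches, and under strong rhythmic suppression the seizure
attractor's activation genuinely drops below the band before its fold —
in both cases the branch is tracked by stability, not label. Borderline
classifications (within 1e-3 of a band edge) raise an explicit ambiguity
error instead of guessing.

**Integration.** LSODA with rtol 1e-8, atol 1e-10 throughout (manifold
shots use 1e-12/1e-14); ramped parameters enter via piecewise-linear
interpolation of named config keys. Limit cycles are detected by upward
crossings of the Poincaré section E = E* anchored at the inner fixed point;
the cycle is accepted when successive returns agree within 1e-6 in state
space, the period is the median of the last five return intervals, and
cycle extrema/period are invariant to tolerance halving within 0.1%
(tested). The cycle-existence predicate seeds at the inner repeller +
(1e-3, 0) and gives up after 2000 time units.

**Saddle-node localization.** Bisection on the equilibrium count to a
bracket ≤ 1e-4, then Newton on the extended system (f = 0, det J = 0)
seeded from the coalescing pair, so |det J| at every reported fold is at
numerical zero (< 1e-6 asserted, ~1e-15 in practice).

**Saddle-homoclinic localization.** Two routes, used together. The robust
route bisects the cycle-existence predicate. The precise route measures a
split function: the saddle's unstable manifold is shot forward and its
stable manifold backward (seeded 1e-8 along the oriented eigenvectors) onto
the section through the inner repeller perpendicular to the repeller–saddle
axis; the signed gap between the two first same-side hits changes sign
exactly at the homoclinic connection. The split function exists only near
the bifurcation (far from it the stable manifold leaves Ω instead of
winding around the repeller), so the predicate bisection brackets first and
the split function refines to ~1e-6; if refinement is unavailable the
predicate bracket (≤ 1e-4) is reported. The two routes agree to ~1e-5 on
all three homoclinics, and the diverging cycle period / shrinking
cycle-to-saddle distance on approach are computed as corroborating
evidence.

**Termination thresholds.** The seizure attractor is continued in the
intervention parameter via the predicate "an attracting equilibrium
exists" (in the regimes swept, normal activity is a limit cycle, so the
only attracting fixed point is the seizure one — asserted at the sweep
start), bisected to ≤ 1e-4 and polished on the extended fold system. A
sweep in which the attractor survives the whole range returns an explicit
no-termination result, which is the expected outcome for GABAergic
enhancement under depolarizing GABA.

**Ramp experiments.** Time-series presets follow the hold / 50-unit linear
ramp / hold window pattern of the drive experiment; for the sweeps whose
exact ramp windows are not prescribed, the same pattern is the package's
choice and the knots are exposed in the scenario config. The seizure jump
under a ramp lags the static bifurcation value (a dynamic
bifurcation-delay effect): the escape window — from the last completed
oscillation to the crossing of the instantaneous saddle — brackets the
static homoclinic value, and its midpoint maps back to within 2% at the
standard ramp rate (tested, with the window width reported as the measured
lag).

## Synthetic regression fixtures

`generate_fixtures(seed, n)` draws n multiplicative ±10% perturbations of
the baseline parameters (uniform, seeded; q clipped to ≤ 1), settles each
model from (0.1, 0.1) for 400 time units and records the attained regime.
The unperturbed baseline (normal) and a D_E=4 variant (seizure) are always
included. This corpus emulates parameter uncertainty around one operating
point only — it makes no claim about physiological parameter ranges, noise,
or network effects, so passing it shows refactor stability, not clinical
validity.

## Problem sizes and runtime

Defaults are sized for a single CPU: 50×50 multistarts, 400-point orbit
sampling, 2000-time-unit cycle searches, continuation steps 0.02–0.05.
Every sweep in the acceptance path runs in seconds; the full nine-value
recomputation takes about half a minute.

## Known limitations

* No stochastic forcing: in a noise-free model the system leaves a seizure
  only when the attractor is destroyed, so bistable regimes overstate
  seizure persistence relative to a noisy brain.
* No shunting inhibition, synchronization, multi-population networks, or
  EEG feature mapping; the two attractor classes are a deliberately coarse
  reading of brain state.
* The depletion closure drops the history dependence of the windowed
  average; fast transients in I are felt instantaneously.
* Natural-parameter continuation with bisection suits the simple fold
  structure here; it would need replacing (pseudo-arclength) for branches
  that fold back in the sweep parameter.
* The printed critical values this package is checked against carry finite
  precision of their own; the homoclinic points especially are sensitive to
  the localization method, and the package reports its own split-function
  values with bracket widths rather than adopting any external rounding.
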