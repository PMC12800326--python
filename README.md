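# wcseizure

Seizure onset and termination in a sustenance-extended Wilson–Cowan model,
with a one-parameter bifurcation engine for localizing the transitions that
govern them.

## The scientific problem

Epileptic seizures are episodes of persistent, runaway neuronal firing.
Benzodiazepines terminate most prolonged seizures (status epilepticus) by
enhancing GABAergic inhibition, but roughly a third of cases are refractory —
notably when chloride accumulation makes GABA itself depolarizing. This
package implements a phenomenological two-population neural mass model in
which distinct pathophysiological dysfunctions (hyperexcitation, depletion of
inhibitory neurotransmitter, depolarizing GABAergic transmission) and distinct
interventions (GABAergic enhancement, suppression of rhythmic firing) act as
parameter changes on one dynamical landscape, so that the match — or
mismatch — between dysfunction and treatment becomes a statement about
bifurcations.

## The model

State variables `E, I ∈ [0, 1]` are the fractions of excitatory and
inhibitory neurons firing at dimensionless time `t`. Quiescent neurons
perceive inputs

    x_E = a_EE·E − a_EI·I + D_E        x_I = a_IE·E − a_II·I + D_I

and are recruited through sigmoids `A = (1 + exp(−θ(x − μ)))⁻¹`. The classic
linear decay is replaced by a second-order decay controlled by *sustenance*
coefficients `q_E, q_I ∈ [0, 1]` that encode the propensity for
self-perpetuating firing:

    dE/dt = τ_E ( A_E (1 − E) − E (1 − q_E E) )
    dI/dt = τ_I ( A_I (1 − I) − I (1 − q_I E) )

Note the cross-term: inhibitory sustenance is driven by excitatory activity.
*Normal activity* is the attractor (usually a limit cycle) at the first
intersection of the transition segments of the two nullclines; a *seizure*
is the attractor where both activations saturate — excitation that maximal
inhibition cannot control.

Layers composed onto this core:

| layer | mechanism | parameter |
|---|---|---|
| hyperexcitation | elevated drive | `D_E` |
| depletion | effective inhibition `I_eff = I(1 − ρI)` in both inputs | `ρ ∈ [0,1]` |
| depolarizing GABA | fraction `p = κEI` perceives `x_P = a_EE·E + a_PI·I + D_E`; blend `x_R = p·x_P + (1−p)·x_E` | `κ ≥ 0`, `a_PI` |
| GABAergic enhancement | `x_E = a_EE·E − σ_GABA·a_EI·I + D_E` | `σ_GABA` (neutral 1) |
| rhythmic suppression | `q → q − σ_RS` in both populations | `σ_RS` (neutral 0) |

As a dysfunction parameter grows, the seizure attractor is born in a
saddle-node bifurcation (bistability), and normal activity is destroyed in a
saddle-homoclinic bifurcation (onset). Termination means the reverse fold:
an intervention annihilating the seizure attractor against its saddle.

## Worked example

```python
from wcseizure import (SeizureModel, DysfunctionConfig, find_equilibria,
                       find_limit_cycle, locate_saddle_homoclinic,
                       termination_threshold)

model = SeizureModel.baseline()
cycle = find_limit_cycle(model)
print(f"normal activity: limit cycle, period {cycle.period:.3f}, "
      f"E in [{cycle.E_min:.3f}, {cycle.E_max:.3f}]")

for eq in find_equilibria(model.with_param("D_E", 2.0)):
    print(f"(E*, I*) = ({eq.E:.4f}, {eq.I:.4f})  {eq.stability:9s} {eq.role}")

onset = locate_saddle_homoclinic(model, "D_E", (1.5, 2.0))
print(f"seizure onset (saddle-homoclinic): D_E = {onset.value:.5f} "
      f"+/- {onset.bracket_width:.1e}")

depol = SeizureModel(model.params, DysfunctionConfig(kappa=1.8, a_PI=5.0))
gaba = termination_threshold(depol, "sigma_GABA", (1.0, 3.0))
rs = termination_threshold(depol, "sigma_RS", (0.0, 2.0))
print(f"GABAergic enhancement terminates: {gaba.found}")
print(f"rhythmic suppression terminates at sigma_RS = {rs.point.value:.5f}")
```

prints

```
normal activity: limit cycle, period 5.696, E in [0.038, 0.311]
(E*, I*) = (0.2507, 0.3336)  repeller  other
(E*, I*) = (0.5005, 0.5334)  saddle    other
(E*, I*) = (0.6646, 0.5453)  attractor seizure
seizure onset (saddle-homoclinic): D_E = 1.77749 +/- 5.0e-07
GABAergic enhancement terminates: False
rhythmic suppression terminates at sigma_RS = 1.35375
```

Reading: at baseline the only attractor is a small oscillation (healthy,
minimal non-zero activity). At drive `D_E = 2` the seizure fixed point is the
sole attractor, with the saddle and repeller as non-attracting barriers.
Raising the drive past `D_E ≈ 1.777` destroys the normal-activity cycle —
that is seizure onset. Under depolarizing GABA no amount of GABAergic
enhancement in `[1, 3]` removes the seizure attractor (the benzodiazepine-
refractory case), while rhythmic suppression — counteracting sustenance, as
levetiracetam or phenytoin do — terminates it at `σ_RS ≈ 1.354`.

## Command line

```bash
wcseizure scenario list
wcseizure scenario hyperexcitation-sweep --out out/ --self-check
wcseizure simulate --out run.csv --ramp "D_E=40:0.25,90:2.75"
wcseizure threshold --param sigma_RS --range 0 2 --config depol.yaml
wcseizure equilibria --config cfg.yaml
wcseizure nullclines --out nullclines.csv
wcseizure fixtures --seed 0 --n 10 --out fixtures.json
```

Configs are flat YAML/JSON keyed by the model symbols
(`a_EE, theta_E, mu_E, tau_E, D_E, q_E, rho, kappa, a_PI, sigma_GABA,
sigma_RS, ...`).

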