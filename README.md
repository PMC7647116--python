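# puckslide

Generative modelling and hierarchical Bayesian inference for a puck-sliding
visuomotor task: do people scale their actions the way Newtonian physics
demands, and can they transfer masses inferred from watching collisions into
subsequent motor control?

## The task and the models

A simulated puck of mass *m* rests at a random distance Δx ∈ [1, 5] m from a
target on a surface with friction coefficient μ. A button press of duration
*t* applies a constant force *F*, releasing the puck at *v₀ = F t / m*;
friction then decelerates it at μg. The press-time that lands the puck on
the target is

  T = (m / F) · √(2 μ g Δx),

linear in mass, square-root in distance. An experiment has four phases:
masked "prior" trials, a "feedback" phase with two pucks of different masses
alternating every four trials, a "no-feedback" phase with a new unseen puck,
and a final phase that precedes further no-feedback trials with a movie of
24 frictionless elastic collisions between the new puck and the two familiar
ones.

The **interaction model** is a hierarchical Bayesian account of press-times:
subject *j* perceives the distance with multiplicative log-normal
(Weber–Fechner) noise σ_x, maps the percept to an intended press-time via
either the Newtonian square-root law (with a per-puck mass belief m\_{j,k})
or a linear heuristic (t ∝ x), and emits a press-time with log-normal motor
noise σ_t. A cost function fixes which statistic of the emitted distribution
equals the intention: mode (0-1 loss), median (absolute), or mean
(quadratic). Inverting this generative model by MCMC yields posteriors over
mass beliefs, σ_t, σ_x, and per-trial percepts. The **observation model**
infers the unfamiliar puck's mass from the collision movie: velocities are
perceived with log-normal noise (σ_vel = 0.2, mode at the true velocity) and
the elastic-collision equations tie perceived velocities and masses
together. Model classes are compared with product-space (trans-model) MCMC,
whose index-variable odds equal the Bayes factor, alongside
Kolmogorov–Smirnov and Kullback–Leibler checks of posterior-predictive
press-times and a Bayesian change-point analysis of learning curves.

No human dataset ships with the package; a first-class synthetic-data module
generates cohorts with the study's full structure (16 subjects, two mass
conditions with feedback-phase masses 1.5/2.0 kg and 2.0/2.5 kg, 50/200/100
trials per phase plus 24 collisions, σ_t per subject in 0.15–0.33), which
the test-suite uses for parameter- and model-recovery checks.

## Worked example

```python
from puckslide import EnvironmentParams
from puckslide.synthetic import make_cohort, simulate_cohort
from puckslide.interaction import (InteractionModelSpec, MCMCSettings,
                                   fit, fix_nuisance, residual_analysis)
from puckslide.comparison import ProductSpaceSpec, product_space_bayes_factor

env = EnvironmentParams()                      # mu=0.2, g=9.81, F=10 N
profiles = make_cohort(2, seed=5)              # two synthetic subjects
trials, collisions = simulate_cohort(profiles, env)
fb = trials[trials.phase == "feedback"]

spec = InteractionModelSpec(cost_function="quadratic",
                            mcmc=MCMCSettings(chains=2, warmup=200, draws=300, seed=3))
post = fit(fb, spec)
for prof in profiles:
    mp = post.subjects[prof.subject_id].map_params()
    print(f"{prof.subject_id} ({prof.condition}): "
          f"m_red = {mp['m[red-dots]']:.3f} kg, m_yellow = {mp['m[yellow-diamond]']:.3f} kg, "
          f"sigma_t = {mp['sigma_t']:.3f} (true {prof.sigma_t:.3f})")
print(f"pooled sigma_x MAP = {fix_nuisance(post).sigma_x:.3f} m")
print(f"residual Spearman rho = {residual_analysis(post, fb, spec).rho:.3f}")

ps = ProductSpaceSpec(mcmc=MCMCSettings(chains=2, warmup=150, draws=300, seed=6))
lin = InteractionModelSpec(model_class="linear", sigma_x_fixed=0.05)
new = InteractionModelSpec(model_class="newtonian", sigma_x_fixed=0.05)
rep = product_space_bayes_factor(fb, lin, new, ps)
print(f"Bayes factor K (newtonian : linear) = {rep.K:.3g} -> {rep.interpretation}")
```

prints

```
s01 (light-to-heavy): m_red = 1.483 kg, m_yellow = 2.047 kg, sigma_t = 0.160 (true 0.154)
s02 (heavy-to-light): m_red = 2.034 kg, m_yellow = 2.437 kg, sigma_t = 0.205 (true 0.205)
pooled sigma_x MAP = 0.048 m
residual Spearman rho = -0.032
Bayes factor K (newtonian : linear) = 1.44e+06 -> substantial evidence for the Newtonian model
```

The fitted mass beliefs land within a few percent of the simulated masses
(1.5/2.0 kg and 2.0/2.5 kg), the per-subject press-time variability is
recovered, the pooled perceptual noise sits at the generating 0.05 m, the
residuals of the matched model carry no distance trend, and with 200
informative feedback trials the trans-model sampler leaves essentially no
posterior mass on the linear heuristic (the Bayes factor is a lower bound:
the model index never visits the losing model).

## Command line

`puckslide simulate-cohort | fit-interaction | fit-observation |
compare-models | change-point | validate | run-all` — each a thin wrapper
over the library. `run-all` drives the whole synthetic replication
(generate → fit feedback phase for both classes and cost functions → fix
nuisance parameters → fit remaining phases → Bayes factors per phase subset
→ observation model) from a YAML config and writes a manifest for exact
replay.

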