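# Methods

## Physical model

A puck (mass *m*) slides one-dimensionally under kinetic friction
(coefficient μ, gravity *g*). A button press of duration *t* applies a
constant force *F*; by impulse–momentum the release velocity is
*v₀ = F t / m*, and the sliding distance under constant deceleration μg is
*v₀² / (2 μ g)*. Inverting the chain gives the ideal press-time
*T = (m/F)·√(2 μ g Δx)*. Only relative quantities are identifiable from
behaviour — press-times constrain *m/F·√μg*, not the constants separately —
so μ = 0.2, g = 9.81 m/s², F = 10 N and dt = 1/60 s are conventions, all
overridable in `EnvironmentParams`. Masses inferred by the models are
therefore "effective" masses in the units fixed by these conventions; with
generator and fitter sharing them, recovery is exact in expectation.

`simulate_slide` advances per display frame: `v ← v − μg·dt`, displacement
advanced by the trapezoid of the frame's start/end velocities. Because the
velocity decays linearly between frames, the trapezoid is exact: the frame
simulation agrees with the closed form to rounding error at any frame rate
(a plain rectangle update would carry a v₀·dt/2 half-frame bias, ~0.2% at
task speeds). The final partial frame is truncated analytically so the
displacement never overshoots. Collisions are head-on, one-dimensional,
perfectly elastic (restitution 1) and frictionless; momentum and kinetic
energy are conserved to machine precision by the closed-form solution.

Display geometry: 1080 vertical pixels correspond to ≈11.5 m of simulated
surface (≈93.9 px/m); all stored quantities are SI, pixel values derived.

## Generative model of press-times (interaction model)

For trial *i* of subject *j* with puck *k*:

    x_per ~ LogNormal(ln x + σ_x², σ_x)          percept, mode at the true x
    t_int = (m_jk / F) √(2 μ g x_per)            Newtonian class
          = c_jk · x_per                          linear heuristic class
    t_pre ~ LogNormal(ln t_int + s(σ_t), σ_t)    motor noise

Anchoring the percept's *mode* at the true value keeps percepts unbiased in
the modal sense while giving Weber–Fechner scaling (SD proportional to
magnitude). The same convention is used for velocity percepts in the
observation model, where it is the stated choice; we adopt it for distance
for consistency.

The cost shift *s* encodes the decision rule. For a log-normal with
parameters (μ, σ): mode = e^{μ−σ²}, median = e^{μ}, mean = e^{μ+σ²/2}.
Requiring that the statistic optimal under the 0-1 / absolute / quadratic
loss equal the intention gives s = +σ_t², 0, −σ_t²/2 respectively. The
linear class is given one factor per puck when fitted, mirroring one mass
per puck in the Newtonian class, so the model comparison is between equally
flexible families.

Priors: masses and linear factors ~ gamma (mean 2 kg / SD 2 kg; mean
0.3 s/m / SD 0.3), σ_t ~ gamma (mean 0.25 / SD 0.25), σ_x ~ gamma with
shape 3, rate 40 — mode 0.05, the canonical ~5% Weber fraction for visual
distance estimation. All hyperparameters are configurable.

**Identifiability of σ_x.** In log space the percept enters the press-time
mean linearly, so the marginal of ln t_pre is Gaussian with variance
σ_t² + b²σ_x² (b = ½ Newtonian, 1 linear). With σ_x ≈ 0.05 and σ_t ≈ 0.25,
σ_x contributes well under 1% of that variance: σ_x is essentially
unidentified from press-times and its posterior reproduces its prior. The
pooled σ_x reported by `fix_nuisance` is therefore a prior-consistency
statement, not a data-driven estimate; analyses that matter (masses, σ_t,
model comparison) are insensitive to it, which we verified by fitting with
σ_x fixed and free.

## Sampler

All conditional structure is exploited rather than relying on a generic
sampler:

- **Percept latents.** Given the scalars, each trial's log-percept has an
  exact Gaussian full conditional (precision 1/σ_x² + b²/σ_t²); all latents
  are refreshed jointly by vectorised exact Gibbs every sweep.
- **Masses / linear factors.** Independence Metropolis–Hastings with the
  Gaussian full conditional under a flat log-scale prior as proposal; the
  accept step corrects for the gamma prior, acceptance is near one and
  draws are nearly i.i.d.
- **σ_t.** Adaptive random-walk Metropolis on ln σ_t (several moves per
  sweep), targeting ≈44% acceptance during warmup.
- **σ_x.** Conditional updates barely move because σ_x and the latent
  spread are tightly coupled. The sampler instead moves (σ_x, all latents)
  jointly in non-centred form — latents' standardized residuals held fixed,
  z′ = ln x + σ_x′² + (z − ln x − σ_x²)(σ_x′/σ_x) — with two global
  independence proposals from the σ_x prior plus three local random-walk
  moves per sweep. The percept-prior terms cancel against the
  transformation Jacobian, leaving only the press-time likelihood (and, for
  local moves, the prior ratio) in the acceptance.

Subjects are fitted independently (parameters and latents are
subject-specific); two chains with overdispersed starts by default.
Convergence is flagged when split-chain R-hat ≥ 1.01 or bulk ESS ≤ 400 for
any free parameter (computed with arviz); σ_x, mixing at an effective rate
of a few hundred draws per thousand, occasionally trips the ESS threshold —
the fit warns rather than fails, and the reported posteriors are stable
under longer runs.

**MAP extraction.** The highest-density posterior draw is reported as the
MAP. Ranking draws by the *joint* density including per-trial latents is
degenerate — the joint is unbounded as σ_x → 0 (a spike with vanishing
mass), and empirically always selects the smallest σ_x draw. Draws are
instead ranked by the exact marginal scalar posterior (percepts integrated
analytically). MAP percepts, where needed, are the mode of the latent
conditional at the MAP scalars.

Following the study's two-stage design, nuisance variabilities are
estimated from the feedback phase (the only phase where they are cleanly
separable from mass uncertainty) and held fixed — per-subject σ_t MAPs and
one pooled σ_x — for the prior, no-feedback and post-collision phases.

## Residual analysis and cost-function comparison

Residuals are observed minus predicted press-times, the prediction being
the intended press-time at the MAP parameters and MAP percepts (the
deterministic node of the model); the pooled Spearman correlation of
residuals with the true initial distance is the misfit diagnostic. A
misspecified functional form leaves a strong signed trend (linear fit to
square-root data: ρ ≈ −0.66 at cohort scale); a matched fit leaves |ρ|
small.

A caveat this package makes explicit: because the cost shift is a constant
in log space, it is absorbed exactly by the fitted mass/factor — the three
cost-function fits are likelihood-equivalent and differ only in the mass
estimate. Consequently (i) the decisive cost-function diagnostic is mass
accuracy (on quadratic-generated cohorts the quadratic fit's
condition-level mass error is ~1.5%, versus ~3.5% for absolute and ~9.5%
for 0-1, reflecting biases of e^{−σ²/2} and e^{−1.5σ²}); and (ii) the rank
correlation of residuals with distance tracks whether the prediction
matches the conditional *median* of press-times, which structurally favours
the absolute-loss fit on any generator (the quadratic fit retains an
intrinsic ρ ≈ −(1 − e^{−σ_t²/2})-scaled trend). The residual diagnostic
separates model classes sharply; it cannot, by itself, separate cost
functions within a class.

## Observation model (collision mass inference)

Observed data per collision: true pre-velocities v_F, v_NF, outcome
velocities u_F, u_NF, and the known puck's simulated mass. Latents: the
perceived pre-velocities of every collision and the three masses — the two
known pucks' believed masses under informative priors (moment-matched
gammas from the interaction-model posteriors; a raw-sample KDE prior is
available behind a switch) and the unknown mass m_NF under the
weakly-informative mass prior. Percept noise is log-normal on speed with
σ_vel = 0.2 and mode at the true value; a percept cannot flip a velocity's
sign. The perceived pre-velocities and the masses determine a predicted
outcome through the elastic-collision equations, and the observed outcome
velocities are modelled as mode-anchored log-normal around that prediction
— the single identifiable reading of a network in which the outcome
percept has both the true outcome and the physics prediction as parents.
In the σ_vel → 0 limit with point mass priors the posterior collapses onto
the algebraic solution m_NF = m_F (v_F − u_F)/(u_F + v_F − 2 v_NF).

Sampling: vectorised random-walk Metropolis on the log-speed percepts
(collisions are conditionally independent given the masses) interleaved
with scalar updates of the three log-masses; because mass and percepts are
ridge-coupled, four full update cycles are run per recorded draw.

Movies default to 12 collisions per known puck in random order, known puck
approaching at U(0.5, 2.5) m/s, unknown puck at rest (both configurable; the
original movie statistics are not recoverable). With 24 collisions at
σ_vel = 0.2 and truthful known-mass priors the posterior mean lands within
a few percent of the true mass; the posterior variance decreases from 6 to
24 collisions and remains above the input prior variance — observation is
a noisier channel than interaction.

## Model comparison

**Product space.** A trans-model chain carries the parameters of both
classes plus an index choosing the active model; with equal prior model
probabilities the posterior index odds are the Bayes factor. The
press-time likelihood is used with the percept integrated analytically
(exact, since ln t_pre is Gaussian given the scalars) — this changes
nothing about the Bayes factor and lets the index mix. Pseudo-priors for
the inactive model are normal, moment-matched to short pilot single-model
runs (SD floored at 0.02). Subjects are independent with subject-specific
parameters, so the cohort Bayes factor is the product of per-subject
factors. When the data are decisive the index never visits the losing
model; the factor is then reported as the bound implied by half-counts and
flagged. K = 1 marks equipoise and K = 3.2 the conventional boundary of
substantial evidence.

**Distribution checks.** Two-sample Kolmogorov–Smirnov (scipy) between
observed and posterior-predictive press-times, the latter regenerated
through the full generative path (fresh percepts, cost shift, motor noise)
for each retained draw. KL(observed ‖ predictive) uses a shared 50-bin
histogram over the pooled range with one pseudo-count per bin; the
estimator is biased upward by smoothing at small samples but ordering
between models is stable.

**Change point.** y_t ~ N(μ₁, σ) for t ≤ τ, N(μ₂, σ) after, uniform prior
on τ, conjugate N(data mean, 5×data SD) priors on the levels, σ shared and
marginalised over a 40-point log-spaced grid with a log-uniform prior. The
levels integrate in closed form, so the τ posterior is exact enumeration;
the series is centred first to avoid cancellation on near-constant input.
A near-uniform τ posterior (entropy above 95% of uniform) is flagged as
diffuse rather than treated as an error.

## Synthetic cohorts

`make_cohort` draws subjects with σ_t ~ U(0.15, 0.33), σ_x = 0.05, a prior
mass belief ~ gamma (mean 2 kg, SD 0.5 kg), and condition assignment split
half/half; all per-subject and per-phase randomness derives from one cohort
seed via named substreams. Phases follow the study structure: 50 masked
prior trials (one black puck), 200 feedback trials with two pucks
alternating every four trials (red-dots lighter, yellow-diamond heavier;
1.5/2.0 kg or 2.0/2.5 kg by condition), 100 no-feedback trials with the
rings puck (2.5 or 1.5 kg), and 24 collisions before 100 further
no-feedback trials.

During feedback, mass beliefs update by a conjugate-style running mean of
the masses implied by each observed stopping distance
(m_obs = F·t/√(2 μ g d_obs)), with prior pseudo-count 2 — beliefs move most
of the way to the truth within a handful of trials, consistent with rapid
stabilisation of the error curve; the update rule is a plug-in. Entering
the no-feedback phase the rings belief defaults to the mean of the two
learned beliefs; after the collision movie it is replaced by the median
mass implied by noisily perceived collisions (σ_vel-scaled), a lightweight
stand-in for the full perceptual inference. Ground-truth latents (percepts,
intentions, belief trajectories) are stored in a sidecar table, never in
the observable trial table.

What the generator does *not* emulate: reaction times, fatigue and memory
decay across phases, sequential (trial-order) dependencies beyond belief
learning, 2-D geometry, and any rendering. Passing recovery tests therefore
show that the inference machinery is correct and well calibrated under the
model's own assumptions at realistic noise levels — not that the model is
an adequate description of human data.

## Problem sizes and reproducibility

Recovery analyses run at the study's scale: 16 subjects × 200 feedback
trials for parameter recovery and cost-function comparison; 10 seeded
replicates for model-selection recovery and for the 6-vs-24-collision
variance comparison. Default chains are short (2 × 500–1000 draws after
warmup) — sufficient because the Gibbs/independence updates make most
parameters nearly i.i.d. — and every entry point takes explicit seeds, so
reruns are bit-identical. The pipeline writes a manifest (config hash,
package version, stage outputs) for exact replay; summary tables contain no
timestamps and are byte-identical across reruns.

## Known limitations

- σ_x is prior-dominated (see above); treat its posterior as a prior echo.
- Cost functions are distinguishable only through mass accuracy, not
  through residual correlations or predictive fit (exact shift absorption).
- The product-space Bayes factor saturates to a bound on decisive synthetic
  data; comparing bounds across datasets is not meaningful beyond "decisive".
- Empirical-sample mass priors are moment-matched to gammas by default;
  heavy-tailed interaction posteriors would be summarised optimistically
  (the KDE switch avoids this at some cost in speed).
- The observation model assumes perfect memory of phase-2 mass beliefs and
  no bias from pre-collision guesses; both are deliberate idealisations.
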