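"""Synthetic behavioural data for the puck-sliding task.

The generator emulates the study design the analysis modules assume: a cohort
of subjects split between two mass conditions, each running four phases —

1. ``prior``: 50 trials with an unknown black puck, motion masked (no
   feedback); press-times reflect only prior beliefs.
2. ``feedback``: 200 trials with two pucks (red-dots = lighter,
   yellow-diamond = heavier) alternating every four trials; the sliding is
   shown, so subjects update their mass beliefs from the observed outcomes.
3. ``no_feedback``: 100 trials with a new puck (rings), no feedback; subjects
   fall back on the average of the two learned beliefs.
4. ``collisions_no_feedback``: a movie of 24 frictionless elastic collisions
   (12 with each known puck) followed by 100 more no-feedback trials with the
   rings puck, now using the mass belief inferred from the collisions.

A subject perceives the target distance with multiplicative (Weber–Fechner)
log-normal noise, maps the percept to an intended press-time with either the
Newtonian square-root law or a linear heuristic, and emits an actual
press-time with log-normal motor noise whose cost-optimal statistic (mode /
median / mean for 0-1 / absolute / quadratic loss) equals the intention.
Ground-truth latents (percepts, intentions, belief trajectories) are recorded
alongside the observables so recovery tests can compare.

In the two conditions the pucks slid in phase 2 have masses (1.5, 2.0) kg
("light-to-heavy") or (2.0, 2.5) kg ("heavy-to-light"); the rings puck has
mass 2.5 or 1.5 kg respectively.  Initial distances are i.i.d. uniform on
[1, 5] m.  Per-subject press-time variability is drawn from [0.15, 0.33]
(log-scale), and perceptual noise defaults to 0.05 for all subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .physics import (
    EnvironmentParams,
    PuckSpec,
    collision_implied_mass,
    elastic_collision,
    ideal_press_time,
    release_velocity,
    simulate_slide,
)

__all__ = [
    "CONDITIONS",
    "CONDITION_MASSES",
    "FEEDBACK_PUCK_ORDER",
    "PHASES",
    "PHASE_TRIALS",
    "ParticipantProfile",
    "ProfileDistributions",
    "TrialRecord",
    "CollisionEvent",
    "ConjugateMassLearner",
    "make_cohort",
    "perceive_distance",
    "intended_press_time",
    "cost_shift",
    "emit_press_time",
    "run_phase",
    "generate_collisions",
    "observe_collisions_belief",
    "run_subject",
    "simulate_cohort",
    "trials_to_frame",
    "collisions_to_frame",
]

CONDITIONS = ("light-to-heavy", "heavy-to-light")

# True simulated masses per puck and condition.  The rings puck (phases 3/4)
# is heavier than both feedback pucks in light-to-heavy and lighter in
# heavy-to-light.  The black puck of the masked prior phase never shows its
# motion; its mass (set to the lighter feedback mass) only affects the
# never-displayed ground-truth outcome.
CONDITION_MASSES = {
    "light-to-heavy": {"black": 1.5, "red-dots": 1.5, "yellow-diamond": 2.0, "rings": 2.5},
    "heavy-to-light": {"black": 2.0, "red-dots": 2.0, "yellow-diamond": 2.5, "rings": 1.5},
}

FEEDBACK_PUCK_ORDER = ("red-dots", "yellow-diamond")
FEEDBACK_BLOCK = 4

PHASES = ("prior", "feedback", "no_feedback", "collisions_no_feedback")
PHASE_TRIALS = {"prior": 50, "feedback": 200, "no_feedback": 100, "collisions_no_feedback": 100}
PHASE_PUCKS = {
    "prior": ("black",),
    "feedback": FEEDBACK_PUCK_ORDER,
    "no_feedback": ("rings",),
    "collisions_no_feedback": ("rings",),
}

MODEL_CLASSES = ("linear", "newtonian")
COST_FUNCTIONS = ("zero_one", "absolute", "quadratic")


@dataclass
class ParticipantProfile:
    """Ground-truth generative parameters of one synthetic subject."""

    subject_id: str
    condition: str
    model_class: str = "newtonian"
    cost_function: str = "quadratic"
    sigma_t: float = 0.25
    sigma_x: float = 0.05
    mass_beliefs: dict[str, float] = field(default_factory=dict)
    linear_factor: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.model_class not in MODEL_CLASSES:
            raise ValueError(f"unknown model_class {self.model_class!r}")
        if self.cost_function not in COST_FUNCTIONS:
            raise ValueError(f"unknown cost_function {self.cost_function!r}")
        if self.sigma_t <= 0 or self.sigma_x < 0 or self.linear_factor <= 0:
            raise ValueError("sigma_t, linear_factor must be positive; sigma_x non-negative")
        if any(m <= 0 for m in self.mass_beliefs.values()):
            raise ValueError("mass beliefs must be positive")


@dataclass(frozen=True)
class ProfileDistributions:
    """Population distributions the cohort is drawn from.

    ``sigma_t_range`` spans the range almost all subjects fell in;
    ``prior_mass_gamma`` is the (shape, rate) of the gamma the phase-1 mass
    belief is drawn from (mean 2 kg, SD 0.5 kg by default — a plausible guess
    for a curling-like puck); ``linear_factor_range`` spans scalings that put
    heuristic press-times on the same scale as Newtonian ones over 1–5 m.
    """

    model_class: str = "newtonian"
    cost_function: str = "quadratic"
    sigma_t_range: tuple[float, float] = (0.15, 0.33)
    sigma_x: float = 0.05
    prior_mass_gamma: tuple[float, float] = (16.0, 8.0)
    linear_factor_range: tuple[float, float] = (0.2, 0.4)


@dataclass
class TrialRecord:
    """One sliding trial: observables plus generator ground truth."""

    subject_id: str
    condition: str
    phase: str
    trial_index: int
    puck_id: str
    x: float
    x_per: float
    t_int: float
    t_pre: float
    mass_belief: float
    final_position_error: float
    feedback_shown: bool


@dataclass(frozen=True)
class CollisionEvent:
    """One frictionless elastic collision shown in the phase-4 movie."""

    event_index: int
    known_puck_id: str
    vF: float
    vNF: float
    uF: float
    uNF: float
    mF: float


def make_cohort(
    n_subjects: int,
    condition_split: float = 0.5,
    profile_distributions: ProfileDistributions | None = None,
    seed: int = 0,
) -> list[ParticipantProfile]:
    """Draw a cohort of synthetic subjects.

    Exactly ``round(n_subjects * condition_split)`` subjects are assigned to
    the light-to-heavy condition (half by default), the rest to
    heavy-to-light, in a seed-determined random order.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if profile_distributions is None:
        profile_distributions = ProfileDistributions()
    if not isinstance(profile_distributions, ProfileDistributions):
        raise ValueError("profile_distributions must be a ProfileDistributions")
    dist = profile_distributions
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    n_l2h = int(round(n_subjects * condition_split))
    conditions = np.array(
        ["light-to-heavy"] * n_l2h + ["heavy-to-light"] * (n_subjects - n_l2h)
    )
    rng.shuffle(conditions)
    child_seeds = ss.generate_state(n_subjects + 1)[1:]
    profiles = []
    for i in range(n_subjects):
        shape, rate = dist.prior_mass_gamma
        prior_mass = float(rng.gamma(shape, 1.0 / rate))
        profiles.append(
            ParticipantProfile(
                subject_id=f"s{i + 1:02d}",
                condition=str(conditions[i]),
                model_class=dist.model_class,
                cost_function=dist.cost_function,
                sigma_t=float(rng.uniform(*dist.sigma_t_range)),
                sigma_x=dist.sigma_x,
                mass_beliefs={"black": prior_mass},
                linear_factor=float(rng.uniform(*dist.linear_factor_range)),
                rng_seed=int(child_seeds[i] % (2**31)),
            )
        )
    return profiles


def perceive_distance(x, sigma_x: float, rng: np.random.Generator):
    """Noisy distance percept: log-normal with its mode at the true distance.

    The log-normal location is ``ln x + sigma_x**2`` so that the density peaks
    at ``x``; the multiplicative noise makes the percept SD grow linearly with
    distance (Weber–Fechner).  ``sigma_x = 0`` returns ``x`` exactly.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("distance must be positive")
    if sigma_x < 0:
        raise ValueError("sigma_x must be non-negative")
    if sigma_x == 0:
        return x if x.ndim else float(x)
    out = np.exp(rng.normal(np.log(x) + sigma_x**2, sigma_x))
    return out if out.ndim else float(out)


def intended_press_time(
    x_per, profile: ParticipantProfile, puck_id: str, env: EnvironmentParams
):
    """Deterministic press-time implied by the percept and the model class."""
    if np.any(np.asarray(x_per) <= 0):
        raise ValueError("perceived distance must be positive")
    if profile.model_class == "newtonian":
        return ideal_press_time(x_per, profile.mass_beliefs[puck_id], env)
    return profile.linear_factor * np.asarray(x_per, dtype=float)


def cost_shift(cost_function: str, sigma_t: float) -> float:
    """Log-location shift that makes the cost-optimal statistic equal t_int.

    For a log-normal with parameters (μ, σ): mode = exp(μ − σ²), median =
    exp(μ), mean = exp(μ + σ²/2).  Equating the statistic favoured by each
    loss to the intended press-time gives μ = ln t_int + shift with shift
    +σ² (0-1 loss → mode), 0 (absolute → median), −σ²/2 (quadratic → mean).
    """
    if cost_function == "zero_one":
        return sigma_t**2
    if cost_function == "absolute":
        return 0.0
    if cost_function == "quadratic":
        return -(sigma_t**2) / 2.0
    raise ValueError(f"unknown cost_function {cost_function!r}")


def emit_press_time(t_int, sigma_t: float, cost_function: str, rng: np.random.Generator):
    """Sample an actual press-time given the intention and motor variability."""
    t_int = np.asarray(t_int, dtype=float)
    if np.any(t_int <= 0):
        raise ValueError("t_int must be positive")
    if sigma_t < 0:
        raise ValueError("sigma_t must be non-negative")
    if sigma_t == 0:
        return t_int if t_int.ndim else float(t_int)
    mu = np.log(t_int) + cost_shift(cost_function, sigma_t)
    out = np.exp(rng.normal(mu, sigma_t))
    return out if out.ndim else float(out)


class ConjugateMassLearner:
    """Running conjugate-style update of a mass belief from feedback trials.

    Each observed slide yields an implied mass
    ``m_obs = F t_pre / sqrt(2 μ g d_obs)`` (inverting the press-time law at
    the observed stopping distance).  The belief is the precision-weighted
    mean of the prior belief (with pseudo-count ``prior_strength``) and the
    implied-mass observations — the posterior-mean update of a normal mean
    with known variance.  With the default strength of 2 the belief moves
    most of the way to the truth within a handful of trials, matching the
    rapid adjustment the task affords.
    """

    def __init__(self, prior_mass: float, prior_strength: float = 2.0):
        self.prior_mass = prior_mass
        self.prior_strength = prior_strength
        self._sum = 0.0
        self._n = 0

    @property
    def belief(self) -> float:
        return (self.prior_strength * self.prior_mass + self._sum) / (
            self.prior_strength + self._n
        )

    def observe(self, t_pre: float, observed_distance: float, env: EnvironmentParams):
        if observed_distance > 1e-6:
            m_obs = (
                env.interaction_force
                * t_pre
                / math.sqrt(2.0 * env.deceleration * observed_distance)
            )
            self._sum += m_obs
            self._n += 1
        return self.belief


def _feedback_puck_sequence(n_trials: int) -> list[str]:
    return [
        FEEDBACK_PUCK_ORDER[(i // FEEDBACK_BLOCK) % 2] for i in range(n_trials)
    ]


def run_phase(
    profile: ParticipantProfile,
    phase: str,
    env: EnvironmentParams,
    true_masses: dict[str, float] | None = None,
    seed: int | None = None,
    learner_factory: Callable[[float], ConjugateMassLearner] | None = None,
    n_trials: int | None = None,
) -> list[TrialRecord]:
    """Simulate all trials of one phase for one subject.

    Mutates ``profile.mass_beliefs``: the feedback phase updates the beliefs
    of the two feedback pucks via the learning rule, and the no-feedback
    phase initialises the rings-puck belief to the mean of the two learned
    beliefs if it is not already set.  Ground-truth latents are stored on the
    returned records.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if true_masses is None:
        true_masses = CONDITION_MASSES[profile.condition]
    if seed is None:
        seed = profile.rng_seed
    rng = np.random.default_rng(seed)
    n = PHASE_TRIALS[phase] if n_trials is None else n_trials
    lo, hi = env.distance_range

    feedback = phase == "feedback"
    if feedback:
        pucks = _feedback_puck_sequence(n)
        if learner_factory is None:
            learner_factory = ConjugateMassLearner
        learners = {}
        for p in FEEDBACK_PUCK_ORDER:
            start = profile.mass_beliefs.get(p, profile.mass_beliefs.get("black", 2.0))
            learners[p] = learner_factory(start)
            profile.mass_beliefs[p] = learners[p].belief
    else:
        puck = PHASE_PUCKS[phase][0]
        pucks = [puck] * n
        if puck == "rings" and "rings" not in profile.mass_beliefs:
            fb = [profile.mass_beliefs[p] for p in FEEDBACK_PUCK_ORDER if p in profile.mass_beliefs]
            profile.mass_beliefs["rings"] = (
                float(np.mean(fb)) if fb else profile.mass_beliefs.get("black", 2.0)
            )
        if pucks and pucks[0] not in profile.mass_beliefs:
            raise ValueError(f"no mass belief for puck {pucks[0]!r}")

    records = []
    for i in range(n):
        puck_id = pucks[i]
        x = float(rng.uniform(lo, hi))
        x_per = perceive_distance(x, profile.sigma_x, rng)
        t_int = float(intended_press_time(x_per, profile, puck_id, env))
        t_pre = float(emit_press_time(t_int, profile.sigma_t, profile.cost_function, rng))
        v0 = release_velocity(t_pre, true_masses[puck_id], env)
        d_obs = simulate_slide(v0, env).displacement
        error = d_obs - x
        if feedback:
            profile.mass_beliefs[puck_id] = learners[puck_id].observe(t_pre, d_obs, env)
        records.append(
            TrialRecord(
                subject_id=profile.subject_id,
                condition=profile.condition,
                phase=phase,
                trial_index=i,
                puck_id=puck_id,
                x=x,
                x_per=float(x_per),
                t_int=t_int,
                t_pre=t_pre,
                mass_belief=profile.mass_beliefs[puck_id],
                final_position_error=error,
                feedback_shown=feedback,
            )
        )
    return records


def generate_collisions(
    mNF_true: float,
    known_pucks: Sequence[PuckSpec],
    env: EnvironmentParams,
    seed: int = 0,
    speed_range: tuple[float, float] = (0.5, 2.5),
    nf_speed_range: tuple[float, float] | None = None,
    n_per_puck: int = 12,
) -> list[CollisionEvent]:
    """Generate the phase-4 collision movie.

    ``n_per_puck`` collisions with each of exactly two known pucks, in
    randomized order.  The known puck approaches with a speed uniform on
    ``speed_range``; the unknown puck is at rest unless ``nf_speed_range`` is
    given, in which case it moves toward the known puck (negative velocity).
    Post-collision velocities are the exact frictionless elastic solutions.
    """
    if len(known_pucks) != 2:
        raise ValueError("exactly two known pucks are required")
    if mNF_true <= 0:
        raise ValueError("mNF_true must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation([0] * n_per_puck + [1] * n_per_puck)
    events = []
    for idx, which in enumerate(order):
        puck = known_pucks[which]
        vF = float(rng.uniform(*speed_range))
        vNF = -float(rng.uniform(*nf_speed_range)) if nf_speed_range else 0.0
        uF, uNF = elastic_collision(vF, vNF, puck.mass, mNF_true)
        events.append(
            CollisionEvent(
                event_index=idx,
                known_puck_id=puck.puck_id,
                vF=vF,
                vNF=vNF,
                uF=uF,
                uNF=uNF,
                mF=puck.mass,
            )
        )
    return events


def observe_collisions_belief(
    profile: ParticipantProfile,
    events: Iterable[CollisionEvent],
    rng: np.random.Generator,
    sigma_vel: float = 0.2,
) -> float:
    """Subject's rings-mass belief after watching the collision movie.

    Stand-in for the full perceptual inference: each collision's velocities
    are perceived with multiplicative log-normal noise of scale ``sigma_vel``
    and inverted through the elastic-collision equations using the subject's
    believed known-puck mass; the belief is the median implied mass.  Updates
    ``profile.mass_beliefs['rings']`` and returns it.
    """
    implied = []
    for ev in events:
        noise = np.exp(rng.normal(-(sigma_vel**2) * np.ones(3), sigma_vel))
        vF, vNF, uF = ev.vF * noise[0], ev.vNF * noise[1], ev.uF * noise[2]
        mF_bel = profile.mass_beliefs.get(ev.known_puck_id, ev.mF)
        m = collision_implied_mass(vF, vNF, uF, mF_bel)
        if np.isfinite(m) and m > 0:
            implied.append(float(m))
    if implied:
        profile.mass_beliefs["rings"] = float(np.median(implied))
    return profile.mass_beliefs.get("rings", float("nan"))


def run_subject(
    profile: ParticipantProfile, env: EnvironmentParams
) -> tuple[list[TrialRecord], list[CollisionEvent]]:
    """Run all four phases for one subject, threading beliefs across phases."""
    ss = np.random.SeedSequence(profile.rng_seed)
    seeds = ss.generate_state(7)[1:] % (2**31)
    masses = CONDITION_MASSES[profile.condition]
    trials = []
    trials += run_phase(profile, "prior", env, masses, seed=int(seeds[0]))
    trials += run_phase(profile, "feedback", env, masses, seed=int(seeds[1]))
    trials += run_phase(profile, "no_feedback", env, masses, seed=int(seeds[2]))
    known = [PuckSpec(p, masses[p]) for p in FEEDBACK_PUCK_ORDER]
    events = generate_collisions(masses["rings"], known, env, seed=int(seeds[3]))
    observe_collisions_belief(profile, events, np.random.default_rng(int(seeds[4])))
    trials += run_phase(profile, "collisions_no_feedback", env, masses, seed=int(seeds[5] % (2**31)))
    return trials, events


def trials_to_frame(trials: Iterable[TrialRecord]):
    """Trial records as a pandas DataFrame (observables + latent columns)."""
    import pandas as pd

    return pd.DataFrame([t.__dict__ for t in trials])


def collisions_to_frame(events: Iterable[CollisionEvent], subject_id: str | None = None):
    import pandas as pd

    df = pd.DataFrame([e.__dict__ for e in events])
    if subject_id is not None:
        df.insert(0, "subject_id", subject_id)
    return df


def simulate_cohort(profiles: Sequence[ParticipantProfile], env: EnvironmentParams):
    """Simulate every subject; returns (trials DataFrame, {subject: events})."""
    import pandas as pd

    frames, collisions = [], {}
    for prof in profiles:
        trials, events = run_subject(prof, env)
        frames.append(trials_to_frame(trials))
        collisions[prof.subject_id] = events
    return pd.concat(frames, ignore_index=True), collisions
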