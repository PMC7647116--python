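"""Synthetic cohorts, phases, noise models, and collision movies."""

import numpy as np
import pytest

from puckslide.physics import EnvironmentParams, PuckSpec
from puckslide.synthetic import (
    CONDITION_MASSES,
    FEEDBACK_PUCK_ORDER,
    ParticipantProfile,
    ProfileDistributions,
    cost_shift,
    emit_press_time,
    generate_collisions,
    intended_press_time,
    make_cohort,
    perceive_distance,
    run_phase,
    trials_to_frame,
)


class TestCohort:
    def test_even_split_between_conditions(self):
        profiles = make_cohort(16, seed=1)
        conds = [p.condition for p in profiles]
        assert conds.count("light-to-heavy") == 8
        assert conds.count("heavy-to-light") == 8

    def test_same_seed_reproduces_cohort(self):
        a = make_cohort(6, seed=9)
        b = make_cohort(6, seed=9)
        assert [p.__dict__ for p in a] == [p.__dict__ for p in b]

    def test_single_subject(self):
        (p,) = make_cohort(1, seed=0)
        assert p.condition in CONDITION_MASSES
        assert 0.15 <= p.sigma_t <= 0.33

    def test_invalid_distribution_object_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(4, profile_distributions={}, seed=0)

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            ParticipantProfile("s", "light-to-heavy", sigma_t=-0.1)
        with pytest.raises(ValueError):
            ParticipantProfile("s", "nowhere")


class TestPerceiveDistance:
    def test_noiseless_limit_returns_truth(self):
        rng = np.random.default_rng(0)
        assert perceive_distance(3.0, 0.0, rng) == 3.0

    def test_samples_positive_and_weber_scaling(self):
        # multiplicative noise: sample SD doubles when the distance doubles
        rng = np.random.default_rng(1)
        s2 = perceive_distance(np.full(100_000, 2.0), 0.3, rng)
        s4 = perceive_distance(np.full(100_000, 4.0), 0.3, rng)
        assert np.all(s2 > 0)
        assert np.std(s4) / np.std(s2) == pytest.approx(2.0, rel=0.05)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            perceive_distance(0.0, 0.1, np.random.default_rng(0))


class TestPressTimes:
    @pytest.fixture()
    def profile(self):
        return ParticipantProfile(
            "s01",
            "light-to-heavy",
            mass_beliefs={"red-dots": 1.5, "yellow-diamond": 2.0},
            linear_factor=0.3,
        )

    def test_newtonian_square_root_scaling(self, profile, env):
        t1 = intended_press_time(1.0, profile, "red-dots", env)
        t4 = intended_press_time(4.0, profile, "red-dots", env)
        assert t4 == pytest.approx(2 * t1)

    def test_newtonian_mass_ratio(self, profile, env):
        th = intended_press_time(2.5, profile, "yellow-diamond", env)
        tl = intended_press_time(2.5, profile, "red-dots", env)
        assert th / tl == pytest.approx(4.0 / 3.0)

    def test_linear_heuristic_scaling(self, profile, env):
        profile.model_class = "linear"
        assert intended_press_time(2.0, profile, "red-dots", env) == pytest.approx(
            2 * intended_press_time(1.0, profile, "red-dots", env)
        )

    def test_unknown_puck_raises(self, profile, env):
        with pytest.raises(KeyError):
            intended_press_time(2.0, profile, "no-such-puck", env)

    @pytest.mark.parametrize("cost", ["zero_one", "absolute", "quadratic"])
    def test_noiseless_limit_emits_intention(self, cost):
        rng = np.random.default_rng(0)
        assert emit_press_time(0.8, 0.0, cost, rng) == 0.8

    def test_quadratic_cost_centres_the_mean(self):
        # quadratic loss is minimised by the mean: E[t_pre] = t_int
        rng = np.random.default_rng(2)
        s = emit_press_time(np.full(1_000_000, 0.7), 0.3, "quadratic", rng)
        se = np.std(s) / 1000.0
        assert np.mean(s) == pytest.approx(0.7, abs=4 * se)

    def test_absolute_cost_centres_the_median(self):
        rng = np.random.default_rng(3)
        s = emit_press_time(np.full(1_000_000, 0.7), 0.3, "absolute", rng)
        assert np.median(s) == pytest.approx(0.7, abs=2e-3)

    def test_zero_one_shift_targets_the_mode(self):
        # mode of LN(mu, s) is exp(mu - s^2); the zero-one shift +s^2 undoes it
        assert cost_shift("zero_one", 0.3) == pytest.approx(0.09)
        with pytest.raises(ValueError):
            cost_shift("huber", 0.3)

    def test_nonpositive_intention_rejected(self):
        with pytest.raises(ValueError):
            emit_press_time(0.0, 0.2, "quadratic", np.random.default_rng(0))


class TestPhases:
    @pytest.fixture()
    def profile(self):
        (p,) = make_cohort(1, seed=12)
        return p

    def test_prior_phase_structure(self, profile, env):
        recs = run_phase(profile, "prior", env, seed=1)
        assert len(recs) == 50
        assert {r.puck_id for r in recs} == {"black"}
        assert not any(r.feedback_shown for r in recs)

    def test_feedback_phase_alternates_every_four_trials(self, profile, env):
        recs = run_phase(profile, "feedback", env, seed=1)
        assert len(recs) == 200
        ids = [r.puck_id for r in recs]
        for i, pid in enumerate(ids):
            assert pid == FEEDBACK_PUCK_ORDER[(i // 4) % 2]
        assert all(r.feedback_shown for r in recs)

    def test_distances_uniform_within_arena(self, profile, env):
        recs = run_phase(profile, "feedback", env, seed=2)
        xs = np.array([r.x for r in recs])
        assert xs.min() >= 1.0 and xs.max() <= 5.0

    def test_feedback_learning_converges_to_true_masses(self, profile, env):
        run_phase(profile, "feedback", env, seed=3)
        masses = CONDITION_MASSES[profile.condition]
        for puck in FEEDBACK_PUCK_ORDER:
            assert profile.mass_beliefs[puck] == pytest.approx(masses[puck], rel=0.1)

    def test_no_feedback_belief_averages_feedback_pucks(self, profile, env):
        run_phase(profile, "feedback", env, seed=3)
        run_phase(profile, "no_feedback", env, seed=4)
        expect = np.mean([profile.mass_beliefs[p] for p in FEEDBACK_PUCK_ORDER])
        assert profile.mass_beliefs["rings"] == pytest.approx(expect)

    def test_unknown_phase_rejected(self, profile, env):
        with pytest.raises(ValueError):
            run_phase(profile, "bonus-round", env)

    def test_ground_truth_latents_recorded(self, profile, env):
        df = trials_to_frame(run_phase(profile, "prior", env, seed=5))
        assert {"x_per", "t_int", "mass_belief"} <= set(df.columns)
        assert (df["x_per"] > 0).all()


class TestCollisionMovies:
    def test_structure_and_determinism(self, env):
        known = [PuckSpec("red-dots", 1.5), PuckSpec("yellow-diamond", 2.0)]
        a = generate_collisions(2.5, known, env, seed=4)
        b = generate_collisions(2.5, known, env, seed=4)
        assert len(a) == 24
        counts = {p.puck_id: 0 for p in known}
        for e in a:
            counts[e.known_puck_id] += 1
        assert counts == {"red-dots": 12, "yellow-diamond": 12}
        assert [e.__dict__ for e in a] == [e.__dict__ for e in b]

    def test_every_event_conserves_momentum_and_energy(self, env):
        known = [PuckSpec("red-dots", 1.5), PuckSpec("yellow-diamond", 2.0)]
        for e in generate_collisions(2.5, known, env, seed=4):
            p_in = e.mF * e.vF + 2.5 * e.vNF
            p_out = e.mF * e.uF + 2.5 * e.uNF
            e_in = e.mF * e.vF**2 + 2.5 * e.vNF**2
            e_out = e.mF * e.uF**2 + 2.5 * e.uNF**2
            assert p_out == pytest.approx(p_in, abs=1e-12)
            assert e_out == pytest.approx(e_in, abs=1e-12)

    def test_requires_exactly_two_known_pucks(self, env):
        with pytest.raises(ValueError):
            generate_collisions(2.5, [PuckSpec("red-dots", 1.5)], env)


def test_press_time_variability_grows_with_distance(small_cohort):
    # Weber–Fechner: press-time SD within distance bins increases with the bin
    _, trials, _ = small_cohort
    fb = trials[trials["phase"] == "feedback"]
    bins = pd_cut_sd(fb)
    assert bins[0] < bins[-1]


def pd_cut_sd(fb):
    import pandas as pd

    binned = pd.cut(fb["x"], [1.0, 2.33, 3.66, 5.0])
    return fb.groupby(binned, observed=True)["t_pre"].std().to_numpy()
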