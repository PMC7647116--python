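"""Interaction-model joint density, fitting, and diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from puckslide.physics import EnvironmentParams, ideal_press_time
from puckslide.synthetic import ProfileDistributions, make_cohort, simulate_cohort
from puckslide.interaction import (
    GammaPrior,
    InteractionModelSpec,
    InteractionPosterior,
    MCMCSettings,
    SubjectPosterior,
    fit,
    fix_nuisance,
    gamma_from_mean_sd,
    log_joint,
    posterior_predictive_press_times,
    residual_analysis,
)
from puckslide.comparison import ks_two_sample


def _toy_trials(n=6, seed=0, subject="s01"):
    rng = np.random.default_rng(seed)
    x = rng.uniform(1, 5, n)
    t = rng.uniform(0.3, 1.2, n)
    pucks = np.where(np.arange(n) % 2 == 0, "red-dots", "yellow-diamond")
    return pd.DataFrame(
        {"subject_id": subject, "puck_id": pucks, "x": x, "t_pre": t}
    )


def _oracle_log_joint(trials, latents, spec):
    """Independent density computation built on scipy distributions only."""
    lo, hi = spec.env.distance_range
    lp = len(trials) * np.log(1.0 / (hi - lo))
    gam = lambda v, pr: stats.gamma.logpdf(v, a=pr.shape, scale=1.0 / pr.rate)
    for v in latents["scale"].values():
        lp += gam(v, spec.scale_prior)
    lp += gam(latents["sigma_t"], spec.sigma_t_prior)
    lp += gam(latents["sigma_x"], spec.sigma_x_prior)
    sx, st = latents["sigma_x"], latents["sigma_t"]
    shift = {"zero_one": st**2, "absolute": 0.0, "quadratic": -(st**2) / 2}[
        spec.cost_function
    ]
    env = spec.env
    for (_, row), xp in zip(trials.iterrows(), latents["x_per"]):
        lp += stats.lognorm.logpdf(xp, s=sx, scale=np.exp(np.log(row.x) + sx**2))
        par = latents["scale"][row.puck_id]
        if spec.model_class == "newtonian":
            t_int = (par / env.interaction_force) * np.sqrt(2 * env.deceleration * xp)
        else:
            t_int = par * xp
        lp += stats.lognorm.logpdf(row.t_pre, s=st, scale=np.exp(np.log(t_int) + shift))
    return lp


class TestLogJoint:
    @pytest.mark.parametrize("model_class", ["newtonian", "linear"])
    @pytest.mark.parametrize("cost", ["zero_one", "absolute", "quadratic"])
    def test_matches_independent_scipy_oracle(self, model_class, cost):
        trials = _toy_trials()
        spec = InteractionModelSpec(model_class=model_class, cost_function=cost)
        rng = np.random.default_rng(7)
        for _ in range(3):
            latents = {
                "scale": {"red-dots": rng.uniform(0.2, 3), "yellow-diamond": rng.uniform(0.2, 3)},
                "sigma_t": rng.uniform(0.05, 0.5),
                "sigma_x": rng.uniform(0.01, 0.3),
                "x_per": rng.uniform(0.8, 5.5, len(trials)),
            }
            assert log_joint(trials, latents, spec) == pytest.approx(
                _oracle_log_joint(trials, latents, spec), abs=1e-10
            )

    def test_factorises_over_trials(self):
        spec = InteractionModelSpec()
        t7 = _toy_trials(7, seed=1)
        t6 = t7.iloc[:6]
        rng = np.random.default_rng(0)
        lat7 = {
            "scale": {"red-dots": 1.5, "yellow-diamond": 2.0},
            "sigma_t": 0.25,
            "sigma_x": 0.05,
            "x_per": rng.uniform(1, 5, 7),
        }
        lat6 = dict(lat7, x_per=lat7["x_per"][:6])
        # the scalar priors enter once per evaluation; subtracting two
        # evaluations cancels them, leaving exactly the extra trial's terms
        extra = log_joint(t7, lat7, spec) - log_joint(t6, lat6, spec)
        lat1 = dict(lat7, x_per=lat7["x_per"][6:])
        priors = (
            sum(spec.scale_prior.logpdf(v) for v in lat7["scale"].values())
            + spec.sigma_t_prior.logpdf(lat7["sigma_t"])
            + spec.sigma_x_prior.logpdf(lat7["sigma_x"])
        )
        only = log_joint(t7.iloc[6:], lat1, spec) - priors
        assert extra == pytest.approx(only, abs=1e-10)

    def test_out_of_support_latents_give_minus_inf(self):
        trials = _toy_trials()
        spec = InteractionModelSpec()
        base = {
            "scale": {"red-dots": 1.5, "yellow-diamond": 2.0},
            "sigma_t": 0.25,
            "sigma_x": 0.05,
            "x_per": np.full(len(trials), 2.0),
        }
        assert np.isfinite(log_joint(trials, base, spec))
        assert log_joint(trials, dict(base, sigma_t=-0.1), spec) == -np.inf
        assert log_joint(trials, dict(base, scale={"red-dots": -1, "yellow-diamond": 2}), spec) == -np.inf

    def test_truth_beats_perturbation_on_low_noise_data(self, env):
        # data generated almost noiselessly: the generating latents dominate
        dist = ProfileDistributions(sigma_t_range=(0.01, 0.011), sigma_x=0.01)
        (prof,) = make_cohort(1, profile_distributions=dist, seed=2)
        trials, _ = simulate_cohort([prof], env)
        fb = trials[trials["phase"] == "feedback"].iloc[-40:]
        spec = InteractionModelSpec(env=env)
        masses = {p: prof.mass_beliefs[p] for p in ("red-dots", "yellow-diamond")}
        truth = {
            "scale": masses,
            "sigma_t": prof.sigma_t,
            "sigma_x": 0.01,
            "x_per": fb["x_per"].to_numpy(),
        }
        bent = dict(truth, scale={k: v * 1.3 for k, v in masses.items()})
        assert log_joint(fb, truth, spec) > log_joint(fb, bent, spec)


class TestFit:
    def test_same_seed_gives_identical_summaries(self, feedback_trials):
        spec = InteractionModelSpec(mcmc=MCMCSettings(chains=1, warmup=100, draws=120, seed=11))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(feedback_trials, spec)
            b = fit(feedback_trials, spec)
        for sid in a.subjects:
            assert a.subjects[sid].map_params() == b.subjects[sid].map_params()
            np.testing.assert_array_equal(
                a.subjects[sid].params["sigma_t"], b.subjects[sid].params["sigma_t"]
            )

    def test_recovers_masses_of_small_cohort(self, small_cohort, newtonian_fit):
        profiles, _, _ = small_cohort
        _, post = newtonian_fit
        for prof in profiles:
            mp = post.subjects[prof.subject_id].map_params()
            for puck in ("red-dots", "yellow-diamond"):
                true = prof.mass_beliefs[puck]
                assert mp[f"m[{puck}]"] == pytest.approx(true, rel=0.12)

    def test_low_noise_posteriors_concentrate_on_truth(self, env):
        dist = ProfileDistributions(sigma_t_range=(0.02, 0.021), sigma_x=0.01)
        (prof,) = make_cohort(1, profile_distributions=dist, seed=8)
        trials, _ = simulate_cohort([prof], env)
        fb = trials[trials["phase"] == "feedback"]
        spec = InteractionModelSpec(mcmc=MCMCSettings(chains=2, warmup=200, draws=300, seed=4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post = fit(fb, spec)
        sp = post.subjects[prof.subject_id]
        for puck in ("red-dots", "yellow-diamond"):
            samples = sp.params[f"m[{puck}]"]
            assert np.mean(samples) == pytest.approx(prof.mass_beliefs[puck], rel=0.03)
            assert np.std(samples) < 0.05

    def test_too_few_trials_per_puck_rejected(self):
        spec = InteractionModelSpec()
        with pytest.raises(ValueError):
            fit(_toy_trials(3), spec)  # yellow-diamond has a single trial


class TestNuisance:
    def test_fix_nuisance_collects_per_subject_maps(self, newtonian_fit):
        _, post = newtonian_fit
        fixes = fix_nuisance(post)
        assert set(fixes.sigma_t) == set(post.subjects)
        assert 0.0 < fixes.sigma_x < 0.2
        for sid, sp in post.subjects.items():
            assert fixes.sigma_t[sid] == sp.map_params()["sigma_t"]

    def test_sigma_t_maps_lie_in_posterior_bulk(self, small_cohort, newtonian_fit):
        profiles, _, _ = small_cohort
        _, post = newtonian_fit
        for prof in profiles:
            samples = post.subjects[prof.subject_id].params["sigma_t"]
            lo, hi = np.quantile(samples, [0.025, 0.975])
            assert lo <= prof.sigma_t * 1.15 and prof.sigma_t * 0.85 <= hi

    def test_downstream_fit_accepts_fixed_nuisance(self, small_cohort, newtonian_fit):
        _, trials, _ = small_cohort
        _, post = newtonian_fit
        fixes = fix_nuisance(post)
        prior = trials[trials["phase"] == "prior"]
        spec = InteractionModelSpec(
            sigma_x_fixed=fixes.sigma_x,
            sigma_t_fixed=fixes.sigma_t,
            mcmc=MCMCSettings(chains=1, warmup=100, draws=150, seed=2),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            post_prior = fit(prior, spec)
        for sid, sp in post_prior.subjects.items():
            assert np.all(sp.params["sigma_t"] == fixes.sigma_t[sid])
            assert np.all(sp.params["sigma_x"] == fixes.sigma_x)

    def test_missing_subject_in_fixed_sigma_t_rejected(self, feedback_trials):
        spec = InteractionModelSpec(sigma_t_fixed={"nobody": 0.2})
        with pytest.raises(ValueError):
            fit(feedback_trials, spec)


class TestPosteriorPredictive:
    def test_samples_positive_and_shaped(self, feedback_trials, newtonian_fit):
        spec, post = newtonian_fit
        pp = posterior_predictive_press_times(post, feedback_trials, spec, n_draws=20, seed=1)
        for sid, sims in pp.items():
            n_tr = (feedback_trials["subject_id"] == sid).sum()
            assert sims.shape == (20, n_tr)
            assert np.all(sims > 0)

    def test_matched_model_predicts_better_than_mismatched(
        self, feedback_trials, newtonian_fit, linear_fit
    ):
        obs = feedback_trials["t_pre"].to_numpy()
        Ds = {}
        for name, (spec, post) in {"newtonian": newtonian_fit, "linear": linear_fit}.items():
            pp = posterior_predictive_press_times(post, feedback_trials, spec, n_draws=40, seed=2)
            sim = np.concatenate([v.ravel() for v in pp.values()])
            Ds[name], _ = ks_two_sample(obs, sim)
        assert Ds["newtonian"] < Ds["linear"]

    def test_requires_at_least_one_draw(self, feedback_trials, newtonian_fit):
        spec, post = newtonian_fit
        with pytest.raises(ValueError):
            posterior_predictive_press_times(post, feedback_trials, spec, n_draws=0)


class TestResiduals:
    def test_matched_fit_residuals_uncorrelated_with_distance(
        self, feedback_trials, newtonian_fit
    ):
        spec, post = newtonian_fit
        rep = residual_analysis(post, feedback_trials, spec)
        assert abs(rep.rho) < 0.15

    def test_linear_fit_to_newtonian_data_shows_negative_trend(
        self, feedback_trials, linear_fit
    ):
        spec, post = linear_fit
        rep = residual_analysis(post, feedback_trials, spec)
        assert rep.rho < -0.3

    def test_sigma_t_inflates_under_misspecification(self, newtonian_fit, linear_fit):
        # the linear class must absorb the unmodelled square-root curvature
        _, post_n = newtonian_fit
        _, post_l = linear_fit
        for sid in post_n.subjects:
            st_n = np.mean(post_n.subjects[sid].params["sigma_t"])
            st_l = np.mean(post_l.subjects[sid].params["sigma_t"])
            assert st_l > st_n

    def test_perfect_prediction_reported_as_degenerate(self, env):
        n = 12
        x = np.linspace(1, 5, n)
        t = ideal_press_time(x, 2.0, env)
        trials = pd.DataFrame(
            {"subject_id": "s01", "puck_id": "rings", "x": x, "t_pre": t}
        )
        spec = InteractionModelSpec(cost_function="absolute")
        shape = (1, 1)
        sp = SubjectPosterior(
            subject_id="s01",
            pucks=["rings"],
            params={
                "m[rings]": np.full(shape, 2.0),
                "sigma_t": np.full(shape, 1e-9),
                "sigma_x": np.full(shape, 1e-9),
            },
            x_per=x.reshape(1, 1, n),
            log_joint=np.zeros(shape),
            marginal_log_post=np.zeros(shape),
            diagnostics=pd.DataFrame(),
            converged=True,
        )
        post = InteractionPosterior(spec=spec, subjects={"s01": sp})
        rep = residual_analysis(post, trials, spec)
        assert rep.degenerate
        assert rep.rho == 0.0

    def test_too_few_trials_rejected(self, newtonian_fit):
        spec, post = newtonian_fit
        with pytest.raises(ValueError):
            residual_analysis(post, _toy_trials(2), spec)


def test_gamma_prior_helpers():
    pr = gamma_from_mean_sd(2.0, 2.0)
    assert pr.mean == pytest.approx(2.0)
    assert pr.shape / pr.rate**2 == pytest.approx(4.0)  # variance
    with pytest.raises(ValueError):
        GammaPrior(-1.0, 2.0)
    with pytest.raises(ValueError):
        MCMCSettings(draws=0)
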