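"""Hierarchical Bayesian inference for the sliding-task generative model.

For every trial i of subject j with puck k the generative model is

    x_per ~ LogNormal(ln x + σ_x², σ_x)                (percept, mode at x)
    t_int = (m_{j,k}/F) √(2 μ g x_per)   (Newtonian)   or   c_{j,k} x_per (linear)
    t_pre ~ LogNormal(ln t_int + s(σ_t), σ_t)          (motor noise)

where the cost shift s is +σ_t² / 0 / −σ_t²/2 for the 0-1 / absolute /
quadratic loss, so that the loss-optimal statistic of the press-time
distribution (mode / median / mean) equals the intention.  Masses (or linear
factors) and σ's carry gamma priors.

Everything is Gaussian and linear in log space given the scalar parameters,
so the per-trial percept latents have exact Gaussian full conditionals; the
sampler alternates exact Gibbs refreshes of all latents with adaptive
random-walk Metropolis updates of the log-scalars.  Subjects are fitted
independently (masses, σ_t and the percept latents are subject-specific);
the shared σ_x is pooled afterwards from the per-subject MAPs
(`fix_nuisance`), mirroring the two-stage analysis the task design calls
for: the feedback phase pins down the nuisance variabilities, which are then
held fixed for the remaining phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .physics import EnvironmentParams
from .synthetic import cost_shift

__all__ = [
    "GammaPrior",
    "gamma_from_mean_sd",
    "MCMCSettings",
    "InteractionModelSpec",
    "SubjectPosterior",
    "InteractionPosterior",
    "NuisanceFixes",
    "log_joint",
    "fit",
    "fix_nuisance",
    "posterior_predictive_press_times",
    "residual_analysis",
    "ResidualReport",
]

_LOG_2PI = np.log(2.0 * np.pi)


def _norm_logpdf(x, mu, sigma):
    z = (x - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


@dataclass(frozen=True)
class GammaPrior:
    """Gamma prior in (shape, rate) parametrisation."""

    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("gamma hyperparameters must be positive")

    def logpdf(self, x):
        if np.any(np.asarray(x) <= 0):
            return -np.inf
        x = np.asarray(x, dtype=float)
        return float(
            np.sum(
                self.shape * np.log(self.rate)
                + (self.shape - 1) * np.log(x)
                - self.rate * x
                - _lgamma(self.shape)
            )
        )

    @property
    def mean(self):
        return self.shape / self.rate

    def sample(self, rng, size=None):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)


def _lgamma(a):
    from scipy.special import gammaln

    return gammaln(a)


def gamma_from_mean_sd(mean: float, sd: float) -> GammaPrior:
    """Gamma prior with the given mean and standard deviation."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    return GammaPrior(shape=(mean / sd) ** 2, rate=mean / sd**2)


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 2
    warmup: int = 500
    draws: int = 1000
    seed: int = 0
    thin: int = 1  # full update cycles per recorded draw

    def __post_init__(self):
        if self.draws < 1 or self.chains < 1 or self.warmup < 0 or self.thin < 1:
            raise ValueError("draws and chains must be >= 1, warmup >= 0, thin >= 1")


@dataclass(frozen=True)
class InteractionModelSpec:
    """Model class, cost function, priors and sampler settings.

    Hyperparameters default to weakly-informative choices: mass ~ gamma with
    mean 2 kg / SD 2 kg, σ_t ~ gamma mean 0.25 / SD 0.25, σ_x ~ gamma with
    its mode at 0.05 — the canonical ~5% Weber fraction for visual distance
    (shape 3, rate 40; σ_x is only weakly identified from press-times, so
    its posterior stays close to this prior), linear factor ~ gamma mean
    0.3 / SD 0.3 s/m.  σ_x and per-subject σ_t can instead be fixed, as done for
    the phases beyond feedback.
    """

    model_class: str = "newtonian"
    cost_function: str = "quadratic"
    mass_prior: GammaPrior = field(default_factory=lambda: gamma_from_mean_sd(2.0, 2.0))
    sigma_t_prior: GammaPrior = field(default_factory=lambda: gamma_from_mean_sd(0.25, 0.25))
    sigma_x_prior: GammaPrior = field(default_factory=lambda: GammaPrior(shape=3.0, rate=40.0))
    linear_factor_prior: GammaPrior = field(default_factory=lambda: gamma_from_mean_sd(0.3, 0.3))
    sigma_x_fixed: float | None = None
    sigma_t_fixed: dict[str, float] | None = None
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def __post_init__(self):
        if self.model_class not in ("linear", "newtonian"):
            raise ValueError(f"unknown model_class {self.model_class!r}")
        if self.cost_function not in ("zero_one", "absolute", "quadratic"):
            raise ValueError(f"unknown cost_function {self.cost_function!r}")

    @property
    def slope(self) -> float:
        """Slope of ln t_int in ln x_per: ½ (Newtonian) or 1 (linear)."""
        return 0.5 if self.model_class == "newtonian" else 1.0

    def log_intercept(self, param: float) -> float:
        """ln t_int at x_per = 1 m for mass (Newtonian) or factor (linear)."""
        if self.model_class == "newtonian":
            env = self.env
            return np.log(param) + 0.5 * np.log(2.0 * env.deceleration) - np.log(
                env.interaction_force
            )
        return np.log(param)

    @property
    def scale_prior(self) -> GammaPrior:
        return self.mass_prior if self.model_class == "newtonian" else self.linear_factor_prior


# ---------------------------------------------------------------------------
# joint density


def log_joint(trials: pd.DataFrame, latents: dict, spec: InteractionModelSpec) -> float:
    """Log joint density of one subject's trials and latent values.

    ``latents`` holds ``scale`` (mapping puck_id → mass or linear factor),
    ``sigma_t``, ``sigma_x`` and ``x_per`` (array aligned with ``trials``).
    Values outside the support return −inf rather than raising.
    """
    x = trials["x"].to_numpy(float)
    t = trials["t_pre"].to_numpy(float)
    if np.any(x <= 0) or np.any(t <= 0):
        raise ValueError("trials must have positive x and t_pre")
    scale = latents["scale"]
    sigma_t = float(latents["sigma_t"])
    sigma_x = float(latents["sigma_x"])
    x_per = np.asarray(latents["x_per"], dtype=float)
    if (
        sigma_t <= 0
        or sigma_x <= 0
        or np.any(x_per <= 0)
        or any(v <= 0 for v in scale.values())
    ):
        return -np.inf

    lp = 0.0
    # uniform p(x) over the arena
    lo, hi = spec.env.distance_range
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        return -np.inf
    lp += -len(x) * np.log(hi - lo)
    # scalar priors
    for v in scale.values():
        lp += _gamma_logpdf(v, spec.scale_prior)
    if spec.sigma_t_fixed is None:
        lp += _gamma_logpdf(sigma_t, spec.sigma_t_prior)
    if spec.sigma_x_fixed is None:
        lp += _gamma_logpdf(sigma_x, spec.sigma_x_prior)
    # percept latents: log-normal with mode at x
    z = np.log(x_per)
    lp += float(np.sum(_norm_logpdf(z, np.log(x) + sigma_x**2, sigma_x) - z))
    # press-time likelihood
    a = np.array([spec.log_intercept(scale[k]) for k in trials["puck_id"]])
    s = cost_shift(spec.cost_function, sigma_t)
    mu = a + spec.slope * z + s
    lp += float(np.sum(_norm_logpdf(np.log(t), mu, sigma_t) - np.log(t)))
    return lp


def _gamma_logpdf(x, prior: GammaPrior) -> float:
    if x <= 0:
        return -np.inf
    return float(
        prior.shape * np.log(prior.rate)
        + (prior.shape - 1) * np.log(x)
        - prior.rate * x
        - _lgamma(prior.shape)
    )


# ---------------------------------------------------------------------------
# sampler


class _AdaptiveScale:
    """Robbins–Monro style step-size adaptation toward ~44% acceptance."""

    def __init__(self, scale=0.1):
        self.scale = scale
        self._acc = 0
        self._n = 0

    def update(self, accepted: bool, adapting: bool):
        self.update_rate(float(accepted), adapting)

    def update_rate(self, rate: float, adapting: bool):
        """Accumulate an acceptance rate in [0, 1] for one iteration."""
        self._acc += rate
        self._n += 1
        if adapting and self._n >= 50:
            mean_rate = self._acc / self._n
            self.scale *= float(np.exp(1.2 * (mean_rate - 0.44)))
            self.scale = float(np.clip(self.scale, 1e-4, 5.0))
            self._acc = 0
            self._n = 0


class _SubjectSampler:
    """Gibbs-within-Metropolis sampler for one subject's trials."""

    def __init__(self, trials: pd.DataFrame, spec: InteractionModelSpec, sigma_t_fixed=None):
        self.spec = spec
        self.ln_x = np.log(trials["x"].to_numpy(float))
        self.ln_t = np.log(trials["t_pre"].to_numpy(float))
        self.pucks = list(dict.fromkeys(trials["puck_id"]))
        self.k_idx = trials["puck_id"].map({p: i for i, p in enumerate(self.pucks)}).to_numpy()
        self.n = len(self.ln_t)
        self.b = spec.slope
        self.sigma_t_fixed = sigma_t_fixed
        self.sigma_x_fixed = spec.sigma_x_fixed

    # log target over (log-scalars, z); all Jacobians included
    def _scalar_logpost(self, theta, z):
        spec = self.spec
        scale_vals = np.exp(theta[: len(self.pucks)])
        sigma_t = self.sigma_t_fixed if self.sigma_t_fixed is not None else np.exp(theta[-2])
        sigma_x = self.sigma_x_fixed if self.sigma_x_fixed is not None else np.exp(theta[-1])
        a = np.array([spec.log_intercept(v) for v in scale_vals])[self.k_idx]
        s = cost_shift(spec.cost_function, sigma_t)
        lp = float(np.sum(_norm_logpdf(self.ln_t, a + self.b * z + s, sigma_t)))
        lp += float(np.sum(_norm_logpdf(z, self.ln_x + sigma_x**2, sigma_x)))
        for v in scale_vals:
            lp += _gamma_logpdf(v, spec.scale_prior) + np.log(v)
        if self.sigma_t_fixed is None:
            lp += _gamma_logpdf(sigma_t, spec.sigma_t_prior) + np.log(sigma_t)
        if self.sigma_x_fixed is None:
            lp += _gamma_logpdf(sigma_x, spec.sigma_x_prior) + np.log(sigma_x)
        return lp

    def _marginal_logpost(self, theta):
        """Scalar posterior with the percept latents integrated analytically.

        In log space the percept enters the press-time mean linearly, so the
        marginal of ln t_pre is Gaussian with variance σ_t² + b²σ_x².  The
        joint density with latents is unbounded as σ_x → 0 (a density spike
        with vanishing mass), so MAP extraction uses this marginal instead.
        """
        spec = self.spec
        scale_vals = np.exp(theta[: len(self.pucks)])
        sigma_t = self.sigma_t_fixed if self.sigma_t_fixed is not None else float(np.exp(theta[-2]))
        sigma_x = self.sigma_x_fixed if self.sigma_x_fixed is not None else float(np.exp(theta[-1]))
        a = np.log(scale_vals)[self.k_idx] + self._a_offset
        s = cost_shift(spec.cost_function, sigma_t)
        mu = a + self.b * (self.ln_x + sigma_x**2) + s
        sd = np.sqrt(sigma_t**2 + self.b**2 * sigma_x**2)
        lp = float(np.sum(_norm_logpdf(self.ln_t, mu, sd)))
        for v in scale_vals:
            lp += _gamma_logpdf(v, spec.scale_prior)
        if self.sigma_t_fixed is None:
            lp += _gamma_logpdf(sigma_t, spec.sigma_t_prior)
        if self.sigma_x_fixed is None:
            lp += _gamma_logpdf(sigma_x, spec.sigma_x_prior)
        return lp

    def _gibbs_z(self, theta, rng):
        spec = self.spec
        scale_vals = np.exp(theta[: len(self.pucks)])
        sigma_t = self.sigma_t_fixed if self.sigma_t_fixed is not None else np.exp(theta[-2])
        sigma_x = self.sigma_x_fixed if self.sigma_x_fixed is not None else np.exp(theta[-1])
        a = np.array([spec.log_intercept(v) for v in scale_vals])[self.k_idx]
        s = cost_shift(spec.cost_function, sigma_t)
        prec = 1.0 / sigma_x**2 + self.b**2 / sigma_t**2
        mean = (
            (self.ln_x + sigma_x**2) / sigma_x**2
            + self.b * (self.ln_t - a - s) / sigma_t**2
        ) / prec
        return mean + rng.standard_normal(self.n) / np.sqrt(prec)

    def _init_theta(self, rng):
        spec = self.spec
        theta = np.empty(len(self.pucks) + 2)
        s0 = cost_shift(spec.cost_function, 0.25)
        for i in range(len(self.pucks)):
            mask = self.k_idx == i
            a_hat = float(np.mean(self.ln_t[mask] - self.b * self.ln_x[mask])) - s0
            if spec.model_class == "newtonian":
                env = spec.env
                ln_m = a_hat - 0.5 * np.log(2 * env.deceleration) + np.log(env.interaction_force)
                theta[i] = ln_m
            else:
                theta[i] = a_hat
        theta[-2] = np.log(0.25)
        theta[-1] = np.log(self.sigma_x_fixed if self.sigma_x_fixed is not None else spec.sigma_x_prior.mean)
        theta += rng.normal(0.0, 0.05, size=theta.shape)  # overdisperse chains
        return theta

    def _update_sigma_x_joint(self, theta, z, rng, step=None):
        """Joint non-centred move of σ_x and all percept latents.

        σ_x couples tightly to the latent spread, so a conditional update
        barely moves.  Instead σ_x is proposed together with the latents,
        which are carried along by rescaling their standardized residuals,
        z' = ln x + σ_x'² + (z − ln x − σ_x²)(σ_x'/σ_x); the percept-prior
        terms cancel against the transformation Jacobian.  Without ``step``
        the proposal is an independence draw from the σ_x prior (the prior
        cancels too, leaving the press-time likelihood ratio — a global move
        that escapes sticky latent configurations); with ``step`` it is a
        local random walk on ln σ_x that decorrelates within a
        configuration.  The sampler uses both each sweep.
        """
        sigma_x = float(np.exp(theta[-1]))
        if step is None:
            sigma_x_p = float(self.spec.sigma_x_prior.sample(rng))
            log_corr = 0.0
        else:
            sigma_x_p = sigma_x * float(np.exp(rng.normal(0.0, step)))
            log_corr = (
                _gamma_logpdf(sigma_x_p, self.spec.sigma_x_prior)
                - _gamma_logpdf(sigma_x, self.spec.sigma_x_prior)
                + np.log(sigma_x_p)
                - np.log(sigma_x)
            )
        z_p = self.ln_x + sigma_x_p**2 + (z - self.ln_x - sigma_x**2) * (sigma_x_p / sigma_x)

        scale_vals = np.exp(theta[: len(self.pucks)])
        sigma_t = self.sigma_t_fixed if self.sigma_t_fixed is not None else float(np.exp(theta[-2]))
        a = np.log(scale_vals)[self.k_idx] + self._a_offset
        s = cost_shift(self.spec.cost_function, sigma_t)

        def lik(zz):
            return float(np.sum(_norm_logpdf(self.ln_t, a + self.b * zz + s, sigma_t)))

        if np.log(rng.uniform()) < lik(z_p) - lik(z) + log_corr:
            theta = theta.copy()
            theta[-1] = np.log(sigma_x_p)
            return theta, z_p, True
        return theta, z, False

    # intercept offset: a_k = ln(scale_k) + offset
    @property
    def _a_offset(self) -> float:
        if self.spec.model_class == "newtonian":
            env = self.spec.env
            return 0.5 * np.log(2 * env.deceleration) - np.log(env.interaction_force)
        return 0.0

    def _update_scales(self, theta, z, sigma_t, rng):
        """Independence-MH update of each puck's log mass / log factor.

        The Gaussian full conditional under a flat prior on the log scale is
        used as the proposal; the Metropolis correction accounts for the
        gamma prior, so acceptance is near one and draws are almost i.i.d.
        """
        s = cost_shift(self.spec.cost_function, sigma_t)
        resid = self.ln_t - self.b * z - s - self._a_offset
        for k in range(len(self.pucks)):
            mask = self.k_idx == k
            n_k = int(mask.sum())
            mu_q = float(np.mean(resid[mask]))
            sd_q = sigma_t / np.sqrt(n_k)
            cur = theta[k]
            prop = rng.normal(mu_q, sd_q)

            def extra(v):  # terms beyond the Gaussian likelihood kernel
                return _gamma_logpdf(np.exp(v), self.spec.scale_prior) + v

            # likelihood kernels cancel against the proposal density exactly
            if np.log(rng.uniform()) < extra(prop) - extra(cur):
                theta[k] = prop
        return theta

    def run_chain(self, seed, warmup, draws):
        rng = np.random.default_rng(seed)
        theta = self._init_theta(rng)
        n_scale = len(self.pucks)
        step_t = _AdaptiveScale(0.1)
        step_x = _AdaptiveScale(0.3)
        z = self._gibbs_z(theta, rng)
        out = {j: np.empty(draws) for j in range(n_scale + 2)}
        out_z = np.empty((draws, self.n))
        out_lp = np.empty(draws)
        out_mlp = np.empty(draws)
        for it in range(warmup + draws):
            adapting = it < warmup
            z = self._gibbs_z(theta, rng)
            sigma_t = (
                self.sigma_t_fixed if self.sigma_t_fixed is not None else float(np.exp(theta[-2]))
            )
            theta = self._update_scales(theta, z, sigma_t, rng)
            if self.sigma_t_fixed is None:
                lp = self._scalar_logpost(theta, z)
                for _ in range(4):  # several cheap moves per sweep: RW mixes slowly
                    prop = theta.copy()
                    prop[-2] += rng.normal(0.0, step_t.scale)
                    lp_prop = self._scalar_logpost(prop, z)
                    accept = np.log(rng.uniform()) < lp_prop - lp
                    if accept:
                        theta, lp = prop, lp_prop
                    step_t.update(accept, adapting)
            if self.sigma_x_fixed is None:
                for _ in range(2):
                    theta, z, _acc = self._update_sigma_x_joint(theta, z, rng)
                for _ in range(3):
                    theta, z, acc = self._update_sigma_x_joint(theta, z, rng, step=step_x.scale)
                    step_x.update(acc, adapting)
            if it >= warmup:
                d = it - warmup
                for j in range(n_scale + 2):
                    out[j][d] = theta[j]
                out_z[d] = z
                out_lp[d] = self._scalar_logpost(theta, z)
                out_mlp[d] = self._marginal_logpost(theta)
        params = {}
        label = "m" if self.spec.model_class == "newtonian" else "c"
        for i, p in enumerate(self.pucks):
            params[f"{label}[{p}]"] = np.exp(out[i])
        params["sigma_t"] = (
            np.full(draws, self.sigma_t_fixed)
            if self.sigma_t_fixed is not None
            else np.exp(out[n_scale])
        )
        params["sigma_x"] = (
            np.full(draws, self.sigma_x_fixed)
            if self.sigma_x_fixed is not None
            else np.exp(out[n_scale + 1])
        )
        return params, np.exp(out_z), out_lp, out_mlp


@dataclass
class SubjectPosterior:
    """Posterior samples for one subject: (chains, draws) per parameter."""

    subject_id: str
    pucks: list[str]
    params: dict[str, np.ndarray]
    x_per: np.ndarray  # (chains, draws, n_trials)
    log_joint: np.ndarray  # (chains, draws), full joint incl. latent terms
    marginal_log_post: np.ndarray  # (chains, draws), percepts integrated out
    diagnostics: pd.DataFrame
    converged: bool

    def map_index(self) -> tuple[int, int]:
        # the joint with latents is unbounded as sigma_x -> 0; rank by the
        # marginal scalar posterior instead
        flat = np.argmax(self.marginal_log_post)
        return np.unravel_index(flat, self.marginal_log_post.shape)

    def map_params(self) -> dict[str, float]:
        c, d = self.map_index()
        return {k: float(v[c, d]) for k, v in self.params.items()}

    def map_x_per(self) -> np.ndarray:
        """Percepts of the MAP draw (a sample from their conditional)."""
        c, d = self.map_index()
        return self.x_per[c, d]


@dataclass
class InteractionPosterior:
    spec: InteractionModelSpec
    subjects: dict[str, SubjectPosterior]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (subject, chain, draw, parameter, value) table."""
        rows = []
        for sid, post in self.subjects.items():
            for name, arr in post.params.items():
                ch, dr = arr.shape
                rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "chain": np.repeat(np.arange(ch), dr),
                            "draw": np.tile(np.arange(dr), ch),
                            "parameter": name,
                            "value": arr.ravel(),
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _diagnose(params: dict[str, np.ndarray]) -> tuple[pd.DataFrame, bool]:
    import arviz as az

    rows = []
    ok = True
    for name, arr in params.items():
        if np.allclose(arr, arr.flat[0]):  # fixed parameter
            rows.append({"parameter": name, "rhat": 1.0, "ess": float(arr.size)})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(arr))
            ess = float(az.ess(arr))
        rows.append({"parameter": name, "rhat": rhat, "ess": ess})
        if not (rhat < 1.01 and ess > 400):
            ok = False
    return pd.DataFrame(rows), ok


def fit(trials: pd.DataFrame, spec: InteractionModelSpec) -> InteractionPosterior:
    """Fit the interaction model independently to each subject's trials.

    Emits a warning (and flags the subject) when the split-chain R-hat
    exceeds 1.01 or the effective sample size falls below 400 for any free
    parameter.
    """
    if "subject_id" not in trials.columns:
        trials = trials.assign(subject_id="s01")
    subjects = {}
    mc = spec.mcmc
    for si, (sid, sub) in enumerate(trials.groupby("subject_id", sort=True)):
        for puck, grp in sub.groupby("puck_id"):
            if len(grp) < 2:
                raise ValueError(f"subject {sid}: puck {puck} has fewer than 2 trials")
        stf = None
        if spec.sigma_t_fixed is not None:
            if sid not in spec.sigma_t_fixed:
                raise ValueError(f"sigma_t_fixed missing subject {sid}")
            stf = spec.sigma_t_fixed[sid]
        sampler = _SubjectSampler(sub, spec, sigma_t_fixed=stf)
        chain_params, chain_z, chain_lp, chain_mlp = [], [], [], []
        for c in range(mc.chains):
            seed = np.random.SeedSequence([mc.seed, si, c]).generate_state(1)[0]
            p, zz, lp, mlp = sampler.run_chain(seed, mc.warmup, mc.draws)
            chain_params.append(p)
            chain_z.append(zz)
            chain_lp.append(lp)
            chain_mlp.append(mlp)
        params = {
            k: np.stack([cp[k] for cp in chain_params]) for k in chain_params[0]
        }
        diags, ok = _diagnose(params)
        if not ok:
            warnings.warn(
                f"subject {sid}: convergence diagnostics exceeded thresholds "
                "(R-hat >= 1.01 or ESS <= 400)",
                stacklevel=2,
            )
        subjects[sid] = SubjectPosterior(
            subject_id=sid,
            pucks=sampler.pucks,
            params=params,
            x_per=np.stack(chain_z),
            log_joint=np.stack(chain_lp),
            marginal_log_post=np.stack(chain_mlp),
            diagnostics=diags,
            converged=ok,
        )
    return InteractionPosterior(spec=spec, subjects=subjects)


@dataclass(frozen=True)
class NuisanceFixes:
    sigma_x: float
    sigma_t: dict[str, float]


def fix_nuisance(posterior: InteractionPosterior) -> NuisanceFixes:
    """Pooled σ_x MAP and per-subject σ_t MAPs for reuse in later phases."""
    if not posterior.subjects:
        raise ValueError("posterior has no subjects")
    sigma_x_maps, sigma_t = [], {}
    for sid, post in posterior.subjects.items():
        mp = post.map_params()
        sigma_x_maps.append(mp["sigma_x"])
        sigma_t[sid] = mp["sigma_t"]
    return NuisanceFixes(sigma_x=float(np.mean(sigma_x_maps)), sigma_t=sigma_t)


def posterior_predictive_press_times(
    posterior: InteractionPosterior,
    trials: pd.DataFrame,
    spec: InteractionModelSpec,
    n_draws: int = 50,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Press-times regenerated through the full generative path.

    For each retained posterior draw: sample a fresh percept for every trial,
    form the intention from the drawn mass/factor, apply the cost shift and
    log-normal motor noise.  Returns ``{subject_id: (n_draws, n_trials)}``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if "subject_id" not in trials.columns:
        trials = trials.assign(subject_id="s01")
    rng = np.random.default_rng(seed)
    label = "m" if spec.model_class == "newtonian" else "c"
    out = {}
    for sid, sub in trials.groupby("subject_id", sort=True):
        post = posterior.subjects[sid]
        ch, dr = post.log_joint.shape
        idx = np.linspace(0, ch * dr - 1, n_draws).astype(int)
        x = sub["x"].to_numpy(float)
        a_cols = np.empty((len(idx), len(x)))
        sims = np.empty((len(idx), len(x)))
        for row, flat in enumerate(idx):
            c, d = np.unravel_index(flat, (ch, dr))
            sigma_t = post.params["sigma_t"][c, d]
            sigma_x = post.params["sigma_x"][c, d]
            scale = {
                p: post.params[f"{label}[{p}]"][c, d] for p in post.pucks
            }
            x_per = np.exp(rng.normal(np.log(x) + sigma_x**2, sigma_x))
            a = np.array([spec.log_intercept(scale[k]) for k in sub["puck_id"]])
            mu = a + spec.slope * np.log(x_per) + cost_shift(spec.cost_function, sigma_t)
            sims[row] = np.exp(rng.normal(mu, sigma_t))
        out[sid] = sims
    return out


@dataclass
class ResidualReport:
    residuals: pd.DataFrame  # subject_id, puck_id, x, observed, predicted, residual
    rho: float
    pvalue: float
    degenerate: bool

    @property
    def per_subject(self) -> pd.DataFrame:
        rows = []
        for sid, grp in self.residuals.groupby("subject_id"):
            r, p = stats.spearmanr(grp["residual"], grp["x"])
            rows.append({"subject_id": sid, "rho": r, "pvalue": p})
        return pd.DataFrame(rows)


def residual_analysis(
    posterior: InteractionPosterior, trials: pd.DataFrame, spec: InteractionModelSpec
) -> ResidualReport:
    """Residuals of observed press-times against the MAP intention.

    The prediction for each trial is the intended press-time at the MAP
    percept and MAP mass/factor (the deterministic node of the model); the
    report carries the Spearman correlation of pooled residuals with the true
    initial distance — near zero when the fitted functional form matches the
    generator, systematically signed when it does not.
    """
    if "subject_id" not in trials.columns:
        trials = trials.assign(subject_id="s01")
    if len(trials) < 3:
        raise ValueError("need at least 3 trials for a residual correlation")
    label = "m" if spec.model_class == "newtonian" else "c"
    rows = []
    for sid, sub in trials.groupby("subject_id", sort=True):
        post = posterior.subjects[sid]
        mp = post.map_params()
        a = np.array(
            [spec.log_intercept(mp[f"{label}[{k}]"]) for k in sub["puck_id"]]
        )
        # MAP percepts: the mode of the latent conditional at the MAP
        # scalars (deterministic), not a posterior draw
        sigma_t, sigma_x = mp["sigma_t"], mp["sigma_x"]
        b = spec.slope
        ln_x = np.log(sub["x"].to_numpy(float))
        ln_t = np.log(sub["t_pre"].to_numpy(float))
        s = cost_shift(spec.cost_function, sigma_t)
        prec = 1.0 / sigma_x**2 + b**2 / sigma_t**2
        z = ((ln_x + sigma_x**2) / sigma_x**2 + b * (ln_t - a - s) / sigma_t**2) / prec
        pred = np.exp(a + b * z)
        obs = sub["t_pre"].to_numpy(float)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "puck_id": sub["puck_id"].to_numpy(),
                    "x": sub["x"].to_numpy(float),
                    "observed": obs,
                    "predicted": pred,
                    "residual": obs - pred,
                }
            )
        )
    res = pd.concat(rows, ignore_index=True)
    if np.allclose(res["residual"], 0.0, atol=1e-12) or res["residual"].nunique() == 1:
        return ResidualReport(residuals=res, rho=0.0, pvalue=1.0, degenerate=True)
    rho, p = stats.spearmanr(res["residual"], res["x"])
    return ResidualReport(residuals=res, rho=float(rho), pvalue=float(p), degenerate=False)
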