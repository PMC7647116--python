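"""Model selection and distributional evaluation.

Product-space (Carlin–Chib) model selection between the Newtonian and linear
press-time models: a trans-model chain carries the parameters of both models
plus a latent index choosing which one explains the data at each iteration;
with equal prior model probabilities the Bayes factor equals the posterior
odds of the index.  The press-time likelihood is used with the percept
latent integrated out analytically — in log space the percept is Gaussian
and enters linearly, so the marginal of ln t_pre is exactly Gaussian with
variance σ_t² + b²σ_x² (b = ½ Newtonian, 1 linear); the marginalisation is
exact and leaves the Bayes factor unchanged while letting the index mix.
Pseudo-priors for the inactive model are moment-matched to pilot
single-model posteriors, the standard device for making the index jump.

Also here: the two-sample Kolmogorov–Smirnov statistic, a histogram-based
Kullback–Leibler divergence between observed and posterior-predictive
press-times, and a Bayesian single-change-point model for learning curves
(unknown change trial τ, distinct mean error levels before/after, common
noise SD; τ and the noise scale are marginalised by exact enumeration /
quadrature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .interaction import (
    InteractionModelSpec,
    MCMCSettings,
    _gamma_logpdf,
    _norm_logpdf,
)
from .synthetic import cost_shift

__all__ = [
    "ProductSpaceSpec",
    "BayesFactorReport",
    "product_space_bayes_factor",
    "ks_two_sample",
    "kl_press_time_divergence",
    "ChangePointResult",
    "change_point_fit",
    "EVIDENCE_BAND",
]

EVIDENCE_BAND = 3.2  # posterior odds beyond which evidence counts as substantial


@dataclass(frozen=True)
class ProductSpaceSpec:
    """Settings for the trans-model sampler."""

    prior_prob_newtonian: float = 0.5
    pilot: MCMCSettings = field(default_factory=lambda: MCMCSettings(chains=1, warmup=300, draws=300))
    mcmc: MCMCSettings = field(default_factory=lambda: MCMCSettings(chains=2, warmup=300, draws=700))
    pseudo_sd_floor: float = 0.02
    param_sweeps: int = 2

    def __post_init__(self):
        if not 0 < self.prior_prob_newtonian < 1:
            raise ValueError("prior_prob_newtonian must be in (0, 1)")


class _MarginalModel:
    """Marginal press-time likelihood of one model class for one subject."""

    def __init__(self, trials: pd.DataFrame, spec: InteractionModelSpec, subject_id=None):
        self.spec = spec
        self.b = spec.slope
        self.sigma_x = (
            spec.sigma_x_fixed if spec.sigma_x_fixed is not None else spec.sigma_x_prior.mean
        )
        if len(trials):
            self.ln_x = np.log(trials["x"].to_numpy(float))
            self.ln_t = np.log(trials["t_pre"].to_numpy(float))
            self.pucks = list(dict.fromkeys(trials["puck_id"]))
            self.k_idx = (
                trials["puck_id"].map({p: i for i, p in enumerate(self.pucks)}).to_numpy()
            )
        else:
            self.ln_x = np.empty(0)
            self.ln_t = np.empty(0)
            self.pucks = ["none"]
            self.k_idx = np.empty(0, dtype=int)
        self.sigma_t_fixed = None
        if spec.sigma_t_fixed is not None and subject_id is not None:
            self.sigma_t_fixed = spec.sigma_t_fixed.get(subject_id)
        self.dim = len(self.pucks) + (0 if self.sigma_t_fixed is not None else 1)

    def _unpack(self, phi):
        scale = np.exp(phi[: len(self.pucks)])
        sigma_t = (
            self.sigma_t_fixed if self.sigma_t_fixed is not None else float(np.exp(phi[-1]))
        )
        return scale, sigma_t

    def loglik(self, phi) -> float:
        if len(self.ln_t) == 0:
            return 0.0
        scale, sigma_t = self._unpack(phi)
        a = np.array([self.spec.log_intercept(v) for v in scale])[self.k_idx]
        mu = a + self.b * (self.ln_x + self.sigma_x**2) + cost_shift(
            self.spec.cost_function, sigma_t
        )
        sd = np.sqrt(sigma_t**2 + self.b**2 * self.sigma_x**2)
        return float(np.sum(_norm_logpdf(self.ln_t, mu, sd) - self.ln_t))

    def logprior(self, phi) -> float:
        scale, sigma_t = self._unpack(phi)
        lp = 0.0
        for i, v in enumerate(scale):
            lp += _gamma_logpdf(v, self.spec.scale_prior) + phi[i]
        if self.sigma_t_fixed is None:
            lp += _gamma_logpdf(sigma_t, self.spec.sigma_t_prior) + phi[-1]
        return lp

    def init(self, rng):
        phi = np.empty(self.dim)
        s0 = cost_shift(self.spec.cost_function, 0.25)
        for i in range(len(self.pucks)):
            mask = self.k_idx == i
            if len(self.ln_t) and mask.any():
                a_hat = float(np.mean(self.ln_t[mask] - self.b * self.ln_x[mask])) - s0
            else:
                a_hat = np.log(self.spec.scale_prior.mean)
                if self.spec.model_class == "newtonian":
                    a_hat = self.spec.log_intercept(self.spec.scale_prior.mean)
            # invert the intercept to the natural parameter
            if self.spec.model_class == "newtonian":
                env = self.spec.env
                phi[i] = a_hat - 0.5 * np.log(2 * env.deceleration) + np.log(env.interaction_force)
            else:
                phi[i] = a_hat
        if self.sigma_t_fixed is None:
            phi[-1] = np.log(0.25)
        return phi + rng.normal(0, 0.05, self.dim)


def _pilot_posterior(model: _MarginalModel, settings: MCMCSettings, rng):
    """Short adaptive MH run; returns (pseudo mean, pseudo sd) per coordinate."""
    phi = model.init(rng)
    lp = model.loglik(phi) + model.logprior(phi)
    scales = np.full(model.dim, 0.1)
    acc = np.zeros(model.dim)
    samples = np.empty((settings.draws, model.dim))
    for it in range(settings.warmup + settings.draws):
        for j in range(model.dim):
            prop = phi.copy()
            prop[j] += rng.normal(0, scales[j])
            lp_prop = model.loglik(prop) + model.logprior(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                phi, lp = prop, lp_prop
                acc[j] += 1
            if it < settings.warmup and (it + 1) % 50 == 0:
                scales[j] *= np.exp(1.2 * (acc[j] / 50 - 0.44))
                scales[j] = np.clip(scales[j], 1e-4, 5.0)
                acc[j] = 0
        if it >= settings.warmup:
            samples[it - settings.warmup] = phi
    return samples.mean(axis=0), samples.std(axis=0)


@dataclass
class BayesFactorReport:
    """Posterior odds Newtonian : linear with interpretation."""

    K: float
    phase_subset: str
    interpretation: str
    n_newtonian: int
    n_linear: int
    per_subject: dict[str, float]
    bounded: bool  # True when the index never visited one model

    @staticmethod
    def interpret(K: float) -> str:
        if K >= EVIDENCE_BAND:
            return "substantial evidence for the Newtonian model"
        if K > 1:
            return "weak evidence for the Newtonian model"
        if K == 1:
            return "no evidence either way"
        if K > 1 / EVIDENCE_BAND:
            return "weak evidence for the linear model"
        return "substantial evidence for the linear model"


def product_space_bayes_factor(
    trials: pd.DataFrame,
    spec_linear: InteractionModelSpec,
    spec_newtonian: InteractionModelSpec,
    ps_spec: ProductSpaceSpec | None = None,
    phase_subset: str = "all",
) -> BayesFactorReport:
    """Bayes factor Newtonian : linear via the product-space method.

    Subjects are independent with subject-specific parameters, so the joint
    Bayes factor is the product of per-subject factors; each subject gets its
    own trans-model chain.  When the index never visits one of the models for
    a subject the factor is reported as the bound implied by a half-count and
    the report is flagged (pseudo-priors would need tuning to do better).
    """
    if ps_spec is None:
        ps_spec = ProductSpaceSpec()
    if spec_linear.model_class != "linear" or spec_newtonian.model_class != "newtonian":
        raise ValueError("specs must be a linear and a newtonian model, in that order")
    if len(trials) == 0 or "subject_id" not in trials.columns:
        trials = trials.assign(subject_id="s01") if len(trials) else pd.DataFrame(
            {"subject_id": ["s01"], "x": [np.nan], "t_pre": [np.nan], "puck_id": ["none"]}
        ).iloc[:0]
        groups = [("s01", trials)]
    else:
        groups = list(trials.groupby("subject_id", sort=True))
    if not groups:
        groups = [("s01", trials)]

    per_subject = {}
    tot_n = tot_l = 0
    bounded = False
    pi_N = ps_spec.prior_prob_newtonian
    log_prior_odds = np.log(pi_N) - np.log(1 - pi_N)
    for si, (sid, sub) in enumerate(groups):
        cN, cL, warn = _product_space_single(sub, spec_linear, spec_newtonian, ps_spec, si, sid)
        tot_n += cN
        tot_l += cL
        bounded |= warn
        K_j = ((cN + 0.5) / (cL + 0.5)) / np.exp(log_prior_odds)
        per_subject[sid] = float(K_j)
    K = float(np.prod(list(per_subject.values()))) if per_subject else 1.0
    if bounded:
        warnings.warn(
            "product-space index never visited one model for at least one "
            "subject; Bayes factor reported as a bound (tune pseudo-priors)",
            stacklevel=2,
        )
    return BayesFactorReport(
        K=K,
        phase_subset=phase_subset,
        interpretation=BayesFactorReport.interpret(K),
        n_newtonian=tot_n,
        n_linear=tot_l,
        per_subject=per_subject,
        bounded=bounded,
    )


def _product_space_single(sub, spec_linear, spec_newtonian, ps, subject_index, sid):
    mN = _MarginalModel(sub, spec_newtonian, subject_id=sid)
    mL = _MarginalModel(sub, spec_linear, subject_id=sid)
    seed_root = np.random.SeedSequence([ps.mcmc.seed, subject_index])
    rng_pilot = np.random.default_rng(seed_root.spawn(1)[0])
    pseudoN = _pilot_posterior(mN, ps.pilot, rng_pilot)
    pseudoL = _pilot_posterior(mL, ps.pilot, rng_pilot)
    pseudoN = (pseudoN[0], np.maximum(pseudoN[1], ps.pseudo_sd_floor))
    pseudoL = (pseudoL[0], np.maximum(pseudoL[1], ps.pseudo_sd_floor))
    log_pi_N = np.log(ps.prior_prob_newtonian)
    log_pi_L = np.log(1 - ps.prior_prob_newtonian)

    count_N = count_L = 0
    for c in range(ps.mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence([ps.mcmc.seed, subject_index, c + 1]))
        phiN = mN.init(rng)
        phiL = mL.init(rng)
        index_N = bool(rng.uniform() < ps.prior_prob_newtonian)
        lpN = mN.loglik(phiN) + mN.logprior(phiN)
        lpL = mL.loglik(phiL) + mL.logprior(phiL)
        for it in range(ps.mcmc.warmup + ps.mcmc.draws):
            # update active model parameters, refresh inactive from pseudo-prior
            if index_N:
                phiN, lpN = _mh_sweeps(mN, phiN, lpN, pseudoN[1], rng, ps.param_sweeps)
                phiL = pseudoL[0] + rng.normal(0, 1, mL.dim) * pseudoL[1]
                lpL = mL.loglik(phiL) + mL.logprior(phiL)
            else:
                phiL, lpL = _mh_sweeps(mL, phiL, lpL, pseudoL[1], rng, ps.param_sweeps)
                phiN = pseudoN[0] + rng.normal(0, 1, mN.dim) * pseudoN[1]
                lpN = mN.loglik(phiN) + mN.logprior(phiN)
            # Gibbs update of the model index
            wN = log_pi_N + lpN + _normal_logpdf_vec(phiL, *pseudoL)
            wL = log_pi_L + lpL + _normal_logpdf_vec(phiN, *pseudoN)
            p_N = 1.0 / (1.0 + np.exp(np.clip(wL - wN, -700, 700)))
            index_N = bool(rng.uniform() < p_N)
            if it >= ps.mcmc.warmup:
                if index_N:
                    count_N += 1
                else:
                    count_L += 1
    warn = count_N == 0 or count_L == 0
    return count_N, count_L, warn


def _normal_logpdf_vec(x, mean, sd):
    return float(np.sum(_norm_logpdf(x, mean, sd)))


def _mh_sweeps(model, phi, lp, step_sd, rng, sweeps):
    for _ in range(sweeps):
        for j in range(model.dim):
            prop = phi.copy()
            prop[j] += rng.normal(0, step_sd[j])
            lp_prop = model.loglik(prop) + model.logprior(prop)
            if np.log(rng.uniform()) < lp_prop - lp:
                phi, lp = prop, lp_prop
    return phi, lp


# ---------------------------------------------------------------------------
# distribution comparisons


def ks_two_sample(a, b) -> tuple[float, float]:
    """Classical two-sample Kolmogorov–Smirnov statistic and asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def kl_press_time_divergence(observed, predictive, bins: int = 50) -> float:
    """KL(observed ‖ predictive) on a shared histogram with add-one smoothing.

    Both samples are binned over their pooled range into ``bins`` equal bins;
    one pseudo-count per bin regularises empty bins.  Returns nats, ≥ 0 up to
    the smoothing bias.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predictive = np.asarray(predictive, dtype=float).ravel()
    if observed.size == 0 or predictive.size == 0:
        raise ValueError("both samples must be non-empty")
    if bins < 2:
        raise ValueError("need at least 2 bins")
    lo = min(observed.min(), predictive.min())
    hi = max(observed.max(), predictive.max())
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(observed, bins=edges)[0] + 1.0
    q = np.histogram(predictive, bins=edges)[0] + 1.0
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


# ---------------------------------------------------------------------------
# change point


@dataclass
class ChangePointResult:
    """Posterior over the change trial τ of a two-level mean model.

    ``tau_posterior[i]`` is P(change after trial i+1); ``map_tau`` is
    1-based: trials 1..τ share the first error level, τ+1..n the second.
    """

    tau_posterior: np.ndarray
    map_tau: int
    mean_before: float
    mean_after: float
    diffuse: bool

    @property
    def taus(self) -> np.ndarray:
        return np.arange(1, len(self.tau_posterior) + 1)


def change_point_fit(mean_errors_per_trial) -> ChangePointResult:
    """Bayesian single change point in a per-trial mean-error series.

    Model: y_t ~ N(μ₁, σ) for t ≤ τ and N(μ₂, σ) for t > τ, with a uniform
    prior on τ, weakly-informative conjugate normal priors on the levels
    (centred on the data mean, SD five times the data SD) and a common noise
    SD marginalised over a log-spaced grid.  The levels are integrated in
    closed form, so the τ posterior is exact enumeration.  A near-uniform τ
    posterior (relative entropy > 0.95) is flagged as diffuse rather than an
    error — it is what a constant series produces.
    """
    y = np.asarray(mean_errors_per_trial, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 trials")
    m0 = float(np.mean(y))
    sd = float(np.std(y))
    if sd == 0:
        sd = max(abs(m0), 1.0) * 1e-6
    s0 = 5.0 * sd
    sigmas = np.exp(np.linspace(np.log(sd / 10), np.log(sd * 10), 40))

    # centre the series: the level priors are then N(0, s0); this avoids
    # catastrophic cancellation in the segment sums for near-constant input
    yc = y - m0
    cs = np.concatenate([[0.0], np.cumsum(yc)])
    cs2 = np.concatenate([[0.0], np.cumsum(yc**2)])

    def seg_stats(i, j):  # trials i+1..j (0-based slice [i:j])
        ns = j - i
        s = cs[j] - cs[i]
        ss = cs2[j] - cs2[i]
        ybar = s / ns
        ssdev = max(ss - ns * ybar**2, 0.0)
        return ns, ybar, ssdev

    taus = np.arange(1, n)
    log_post = np.full((taus.size, sigmas.size), -np.inf)
    for ti, tau in enumerate(taus):
        segs = [seg_stats(0, tau), seg_stats(tau, n)]
        for si, sig in enumerate(sigmas):
            lp = 0.0
            for ns, ybar, ssdev in segs:
                lam = 1.0 + ns * s0**2 / sig**2
                lp += (
                    -0.5 * ns * np.log(2 * np.pi * sig**2)
                    - 0.5 * np.log(lam)
                    - 0.5 * (ssdev + ns * ybar**2 / lam) / sig**2
                )
            log_post[ti, si] = lp
    # uniform prior on tau, uniform-in-log prior on sigma
    log_tau = logsumexp(log_post, axis=1)
    log_tau -= logsumexp(log_tau)
    tau_post = np.exp(log_tau)
    map_tau = int(taus[np.argmax(tau_post)])

    # posterior means of the two levels, averaged over (tau, sigma)
    w = np.exp(log_post - logsumexp(log_post))
    mu1 = mu2 = 0.0
    for ti, tau in enumerate(taus):
        (n1, y1, _), (n2, y2, _) = seg_stats(0, tau), seg_stats(tau, n)
        for si, sig in enumerate(sigmas):
            post_mean = lambda ns, ybar: m0 + (ns * ybar / sig**2) / (
                ns / sig**2 + 1.0 / s0**2
            )
            mu1 += w[ti, si] * post_mean(n1, y1)
            mu2 += w[ti, si] * post_mean(n2, y2)

    uniform_entropy = np.log(taus.size)
    entropy = -float(np.sum(tau_post * np.log(np.maximum(tau_post, 1e-300))))
    diffuse = taus.size > 1 and entropy > 0.95 * uniform_entropy
    return ChangePointResult(
        tau_posterior=tau_post,
        map_tau=map_tau,
        mean_before=float(mu1),
        mean_after=float(mu2),
        diffuse=diffuse,
    )
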