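"""Bayesian mass inference from observed elastic collisions.

A subject watches frictionless 1-D elastic collisions between a familiar
puck (mass ``mF``, believed with some uncertainty from prior interaction)
and an unfamiliar one (mass ``mNF``, the target of inference).  Velocities
are perceived with multiplicative log-normal noise of log-scale ``σ_vel``
(default 0.2), the percept distribution having its mode at the actual
velocity.  Perceived pre-collision velocities and the two masses determine a
predicted outcome through the elastic-collision equations; the observed
post-collision velocities are modelled as log-normal (mode-anchored) around
that prediction.  Percept noise acts on speed; a percept cannot flip the
sign of a velocity, so a predicted outcome with the wrong sign has zero
likelihood.

Latents are the perceived pre-collision velocities of every collision, the
believed masses of the two known pucks (informative priors, e.g. the
interaction-model posteriors moment-matched to gammas), and ``mNF``.  The
sampler alternates vectorised random-walk Metropolis updates of the percepts
(collisions are conditionally independent) with scalar updates of the
log-masses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .physics import collision_implied_mass, elastic_collision
from .interaction import (
    GammaPrior,
    MCMCSettings,
    _AdaptiveScale,
    _diagnose,
    _gamma_logpdf,
    _norm_logpdf,
    gamma_from_mean_sd,
)
from .synthetic import CollisionEvent

__all__ = [
    "ObservationModelSpec",
    "ObservationPosterior",
    "MassPrior",
    "gamma_from_samples",
    "log_joint_observation",
    "fit_observation",
    "uncertainty_trajectory",
]


def gamma_from_samples(samples: np.ndarray) -> GammaPrior:
    """Moment-matched gamma prior from an empirical posterior sample set."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0 or np.any(samples <= 0):
        raise ValueError("samples must be non-empty and strictly positive")
    sd = float(np.std(samples))
    if sd == 0:
        sd = 1e-6 * float(np.mean(samples))
    return gamma_from_mean_sd(float(np.mean(samples)), sd)


class MassPrior:
    """Prior over a mass: parametric gamma or an empirical sample set.

    Empirical sample sets are moment-matched to a gamma by default (keeps the
    support positive and matches the gamma prior family used upstream); with
    ``empirical=True`` the raw samples are used through a Gaussian KDE on the
    log scale instead.
    """

    def __init__(self, source, empirical: bool = False):
        if isinstance(source, GammaPrior):
            self._gamma = source
            self._kde = None
        else:
            samples = np.asarray(source, dtype=float)
            if samples.size == 0 or np.any(samples <= 0):
                raise ValueError("prior samples must be non-empty and positive")
            if empirical:
                from scipy.stats import gaussian_kde

                self._kde = gaussian_kde(np.log(samples))
                self._gamma = gamma_from_samples(samples)  # kept for mean/sample
            else:
                self._kde = None
                self._gamma = gamma_from_samples(samples)

    @property
    def mean(self) -> float:
        return self._gamma.mean

    @property
    def variance(self) -> float:
        return self._gamma.shape / self._gamma.rate**2

    def logpdf(self, m: float) -> float:
        if m <= 0:
            return -np.inf
        if self._kde is not None:
            dens = float(self._kde(np.log(m))[0])
            if dens <= 0:
                return -np.inf
            return np.log(dens) - np.log(m)
        return _gamma_logpdf(m, self._gamma)


@dataclass(frozen=True)
class ObservationModelSpec:
    """Velocity-percept noise, mass priors, and sampler settings."""

    prior_mass_NF: MassPrior
    prior_mass_F: dict[str, MassPrior]
    sigma_vel: float = 0.2
    # percepts and the unknown mass are strongly coupled, so several full
    # update cycles per recorded draw keep the retained chain well mixed
    mcmc: MCMCSettings = field(default_factory=lambda: MCMCSettings(thin=4))

    def __post_init__(self):
        if self.sigma_vel <= 0:
            raise ValueError("sigma_vel must be positive")


def _events_arrays(events: Sequence[CollisionEvent]):
    vF = np.array([e.vF for e in events])
    vNF = np.array([e.vNF for e in events])
    uF = np.array([e.uF for e in events])
    uNF = np.array([e.uNF for e in events])
    pucks = list(dict.fromkeys(e.known_puck_id for e in events))
    k_idx = np.array([pucks.index(e.known_puck_id) for e in events])
    return vF, vNF, uF, uNF, pucks, k_idx


def _outcome_loglik(vF_per, vNF_per, mF, mNF, uF_obs, uNF_obs, sigma):
    """Log-likelihood of observed outcomes given percepts and masses.

    Mode-anchored log-normal on speed; sign mismatch between prediction and
    observation gives −inf (vectorised over collisions).
    """
    uF_pred, uNF_pred = elastic_collision(vF_per, vNF_per, mF, mNF)
    out = np.zeros_like(np.asarray(vF_per, dtype=float))
    for pred, obs in ((uF_pred, uF_obs), (uNF_pred, uNF_obs)):
        pred = np.asarray(pred, dtype=float)
        obs = np.asarray(obs, dtype=float)
        bad = (np.sign(pred) != np.sign(obs)) | (np.abs(pred) < 1e-12)
        mag_p = np.abs(np.where(bad, 1.0, pred))
        mag_o = np.abs(np.where(bad, 1.0, obs))
        term = _norm_logpdf(np.log(mag_o), np.log(mag_p) + sigma**2, sigma) - np.log(mag_o)
        out = out + np.where(bad, -np.inf, term)
    return out


def log_joint_observation(
    events: Sequence[CollisionEvent], latents: dict, spec: ObservationModelSpec
) -> float:
    """Log joint of the collision observations and latent values.

    ``latents``: ``vF_per``/``vNF_per`` arrays aligned with events, ``mF``
    mapping known puck id → believed mass, ``mNF``.  Out-of-support values
    return −inf.
    """
    vF, vNF, uF, uNF, pucks, k_idx = _events_arrays(events)
    vF_per = np.asarray(latents["vF_per"], dtype=float)
    vNF_per = np.asarray(latents["vNF_per"], dtype=float)
    mNF = float(latents["mNF"])
    mF_map = latents["mF"]
    if mNF <= 0 or any(v <= 0 for v in mF_map.values()):
        return -np.inf
    sigma = spec.sigma_vel
    lp = spec.prior_mass_NF.logpdf(mNF)
    for p in pucks:
        lp += spec.prior_mass_F[p].logpdf(float(mF_map[p]))
    if not np.isfinite(lp):
        return -np.inf
    # percept terms for moving pre-collision pucks; resting pucks are
    # perceived exactly (their percept must be zero)
    for v_true, v_per in ((vF, vF_per), (vNF, vNF_per)):
        moving = np.abs(v_true) > 1e-12
        if np.any(~moving) and np.any(np.abs(v_per[~moving]) > 1e-12):
            return -np.inf
        if np.any(np.sign(v_per[moving]) != np.sign(v_true[moving])):
            return -np.inf
        mag_t = np.abs(v_true[moving])
        mag_p = np.abs(v_per[moving])
        lp += float(
            np.sum(_norm_logpdf(np.log(mag_p), np.log(mag_t) + sigma**2, sigma) - np.log(mag_p))
        )
    mF_arr = np.array([mF_map[p] for p in pucks])[k_idx]
    lp += float(np.sum(_outcome_loglik(vF_per, vNF_per, mF_arr, mNF, uF, uNF, sigma)))
    return lp


class _CollisionSampler:
    def __init__(self, events: Sequence[CollisionEvent], spec: ObservationModelSpec):
        self.spec = spec
        self.vF, self.vNF, self.uF, self.uNF, self.pucks, self.k_idx = _events_arrays(events)
        for p in self.pucks:
            if p not in spec.prior_mass_F:
                raise ValueError(f"no prior for known puck {p!r}")
        self.n = len(self.vF)
        self.nf_moving = np.abs(self.vNF) > 1e-12
        self.sgnF = np.sign(self.vF)
        self.sgnNF = np.where(self.nf_moving, np.sign(self.vNF), 0.0)

    def _percept_logprior(self, w, v_true, moving):
        sigma = self.spec.sigma_vel
        out = np.zeros(self.n)
        mag_t = np.abs(np.where(moving, v_true, 1.0))
        term = _norm_logpdf(w, np.log(mag_t) + sigma**2, sigma)
        return np.where(moving, term, 0.0)

    def _collision_loglik(self, wF, wNF, mF_vals, mNF):
        vF_per = self.sgnF * np.exp(wF)
        vNF_per = np.where(self.nf_moving, self.sgnNF * np.exp(wNF), 0.0)
        mF_arr = mF_vals[self.k_idx]
        return _outcome_loglik(vF_per, vNF_per, mF_arr, mNF, self.uF, self.uNF, self.spec.sigma_vel)

    def _mass_logprior(self, ln_mF, ln_mNF):
        lp = self.spec.prior_mass_NF.logpdf(np.exp(ln_mNF)) + ln_mNF
        for i, p in enumerate(self.pucks):
            lp += self.spec.prior_mass_F[p].logpdf(np.exp(ln_mF[i])) + ln_mF[i]
        return lp

    def _init(self, rng):
        mF0 = np.array([self.spec.prior_mass_F[p].mean for p in self.pucks])
        implied = collision_implied_mass(self.vF, self.vNF, self.uF, mF0[self.k_idx])
        implied = implied[np.isfinite(implied) & (implied > 0)]
        mNF0 = float(np.median(implied)) if implied.size else self.spec.prior_mass_NF.mean
        wF = np.log(np.abs(self.vF))
        wNF = np.log(np.abs(np.where(self.nf_moving, self.vNF, 1.0)))
        jit = rng.normal(0, 0.02)
        return (
            wF + rng.normal(0, 0.02, self.n),
            wNF + rng.normal(0, 0.02, self.n),
            np.log(mF0) + rng.normal(0, 0.02, len(self.pucks)),
            np.log(mNF0) + jit,
        )

    def _percept_update(self, rng, adapting):
        """Vectorised RW-MH on the log-speed percepts of moving pucks."""
        for which in ("F", "NF"):
            if which == "F":
                w, step = self._wF, self._stepF
                v_true, moving = self.vF, np.ones(self.n, bool)
            else:
                if not np.any(self.nf_moving):
                    continue
                w, step = self._wNF, self._stepNF
                v_true, moving = self.vNF, self.nf_moving
            prop = w + rng.normal(0, step.scale, self.n)
            if which == "F":
                lik_prop = self._collision_loglik(prop, self._wNF, self._mF_vals, self._mNF)
            else:
                lik_prop = self._collision_loglik(self._wF, prop, self._mF_vals, self._mNF)
            pri = self._percept_logprior(w, v_true, moving)
            pri_prop = self._percept_logprior(prop, v_true, moving)
            acc = np.log(rng.uniform(size=self.n)) < (lik_prop + pri_prop) - (self._lik + pri)
            acc &= moving
            w[acc] = prop[acc]
            self._lik = np.where(acc, lik_prop, self._lik)
            n_eff = max(int(moving.sum()), 1)
            step.update_rate(float(acc.sum()) / n_eff, adapting)

    def _mass_update(self, rng, adapting):
        for j in range(len(self.pucks) + 1):
            if j < len(self.pucks):
                prop_mF = self._ln_mF.copy()
                prop_mF[j] += rng.normal(0, self._step_m[j].scale)
                prop_mNF = self._ln_mNF
            else:
                prop_mF = self._ln_mF
                prop_mNF = self._ln_mNF + rng.normal(0, self._step_m[j].scale)
            lik_prop = self._collision_loglik(self._wF, self._wNF, np.exp(prop_mF), np.exp(prop_mNF))
            num = np.sum(lik_prop) + self._mass_logprior(prop_mF, prop_mNF)
            den = np.sum(self._lik) + self._mass_logprior(self._ln_mF, self._ln_mNF)
            accept = np.log(rng.uniform()) < num - den
            if accept:
                self._ln_mF, self._ln_mNF, self._lik = prop_mF, prop_mNF, lik_prop
                self._mF_vals, self._mNF = np.exp(self._ln_mF), float(np.exp(self._ln_mNF))
            self._step_m[j].update(bool(accept), adapting)

    def _cycle(self, rng, adapting):
        self._percept_update(rng, adapting)
        self._mass_update(rng, adapting)

    def _log_joint_state(self):
        priF = self._percept_logprior(self._wF, self.vF, np.ones(self.n, bool))
        priNF = self._percept_logprior(self._wNF, self.vNF, self.nf_moving)
        # the percept-prior terms above are Gaussian in w (log-speed space);
        # consistent with the sampling parametrisation
        return float(
            np.sum(self._lik) + np.sum(priF) + np.sum(priNF)
            + self._mass_logprior(self._ln_mF, self._ln_mNF)
        )

    def run_chain(self, seed, warmup, draws, thin=1):
        rng = np.random.default_rng(seed)
        self._wF, self._wNF, self._ln_mF, self._ln_mNF = self._init(rng)
        self._stepF = _AdaptiveScale(0.1)
        self._stepNF = _AdaptiveScale(0.1)
        self._step_m = [_AdaptiveScale(0.05) for _ in range(len(self.pucks) + 1)]
        self._mF_vals = np.exp(self._ln_mF)
        self._mNF = float(np.exp(self._ln_mNF))
        self._lik = self._collision_loglik(self._wF, self._wNF, self._mF_vals, self._mNF)
        out_mNF = np.empty(draws)
        out_mF = np.empty((draws, len(self.pucks)))
        out_lp = np.empty(draws)
        for it in range(warmup + draws):
            adapting = it < warmup
            for _cycle in range(thin):
                self._cycle(rng, adapting)
            if it >= warmup:
                d = it - warmup
                out_mNF[d] = self._mNF
                out_mF[d] = self._mF_vals.copy()
                out_lp[d] = self._log_joint_state()
        return out_mNF, out_mF, out_lp


@dataclass
class ObservationPosterior:
    """Posterior over the unknown mass; samples are (chains, draws)."""

    m_NF: np.ndarray
    m_F: dict[str, np.ndarray]
    log_joint: np.ndarray
    diagnostics: pd.DataFrame
    converged: bool

    @property
    def mean(self) -> float:
        return float(np.mean(self.m_NF))

    @property
    def variance(self) -> float:
        return float(np.var(self.m_NF))

    @property
    def map(self) -> float:
        c, d = np.unravel_index(np.argmax(self.log_joint), self.log_joint.shape)
        return float(self.m_NF[c, d])

    def summary(self) -> dict:
        return {"mean": self.mean, "variance": self.variance, "map": self.map}


def fit_observation(
    events: Sequence[CollisionEvent], spec: ObservationModelSpec
) -> ObservationPosterior:
    """Posterior over the unknown puck's mass given the collision movie."""
    if len(events) < 1:
        raise ValueError("need at least one collision")
    sampler = _CollisionSampler(events, spec)
    mc = spec.mcmc
    chains_mNF, chains_mF, chains_lp = [], [], []
    for c in range(mc.chains):
        seed = np.random.SeedSequence([mc.seed, c]).generate_state(1)[0]
        m_nf, m_f, lp = sampler.run_chain(seed, mc.warmup, mc.draws, thin=mc.thin)
        chains_mNF.append(m_nf)
        chains_mF.append(m_f)
        chains_lp.append(lp)
    m_NF = np.stack(chains_mNF)
    m_F = {
        p: np.stack([cf[:, i] for cf in chains_mF]) for i, p in enumerate(sampler.pucks)
    }
    params = {"m_NF": m_NF, **{f"m_F[{p}]": arr for p, arr in m_F.items()}}
    diags, ok = _diagnose(params)
    if not ok:
        warnings.warn(
            "observation fit: convergence diagnostics exceeded thresholds",
            stacklevel=2,
        )
    return ObservationPosterior(
        m_NF=m_NF, m_F=m_F, log_joint=np.stack(chains_lp), diagnostics=diags, converged=ok
    )


def uncertainty_trajectory(
    events: Sequence[CollisionEvent],
    spec: ObservationModelSpec,
    checkpoints: Sequence[int] = (6, 24),
) -> dict[int, float]:
    """Posterior variance of the unknown mass after prefixes of the movie.

    Refits on the first ``k`` collisions for each checkpoint ``k``; the
    variance is non-increasing in expectation as more collisions are seen.
    """
    out = {}
    for k in checkpoints:
        if k > len(events):
            raise ValueError(f"checkpoint {k} exceeds number of events {len(events)}")
        post = fit_observation(list(events)[:k], spec)
        out[int(k)] = post.variance
    return out
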