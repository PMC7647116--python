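"""End-to-end synthetic-replication pipeline.

Orchestrates the full analysis in the order the study design dictates:
generate a cohort and its four phases of trials, fit the interaction model
to the feedback phase for both model classes and the configured cost
functions, fix the nuisance variabilities from the winning fit, fit the
remaining phases with them held fixed, compute product-space Bayes factors
per phase subset, and run the collision observation model seeded with the
feedback-phase mass posteriors.  All randomness flows from the single
top-level seed via named substreams; the manifest records every output for
exact replay.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .physics import EnvironmentParams
from .synthetic import (
    FEEDBACK_PUCK_ORDER,
    ProfileDistributions,
    make_cohort,
    simulate_cohort,
)
from .interaction import (
    InteractionModelSpec,
    MCMCSettings,
    fit,
    fix_nuisance,
    residual_analysis,
)
from .observation import MassPrior, ObservationModelSpec, fit_observation
from .comparison import ProductSpaceSpec, product_space_bayes_factor
from .io import dump_json, dump_yaml, write_collisions, write_latents, write_trial_table

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

PHASE_SUBSETS = {
    "prior": ["prior"],
    "feedback": ["feedback"],
    "all_but_prior": ["feedback", "no_feedback", "collisions_no_feedback"],
    "all": ["prior", "feedback", "no_feedback", "collisions_no_feedback"],
}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; serialisable to YAML."""

    outdir: str = "puckslide_run"
    seed: int = 1
    n_subjects: int = 4
    model_class: str = "newtonian"
    cost_function: str = "quadratic"
    cost_functions: tuple[str, ...] = ("zero_one", "absolute", "quadratic")
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    profile_distributions: ProfileDistributions = field(default_factory=ProfileDistributions)
    mcmc: MCMCSettings = field(default_factory=lambda: MCMCSettings(chains=2, warmup=300, draws=300))
    bayes_factors: bool = True
    verbosity: int = 1

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir,
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "model_class": self.model_class,
            "cost_function": self.cost_function,
            "cost_functions": list(self.cost_functions),
            "env": self.env.to_dict(),
            "profile_distributions": {
                "model_class": self.profile_distributions.model_class,
                "cost_function": self.profile_distributions.cost_function,
                "sigma_t_range": list(self.profile_distributions.sigma_t_range),
                "sigma_x": self.profile_distributions.sigma_x,
                "prior_mass_gamma": list(self.profile_distributions.prior_mass_gamma),
                "linear_factor_range": list(self.profile_distributions.linear_factor_range),
            },
            "mcmc": {
                "chains": self.mcmc.chains,
                "warmup": self.mcmc.warmup,
                "draws": self.mcmc.draws,
                "seed": self.mcmc.seed,
            },
            "bayes_factors": self.bayes_factors,
            "verbosity": self.verbosity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "env" in d:
            d["env"] = EnvironmentParams.from_dict(d["env"])
        if "profile_distributions" in d:
            pd_ = dict(d["profile_distributions"])
            for key in ("sigma_t_range", "prior_mass_gamma", "linear_factor_range"):
                if key in pd_:
                    pd_[key] = tuple(pd_[key])
            d["profile_distributions"] = ProfileDistributions(**pd_)
        if "mcmc" in d:
            d["mcmc"] = MCMCSettings(**d["mcmc"])
        if "cost_functions" in d:
            d["cost_functions"] = tuple(d["cost_functions"])
        return cls(**d)


@dataclass
class RunManifest:
    config_hash: str
    package_version: str
    stages: dict[str, dict]
    started: float
    finished: float | None = None

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "package_version": self.package_version,
            "stages": self.stages,
            "started": self.started,
            "finished": self.finished,
        }


def _log(cfg: PipelineConfig, msg: str):
    if cfg.verbosity:
        import sys

        print(f"[puckslide] {msg}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run all stages; returns the manifest (also written to the outdir).

    Output summary tables contain no timestamps, so a rerun with the same
    config is byte-identical; wall-clock stamps live only in the manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        package_version=__version__,
        stages={},
        started=time.time(),
    )
    dump_yaml(config.to_dict(), out / "config.yaml")

    def record(stage, **files):
        manifest.stages[stage] = {k: str(v) for k, v in files.items()}
        dump_json(manifest.to_dict(), out / "manifest.json")

    try:
        # 1. cohort + data
        _log(config, "simulating cohort")
        profiles = make_cohort(
            config.n_subjects,
            profile_distributions=config.profile_distributions,
            seed=config.seed,
        )
        trials, collisions = simulate_cohort(profiles, config.env)
        p_trials = write_trial_table(trials, out / "trials.csv")
        p_lat = write_latents(trials, out / "latents.csv")
        p_coll = write_collisions(collisions, out / "collisions.csv")
        record("simulate", trials=p_trials, latents=p_lat, collisions=p_coll)

        # 2. feedback-phase fits for both classes and each cost function
        feedback = trials[trials["phase"] == "feedback"]
        fits = {}
        fit_summary_rows = []
        for model_class in ("newtonian", "linear"):
            for cost in config.cost_functions:
                _log(config, f"fitting feedback phase: {model_class}/{cost}")
                spec = InteractionModelSpec(
                    model_class=model_class,
                    cost_function=cost,
                    env=config.env,
                    mcmc=replace(config.mcmc, seed=config.seed * 1000 + 1),
                )
                post = fit(feedback, spec)
                fits[(model_class, cost)] = (spec, post)
                rep = residual_analysis(post, feedback, spec)
                fit_summary_rows.append(
                    {
                        "model_class": model_class,
                        "cost_function": cost,
                        "residual_rho": rep.rho,
                        "residual_p": rep.pvalue,
                    }
                )
        fit_summary = pd.DataFrame(fit_summary_rows)
        p_fit = out / "feedback_fit_summary.csv"
        fit_summary.to_csv(p_fit, index=False)
        key = (config.model_class, config.cost_function)
        spec_sel, post_sel = fits[key]
        p_post = out / "feedback_posterior.csv"
        post_sel.to_frame().to_csv(p_post, index=False)
        record("fit_feedback", summary=p_fit, posterior=p_post)

        # 3. nuisance fixes from the selected fit
        fixes = fix_nuisance(post_sel)
        p_nui = dump_json(
            {"sigma_x": fixes.sigma_x, "sigma_t": fixes.sigma_t}, out / "nuisance.json"
        )
        record("fix_nuisance", nuisance=p_nui)

        # 4. remaining phases with nuisance fixed
        phase_posts = {}
        for phase in ("prior", "no_feedback", "collisions_no_feedback"):
            _log(config, f"fitting phase: {phase}")
            spec_p = InteractionModelSpec(
                model_class=config.model_class,
                cost_function=config.cost_function,
                env=config.env,
                sigma_x_fixed=fixes.sigma_x,
                sigma_t_fixed=fixes.sigma_t,
                mcmc=replace(config.mcmc, seed=config.seed * 1000 + 2),
            )
            phase_posts[phase] = fit(trials[trials["phase"] == phase], spec_p)
        mass_rows = []
        for phase, post in list(phase_posts.items()) + [("feedback", post_sel)]:
            for sid, sp in post.subjects.items():
                mp = sp.map_params()
                for name, val in mp.items():
                    if name.startswith(("m[", "c[")):
                        mass_rows.append(
                            {"phase": phase, "subject_id": sid, "parameter": name, "map": val}
                        )
        p_mass = out / "map_parameters.csv"
        pd.DataFrame(mass_rows).sort_values(["phase", "subject_id", "parameter"]).to_csv(
            p_mass, index=False
        )
        record("fit_phases", map_parameters=p_mass)

        # 5. Bayes factors per phase subset
        if config.bayes_factors:
            bf = {}
            for label, phases in PHASE_SUBSETS.items():
                _log(config, f"product-space Bayes factor: {label}")
                sub = trials[trials["phase"].isin(phases)]
                spec_lin = InteractionModelSpec(
                    model_class="linear",
                    cost_function=config.cost_function,
                    env=config.env,
                    sigma_x_fixed=fixes.sigma_x,
                    mcmc=replace(config.mcmc, seed=config.seed * 1000 + 3),
                )
                spec_new = replace(spec_lin, model_class="newtonian")
                ps = ProductSpaceSpec(
                    mcmc=replace(config.mcmc, seed=config.seed * 1000 + 4, warmup=200, draws=400)
                )
                rep = product_space_bayes_factor(sub, spec_lin, spec_new, ps, phase_subset=label)
                bf[label] = {
                    "K": rep.K,
                    "interpretation": rep.interpretation,
                    "bounded": rep.bounded,
                }
            p_bf = dump_json(bf, out / "bayes_factors.json")
            record("bayes_factors", report=p_bf)

        # 6. observation model per subject, priors from the feedback fit
        obs_summary = {}
        for sid, events in collisions.items():
            sp = post_sel.subjects[sid]
            prior_F = {
                p: (
                    MassPrior(sp.params[f"m[{p}]"].ravel())
                    if f"m[{p}]" in sp.params
                    else MassPrior(spec_sel.mass_prior)  # linear fits carry no masses
                )
                for p in FEEDBACK_PUCK_ORDER
            }
            spec_obs = ObservationModelSpec(
                prior_mass_NF=MassPrior(spec_sel.mass_prior),
                prior_mass_F=prior_F,
                mcmc=replace(config.mcmc, seed=config.seed * 1000 + 5),
            )
            post_obs = fit_observation(events, spec_obs)
            obs_summary[sid] = post_obs.summary()
        p_obs = dump_json(obs_summary, out / "observation_posteriors.json")
        record("observation", report=p_obs)
    except Exception:
        manifest.finished = time.time()
        dump_json(manifest.to_dict(), out / "manifest.json")
        raise

    manifest.finished = time.time()
    dump_json(manifest.to_dict(), out / "manifest.json")
    _log(config, "pipeline complete")
    return manifest
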