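"""Reading, writing and validating the package's table formats.

Trial tables are plain CSV with the observable columns

    subject_id, condition, phase, trial_index, puck_id, x, t_pre, error,
    feedback_shown

(distances in metres, press-times in seconds, signed final-position error in
metres).  Generator ground-truth latents (percept, intention, belief) travel
in a parallel sidecar CSV so that analyses can never silently condition on
them.  Collision movies are CSV with one elastic collision per row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import CollisionEvent, PHASES

__all__ = [
    "TRIAL_COLUMNS",
    "LATENT_COLUMNS",
    "COLLISION_COLUMNS",
    "write_trial_table",
    "read_trial_table",
    "write_latents",
    "read_latents",
    "write_collisions",
    "read_collisions",
    "validate_trial_table",
    "ValidationReport",
    "load_yaml",
    "dump_yaml",
    "dump_json",
]

TRIAL_COLUMNS = [
    "subject_id",
    "condition",
    "phase",
    "trial_index",
    "puck_id",
    "x",
    "t_pre",
    "error",
    "feedback_shown",
]
LATENT_COLUMNS = ["subject_id", "phase", "trial_index", "x_per", "t_int", "mass_belief"]
COLLISION_COLUMNS = ["subject_id", "event_index", "known_puck_id", "vF", "vNF", "uF", "uNF", "mF"]


def write_trial_table(trials: pd.DataFrame, path) -> Path:
    """Write the observable columns of a (generated or measured) trial table."""
    df = trials.rename(columns={"final_position_error": "error"})
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table missing columns {missing}")
    path = Path(path)
    df[TRIAL_COLUMNS].to_csv(path, index=False)
    return path


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial table at {path} missing columns {missing}")
    return df


def write_latents(trials: pd.DataFrame, path) -> Path:
    path = Path(path)
    trials[LATENT_COLUMNS].to_csv(path, index=False)
    return path


def read_latents(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_collisions(collisions: dict[str, list[CollisionEvent]], path) -> Path:
    rows = []
    for sid, events in collisions.items():
        for e in events:
            rows.append({"subject_id": sid, **e.__dict__})
    path = Path(path)
    pd.DataFrame(rows, columns=COLLISION_COLUMNS).to_csv(path, index=False)
    return path


def read_collisions(path) -> dict[str, list[CollisionEvent]]:
    df = pd.read_csv(path)
    missing = [c for c in COLLISION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"collision table at {path} missing columns {missing}")
    out: dict[str, list[CollisionEvent]] = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        out[sid] = [
            CollisionEvent(
                event_index=int(r.event_index),
                known_puck_id=str(r.known_puck_id),
                vF=float(r.vF),
                vNF=float(r.vNF),
                uF=float(r.uF),
                uNF=float(r.uNF),
                mF=float(r.mF),
            )
            for r in grp.itertuples()
        ]
    return out


@dataclass
class ValidationReport:
    ok: bool
    violations: list[dict]

    def to_json(self) -> str:
        return json.dumps({"ok": self.ok, "violations": self.violations}, indent=2)


def validate_trial_table(path, distance_range=(1.0, 5.0)) -> ValidationReport:
    """Schema, range and invariant checks on a trial-table CSV.

    Checks the header, ``x`` within the arena range, ``t_pre > 0``, valid
    phase labels, and that feedback is only flagged in the feedback phase.
    Returns a machine-readable violation list rather than raising, except
    for unreadable files / wrong schema.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schema error: missing columns {missing}")
    lo, hi = distance_range
    violations = []

    def flag(mask, rule):
        for idx in df.index[mask]:
            violations.append({"row": int(idx), "rule": rule})

    flag(~df["phase"].isin(PHASES), "invalid phase label")
    flag(~(df["x"].between(lo, hi)), f"x outside [{lo}, {hi}]")
    flag(~(df["t_pre"] > 0), "t_pre not positive")
    fb = df["feedback_shown"].astype(bool)
    flag(fb & (df["phase"] != "feedback"), "feedback shown outside feedback phase")
    flag(~fb & (df["phase"] == "feedback"), "feedback missing in feedback phase")
    return ValidationReport(ok=not violations, violations=violations)


def load_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
    return path


def dump_json(obj, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
    return path
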