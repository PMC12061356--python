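"""Trial-table readers/writers and the end-to-end pipeline.

The standard dialect is a plain CSV with one row per choice: mouse_id,
sex, session, trial, side, x, y (screen-global pixels), reward, rt and —
once labelled — state, state_side, p_explore. An ``abet-export`` dialect
accepts aperture-local coordinates (each 240 x 240 aperture generates its
own x/y) and converts them to screen-global using the documented aperture
offsets.

``run_pipeline`` chains the stages — simulate/ingest, explore/exploit
labelling, trial metrics, bout geometry, mixed-model report — and writes
a manifest (seed, config hash, package version) so a run can be
reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bouts import bout_table, centroid_shift_distances, episode_counts, \
    segment_state_episodes, spatial_bouts
from .cohort import CohortConfig, generate_cohort
from .glmm import run_standard_models
from .hmm import ExploreExploitHMM
from .metrics import reward_metric_table, state_metric_table
from .rlck import RLCKModel
from .screen import APERTURE_ORIGIN, APERTURE_SIZE_PX, SCREEN_H_PX, SCREEN_W_PX

__all__ = [
    "TrialTableError",
    "read_trials",
    "write_trials",
    "label_trials",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)

REQUIRED = ["mouse_id", "sex", "session", "trial", "side", "x", "y", "reward", "rt"]

ABET_COLUMNS = {
    "Animal ID": "mouse_id",
    "Sex": "sex",
    "Session": "session",
    "Trial": "trial",
    "Side": "side",
    "Touch X": "x",
    "Touch Y": "y",
    "Reward": "reward",
    "Response Time": "rt",
}


class TrialTableError(ValueError):
    """Schema violation in a trial table, listing offending rows/columns."""


def _validate(df: pd.DataFrame, path: str = "<memory>") -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    problems = []
    bad = ~df["side"].isin(["left", "right"])
    if bad.any():
        problems.append(f"side not left/right at rows {list(df.index[bad][:5])}")
    bad = (df["x"] < 0) | (df["x"] >= SCREEN_W_PX)
    if bad.any():
        problems.append(
            f"x outside [0, {SCREEN_W_PX}) at rows {list(df.index[bad][:5])}"
        )
    bad = (df["y"] < 0) | (df["y"] >= SCREEN_H_PX)
    if bad.any():
        problems.append(
            f"y outside [0, {SCREEN_H_PX}) at rows {list(df.index[bad][:5])}"
        )
    bad = df["rt"] < 0
    if bad.any():
        problems.append(f"negative rt at rows {list(df.index[bad][:5])}")
    if not df["reward"].isin([0, 1]).all():
        problems.append("reward must be 0/1")
    mono = df.groupby(["mouse_id", "session"])["trial"].apply(
        lambda s: bool(np.all(np.diff(s.to_numpy()) > 0))
    )
    if not mono.all():
        problems.append(
            f"non-increasing trial indices in sessions {list(mono.index[~mono][:5])}"
        )
    if problems:
        raise TrialTableError(f"{path}: " + "; ".join(problems))
    return df


def aperture_local_to_global(x_local, y_local, side):
    """Map aperture-local (0..239) coordinates onto the 800 x 600 screen."""
    x_local = np.asarray(x_local, dtype=float)
    y_local = np.asarray(y_local, dtype=float)
    if np.any((x_local < 0) | (x_local >= APERTURE_SIZE_PX)):
        raise TrialTableError("aperture-local x outside [0, 240)")
    if np.any((y_local < 0) | (y_local >= APERTURE_SIZE_PX)):
        raise TrialTableError("aperture-local y outside [0, 240)")
    x0 = np.array([APERTURE_ORIGIN[s][0] for s in np.atleast_1d(side)])
    y0 = np.array([APERTURE_ORIGIN[s][1] for s in np.atleast_1d(side)])
    return x_local + x0, y_local + y0


def global_to_aperture_local(x, y, side):
    """Inverse of :func:`aperture_local_to_global`."""
    x0 = np.array([APERTURE_ORIGIN[s][0] for s in np.atleast_1d(side)])
    y0 = np.array([APERTURE_ORIGIN[s][1] for s in np.atleast_1d(side)])
    return np.asarray(x, dtype=float) - x0, np.asarray(y, dtype=float) - y0


def read_trials(path, dialect: str = "standard") -> pd.DataFrame:
    """Read and validate a trial table CSV."""
    if dialect not in ("standard", "abet-export"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, comment="#")
    if dialect == "abet-export":
        df = df.rename(columns=ABET_COLUMNS)
        df["side"] = df["side"].str.lower()
        df["x"], df["y"] = aperture_local_to_global(df["x"], df["y"], df["side"])
    return _validate(df, str(path))


def write_trials(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a trial table with a versioned schema header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# touchbandit trial-table v1 (touchbandit {__version__}")
        fh.write(f", seed={seed})\n" if seed is not None else ")\n")
        df.to_csv(fh, index=False)


def label_trials(
    trials: pd.DataFrame, per: str = "mouse", seed: int = 0, **fit_kwargs
) -> tuple[pd.DataFrame, dict]:
    """Fit the constrained HMM and decode explore/exploit labels.

    ``per='mouse'`` fits one HMM per animal across its sessions (the
    default); ``per='pooled'`` fits a single cohort-level model. Adds
    ``state`` (explore/exploit), ``state_side`` and ``p_explore``.
    """
    if per not in ("mouse", "pooled"):
        raise ValueError("per must be 'mouse' or 'pooled'")
    out = trials.copy().sort_values(["mouse_id", "session", "trial"])
    out["state"] = ""
    out["state_side"] = ""
    out["p_explore"] = np.nan
    fits = {}
    if per == "pooled":
        model = ExploreExploitHMM.from_dataframe(out)
        pooled = model.fit(seed=seed, **fit_kwargs)
    for mouse, g in out.groupby("mouse_id", sort=False):
        if per == "mouse":
            model = ExploreExploitHMM.from_dataframe(g)
            res = model.fit(seed=seed, **fit_kwargs)
        else:
            res = pooled
        fits[mouse] = res
        for (_, session), sess in g.groupby(["mouse_id", "session"], sort=False):
            seq = res.decode(sess["side"].to_numpy())
            out.loc[sess.index, "state"] = np.where(
                seq.explore_mask, "explore", "exploit"
            )
            out.loc[sess.index, "state_side"] = seq.labels
            out.loc[sess.index, "p_explore"] = seq.p_explore
    return out.reset_index(drop=True), fits


def fit_agents(trials: pd.DataFrame, seed: int = 0, n_restarts: int = 10):
    """Per-mouse RLCK maximum-likelihood fits as a tidy table."""
    rows = []
    for mouse, g in trials.groupby("mouse_id", sort=False):
        res = RLCKModel.from_dataframe(g).fit(n_restarts=n_restarts, seed=seed)
        rows.append(
            {
                "mouse_id": mouse,
                "alpha": res.params.alpha,
                "beta": res.params.beta,
                "bias": res.params.bias,
                "kappa": res.params.kappa,
                "nll": res.nll,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """End-to-end run configuration."""

    out_dir: str = "touchbandit_run"
    seed: int = 0
    trials_path: str | None = None  # ingest instead of simulating
    dialect: str = "standard"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    label_per: str = "mouse"
    use_existing_labels: bool = False
    fit_rlck: bool = True
    hmm_restarts: int = 3

    def config_hash(self) -> str:
        def enc(o):
            if hasattr(o, "__dataclass_fields__"):
                return {k: enc(v) for k, v in asdict(o).items()}
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o

        blob = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate/ingest -> label -> metrics -> bouts -> models.

    Writes five output tables plus a manifest into ``config.out_dir`` and
    returns them in memory. Any stage failure aborts with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "ingest"
    try:
        if config.trials_path is not None:
            trials = read_trials(config.trials_path, config.dialect)
        else:
            trials = generate_cohort(config.cohort, seed=config.seed).trials

        stage = "label"
        if config.use_existing_labels:
            if "state" not in trials.columns:
                raise TrialTableError(
                    "labelling disabled but trial table has no state column"
                )
            labeled = trials
        else:
            labeled, _ = label_trials(
                trials,
                per=config.label_per,
                seed=config.seed,
                n_restarts=config.hmm_restarts,
            )

        stage = "metrics"
        state_tbl = state_metric_table(labeled)
        reward_tbl = reward_metric_table(labeled)

        stage = "bouts"
        episodes = segment_state_episodes(labeled)
        counts = episode_counts(episodes)
        counts["sex"] = counts["mouse_id"].map(
            labeled.groupby("mouse_id")["sex"].first()
        )
        bouts = bout_table(labeled)
        bouts["sex"] = bouts["mouse_id"].map(
            labeled.groupby("mouse_id")["sex"].first()
        )
        shifts = centroid_shift_distances(spatial_bouts(labeled))
        shifts["sex"] = shifts["mouse_id"].map(
            labeled.groupby("mouse_id")["sex"].first()
        )

        stage = "stats"
        tables = {
            "state": state_tbl,
            "reward": reward_tbl,
            "bouts": bouts,
            "shifts": shifts,
            "counts": counts,
        }
        if config.fit_rlck:
            agents = fit_agents(labeled, seed=config.seed)
            tables["alpha"] = state_tbl.merge(
                agents[["mouse_id", "alpha"]], on="mouse_id"
            )
        report = run_standard_models(tables, skip_missing=not config.fit_rlck)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    outputs = {
        "trials_labeled": labeled,
        "state_metrics": state_tbl,
        "reward_metrics": reward_tbl,
        "bouts": bouts,
        "model_report": report,
    }
    manifest = {
        "touchbandit_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stage_rows": {k: len(v) for k, v in outputs.items()},
    }
    write_trials(labeled, out_dir / "trials_labeled.csv", seed=config.seed)
    for name in ("state_metrics", "reward_metrics", "bouts", "model_report"):
        outputs[name].to_csv(out_dir / f"{name}.csv", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = manifest
    return outputs
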