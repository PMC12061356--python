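"""Trial-level spatial and temporal precision metrics.

Works on tidy trial tables (one row per touch) with screen-global pixel
coordinates. All reported distances are in millimetres (1 px = 0.29 mm);
column names carry the unit (``*_px``, ``*_mm``) and the converters below
are the only place the units meet, so pipelines cannot silently mix them.

Metrics:

* distance from the screen centre, |400 - x| on the x-coordinate alone
  (the vertical coordinate does not separate the two apertures);
* successive-touch Euclidean distance, restricted to consecutive trials on
  the same aperture side and in the same explore/exploit state — pairs
  spanning a side and/or state transition are excluded and accounted for;
* Mahalanobis distance of each touch from its group centroid under the
  group's sample covariance, computed per aperture and optionally per
  state population so no touches are discarded;
* previous-reward conditioning and per-mouse response-latency summaries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .screen import CENTER_X_PX, MM_PER_PX, SCREEN_H_PX, SCREEN_W_PX, px_to_mm

__all__ = [
    "px_to_mm",
    "distance_from_center_px",
    "center_distance_mm",
    "successive_euclidean",
    "exclusion_summary",
    "mahalanobis_distances",
    "mahalanobis_table",
    "add_prev_reward",
    "condition_on_prev_reward",
    "latency_summary",
    "state_metric_table",
    "reward_metric_table",
]

log = logging.getLogger(__name__)


def distance_from_center_px(x):
    """|400 - x| in pixels; always nonnegative."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x >= SCREEN_W_PX)):
        raise ValueError(f"x must lie in [0, {SCREEN_W_PX})")
    d = np.abs(CENTER_X_PX - x)
    return float(d) if d.ndim == 0 else d


def center_distance_mm(x):
    """Distance from the screen midline in millimetres."""
    return px_to_mm(distance_from_center_px(x))


def _validate_trials(df: pd.DataFrame, need_state: bool = False) -> None:
    required = {"mouse_id", "session", "trial", "side", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    if need_state:
        if "state" not in df.columns or df["state"].isna().any():
            raise ValueError("state labels are required and must be complete")
    if np.any((df["x"] < 0) | (df["x"] >= SCREEN_W_PX)):
        raise ValueError("x out of screen range")
    if np.any((df["y"] < 0) | (df["y"] >= SCREEN_H_PX)):
        raise ValueError("y out of screen range")


def successive_euclidean(trials: pd.DataFrame) -> pd.DataFrame:
    """Pairwise successive-touch distances with transition exclusions.

    Returns one row per consecutive trial pair within a mouse x session
    (never spanning session boundaries): distance in mm, the state/side
    of the pair, ``prev_reward`` (the outcome of the pair's first trial),
    an ``included`` flag and the ``exclusion_reason`` in
    {none, side_transition, state_transition, both}.
    """
    _validate_trials(trials, need_state=True)
    out = []
    for (mouse, session), g in trials.groupby(["mouse_id", "session"], sort=False):
        g = g.sort_values("trial")
        if len(g) < 2:
            continue
        dx = np.diff(g["x"].to_numpy(dtype=float))
        dy = np.diff(g["y"].to_numpy(dtype=float))
        dist_mm = np.hypot(dx, dy) * MM_PER_PX
        side = g["side"].to_numpy()
        state = g["state"].to_numpy()
        side_tr = side[1:] != side[:-1]
        state_tr = state[1:] != state[:-1]
        reason = np.where(
            side_tr & state_tr,
            "both",
            np.where(side_tr, "side_transition", np.where(state_tr, "state_transition", "none")),
        )
        pairs = pd.DataFrame(
            {
                "mouse_id": mouse,
                "session": session,
                "trial": g["trial"].to_numpy()[1:],
                "dist_mm": dist_mm,
                "side": side[1:],
                "state": state[1:],
                "included": reason == "none",
                "exclusion_reason": reason,
            }
        )
        if "sex" in g.columns:
            pairs["sex"] = g["sex"].to_numpy()[1:]
        if "reward" in g.columns:
            pairs["prev_reward"] = g["reward"].to_numpy()[:-1]
        out.append(pairs)
    if not out:
        raise ValueError("no session contained two or more trials")
    return pd.concat(out, ignore_index=True)


def exclusion_summary(pairs: pd.DataFrame) -> dict:
    """Exclusion accounting: overall percent omitted and its breakdown."""
    n = len(pairs)
    reasons = pairs["exclusion_reason"].value_counts()
    n_side = int(reasons.get("side_transition", 0))
    n_state = int(reasons.get("state_transition", 0))
    n_both = int(reasons.get("both", 0))
    n_excl = n_side + n_state + n_both
    assert n_excl == int((~pairs["included"]).sum())
    return {
        "n_pairs": n,
        "n_excluded": n_excl,
        "pct_excluded": 100.0 * n_excl / n,
        "pct_side_transition": 100.0 * n_side / n,
        "pct_state_transition": 100.0 * n_state / n,
        "pct_both": 100.0 * n_both / n,
    }


def mahalanobis_distances(points: np.ndarray) -> np.ndarray:
    """Distance of each (x, y) point from the group centroid under the
    group's sample covariance: sqrt((p - c)^T C^-1 (p - c))."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if len(pts) < 3:
        raise ValueError("need >= 3 points for an invertible covariance")
    centroid = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    if np.linalg.matrix_rank(cov) < 2:
        raise np.linalg.LinAlgError("singular covariance (collinear points)")
    inv = np.linalg.inv(cov)
    d = pts - centroid
    return np.sqrt(np.einsum("ni,ij,nj->n", d, inv, d))


def mahalanobis_table(
    trials: pd.DataFrame, split_by_state: bool = True
) -> pd.DataFrame:
    """Per-touch Mahalanobis distances, grouped per aperture side and
    (optionally) per explore/exploit touch population.

    Degenerate groups (under three points or singular covariance) are
    skipped with a log entry; their rows get NaN distances.
    """
    need_state = split_by_state
    _validate_trials(trials, need_state=need_state)
    keys = ["side", "state"] if split_by_state else ["side"]
    out = trials.copy()
    out["mahal"] = np.nan
    for key, g in trials.groupby(keys, sort=False):
        try:
            d = mahalanobis_distances(g[["x", "y"]].to_numpy())
        except (ValueError, np.linalg.LinAlgError) as err:
            log.warning("degenerate Mahalanobis group %s skipped: %s", key, err)
            continue
        out.loc[g.index, "mahal"] = d
    return out


def add_prev_reward(trials: pd.DataFrame) -> pd.DataFrame:
    """Previous-trial outcome within each session; NaN at trial 1."""
    out = trials.copy()
    out["prev_reward"] = (
        out.sort_values("trial")
        .groupby(["mouse_id", "session"])["reward"]
        .shift(1)
    )
    return out


def condition_on_prev_reward(
    table: pd.DataFrame, value: str, extra_keys: tuple = ()
) -> pd.DataFrame:
    """Mean of a metric split by previous-trial outcome (first trials,
    where prev_reward is undefined, are dropped). Flags empty cells."""
    if "prev_reward" not in table.columns:
        raise ValueError("table must carry a prev_reward column")
    t = table.dropna(subset=["prev_reward", value])
    keys = ["mouse_id", *extra_keys, "prev_reward"]
    res = t.groupby(keys, sort=False)[value].mean().reset_index()
    for lev in (0, 1):
        if not (res["prev_reward"] == lev).any():
            log.warning("prev_reward level %d has no observations", lev)
    return res


def latency_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per mouse x state mean and median response time (seconds)."""
    if "rt" not in trials.columns:
        raise ValueError("trial table has no rt column")
    if np.any(trials["rt"] < 0):
        raise ValueError("negative response times")
    return (
        trials.groupby(["mouse_id", "state"], sort=False)["rt"]
        .agg(["mean", "median", "count"])
        .reset_index()
    )


def _mouse_sex(trials: pd.DataFrame) -> pd.Series:
    return trials.groupby("mouse_id", sort=False)["sex"].first()


def state_metric_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Tidy per mouse x session x state response table for model fitting.

    Columns: dist_mm (mean included successive Euclidean), mahal,
    center_dist_mm, rt, with sex carried along. Averaging to the
    mouse x session x state level before group statistics keeps one row
    per condition per session, mirroring session-averaged analyses.
    """
    pairs = successive_euclidean(trials)
    eu = (
        pairs[pairs["included"]]
        .groupby(["mouse_id", "session", "state"], sort=False)["dist_mm"]
        .mean()
        .reset_index()
    )
    mah = mahalanobis_table(trials, split_by_state=True)
    mah_g = (
        mah.groupby(["mouse_id", "session", "state"], sort=False)["mahal"]
        .mean()
        .reset_index()
    )
    t = trials.copy()
    t["center_dist_mm"] = center_distance_mm(t["x"])
    agg = (
        t.groupby(["mouse_id", "session", "state"], sort=False)
        .agg(center_dist_mm=("center_dist_mm", "mean"), rt=("rt", "mean"))
        .reset_index()
    )
    out = eu.merge(mah_g, on=["mouse_id", "session", "state"], how="outer").merge(
        agg, on=["mouse_id", "session", "state"], how="outer"
    )
    out["sex"] = out["mouse_id"].map(_mouse_sex(trials))
    return out


def reward_metric_table(trials: pd.DataFrame) -> pd.DataFrame:
    """Per mouse x session x state x prev_reward means of the distance
    metrics (trial 1 of each session excluded)."""
    pairs = successive_euclidean(trials)
    eu = (
        pairs[pairs["included"]]
        .groupby(["mouse_id", "session", "state", "prev_reward"], sort=False)[
            "dist_mm"
        ]
        .mean()
        .reset_index()
    )
    mah = add_prev_reward(mahalanobis_table(trials, split_by_state=True))
    mah_g = (
        mah.dropna(subset=["prev_reward"])
        .groupby(["mouse_id", "session", "state", "prev_reward"], sort=False)[
            "mahal"
        ]
        .mean()
        .reset_index()
    )
    out = eu.merge(
        mah_g, on=["mouse_id", "session", "state", "prev_reward"], how="outer"
    )
    out["sex"] = out["mouse_id"].map(_mouse_sex(trials))
    out["prev_reward"] = out["prev_reward"].astype(int)
    return out
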