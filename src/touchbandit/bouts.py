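"""Bout segmentation and bout-geometry statistics.

A *state episode* is a maximal run of consecutive trials in one
explore/exploit state; episode boundaries fall exactly at explore<->exploit
transitions, so explore and exploit episodes alternate within a session.
For spatial statistics each episode is further partitioned by aperture
side into *bouts* (an explore episode can contain touches on both sides,
which are analysed separately); each bout carries the centroid of its
member touches.

Geometry per bout:

* centroid-shift distances — Euclidean distance (mm) between centroids of
  successive bouts of the same state (and side);
* density boundary — the touches are binned on a 2D histogram whose
  automatic bin edges are coarsened by a factor of two, counts are
  normalised to [0, 1], and the outer boundary of the region whose
  density reaches the outermost iso-level is traced along bin edges
  (marching squares on the indicator grid). Area is the shoelace sum over
  the top-level boundary polygons (containment hierarchy), perimeter the
  summed edge lengths, both in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from shapely.geometry import Polygon as _ShapelyPolygon

from .screen import MM_PER_PX

__all__ = [
    "segment_state_episodes",
    "episode_counts",
    "spatial_bouts",
    "centroid_shift_distances",
    "polygon_area_perimeter",
    "bout_density_boundary",
    "bout_table",
    "ContourResult",
]


def _episode_ids(states: np.ndarray) -> np.ndarray:
    """0-based episode index per trial; increments at each state change."""
    change = np.concatenate([[0], (states[1:] != states[:-1]).astype(int)])
    return np.cumsum(change)


def segment_state_episodes(trials: pd.DataFrame) -> pd.DataFrame:
    """One row per state episode per mouse x session, spans contiguous."""
    if "state" not in trials.columns or trials["state"].isna().any():
        raise ValueError("state labels are required and must be complete")
    rows = []
    for (mouse, session), g in trials.groupby(["mouse_id", "session"], sort=False):
        g = g.sort_values("trial")
        states = g["state"].to_numpy()
        eid = _episode_ids(states)
        for e in np.unique(eid):
            sub = g.iloc[eid == e]
            rows.append(
                {
                    "mouse_id": mouse,
                    "session": session,
                    "episode": int(e),
                    "state": sub["state"].iloc[0],
                    "trial_start": int(sub["trial"].iloc[0]),
                    "trial_end": int(sub["trial"].iloc[-1]),
                    "n_trials": len(sub),
                }
            )
    return pd.DataFrame(rows)


def episode_counts(episodes: pd.DataFrame) -> pd.DataFrame:
    """Per-session explore/exploit episode counts (n_explore, n_exploit)."""
    counts = (
        episodes.groupby(["mouse_id", "session", "state"], sort=False)
        .size()
        .unstack("state", fill_value=0)
        .reset_index()
    )
    for col in ("explore", "exploit"):
        if col not in counts.columns:
            counts[col] = 0
    return counts.rename(columns={"explore": "n_explore", "exploit": "n_exploit"})


def spatial_bouts(trials: pd.DataFrame) -> pd.DataFrame:
    """Side-partitioned bouts with centroids; bout order follows time.

    Within an episode, touches on each aperture form one bout (sides are
    analysed separately). Returns mouse_id, session, episode, state, side,
    n_trials, centroid_x_px, centroid_y_px, member trial indices.
    """
    if "state" not in trials.columns or trials["state"].isna().any():
        raise ValueError("state labels are required and must be complete")
    rows = []
    for (mouse, session), g in trials.groupby(["mouse_id", "session"], sort=False):
        g = g.sort_values("trial")
        eid = _episode_ids(g["state"].to_numpy())
        g = g.assign(_episode=eid)
        for (e, side), sub in g.groupby(["_episode", "side"], sort=False):
            rows.append(
                {
                    "mouse_id": mouse,
                    "session": session,
                    "episode": int(e),
                    "state": sub["state"].iloc[0],
                    "side": side,
                    "n_trials": len(sub),
                    "centroid_x_px": float(sub["x"].mean()),
                    "centroid_y_px": float(sub["y"].mean()),
                    "trials": sub["trial"].to_numpy(),
                }
            )
    bouts = pd.DataFrame(rows)
    return bouts.sort_values(["mouse_id", "session", "episode", "side"]).reset_index(
        drop=True
    )


def centroid_shift_distances(bouts: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance (mm) between successive same-state, same-side
    bout centroids within a session; empty when fewer than two bouts."""
    rows = []
    for (mouse, session, state, side), g in bouts.groupby(
        ["mouse_id", "session", "state", "side"], sort=False
    ):
        g = g.sort_values("episode")
        if len(g) < 2:
            continue
        dx = np.diff(g["centroid_x_px"].to_numpy())
        dy = np.diff(g["centroid_y_px"].to_numpy())
        for i, d in enumerate(np.hypot(dx, dy) * MM_PER_PX):
            rows.append(
                {
                    "mouse_id": mouse,
                    "session": session,
                    "state": state,
                    "side": side,
                    "shift_index": i,
                    "shift_mm": float(d),
                }
            )
    return pd.DataFrame(
        rows, columns=["mouse_id", "session", "state", "side", "shift_index", "shift_mm"]
    )


def polygon_area_perimeter(vertices) -> tuple[float, float]:
    """Shoelace area (absolute) and perimeter of a simple polygon."""
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs >= 3 (x, y) vertices")
    if np.allclose(v[0], v[-1]):
        v = v[:-1]
        if len(v) < 3:
            raise ValueError("polygon needs >= 3 distinct vertices")
    x, y = v[:, 0], v[:, 1]
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    closed = np.vstack([v, v[0]])
    perim = float(np.sum(np.hypot(np.diff(closed[:, 0]), np.diff(closed[:, 1]))))
    return float(area), perim


@dataclass
class ContourResult:
    """Outer density boundary of one bout's touches (mm units)."""

    polygons: list = field(default_factory=list)  # outer boundaries, (k, 2) mm
    area_mm2: float = np.nan
    perimeter_mm: float = np.nan
    n_points: int = 0
    n_components: int = 0
    degenerate: bool = False


def _coarsen_edges(edges: np.ndarray) -> np.ndarray:
    """Merge adjacent bin pairs ("every other bin"), keeping the last edge."""
    out = edges[::2]
    if out[-1] != edges[-1]:
        out = np.append(out, edges[-1])
    return out


def bout_density_boundary(
    points_mm,
    min_points: int = 5,
    outer_level: float = 0.1,
    bins: str | int = "auto",
) -> ContourResult:
    """Trace the outer boundary of a bout's touch-density footprint.

    ``outer_level`` is the outermost of ten equal iso-levels on the
    normalised density scale [0, 1]; bins come from automatic edge
    selection coarsened by a factor of two.
    """
    pts = np.asarray(points_mm, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n < min_points or np.allclose(pts, pts[0], atol=1e-12):
        return ContourResult(n_points=n, degenerate=True)
    ex = _coarsen_edges(np.histogram_bin_edges(pts[:, 0], bins=bins))
    ey = _coarsen_edges(np.histogram_bin_edges(pts[:, 1], bins=bins))
    if len(ex) < 2 or len(ey) < 2:
        return ContourResult(n_points=n, degenerate=True)
    counts, ex, ey = np.histogram2d(pts[:, 0], pts[:, 1], bins=[ex, ey])
    density = counts / counts.max()
    occupied = (density >= outer_level).astype(float)
    # pad with an empty ring so every boundary closes, then march at 0.5:
    # contour vertices then sit midway between cell centres, i.e. on bin edges
    padded = np.pad(occupied, 1)
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    # cell-centre coordinates for padded indices (ring cells one width out)
    gx = np.concatenate([[cx[0] - (cx[1] - cx[0]) if len(cx) > 1 else cx[0] - 1.0], cx,
                         [cx[-1] + (cx[-1] - cx[-2]) if len(cx) > 1 else cx[-1] + 1.0]])
    gy = np.concatenate([[cy[0] - (cy[1] - cy[0]) if len(cy) > 1 else cy[0] - 1.0], cy,
                         [cy[-1] + (cy[-1] - cy[-2]) if len(cy) > 1 else cy[-1] + 1.0]])
    contours = measure.find_contours(padded, level=0.5)
    polys = []
    for c in contours:
        if len(c) < 4 or not np.allclose(c[0], c[-1]):
            continue
        xs = np.interp(c[:, 0], np.arange(len(gx)), gx)
        ys = np.interp(c[:, 1], np.arange(len(gy)), gy)
        poly = np.column_stack([xs, ys])
        if _ShapelyPolygon(poly).area > 0:
            polys.append(poly)
    if not polys:
        return ContourResult(n_points=n, degenerate=True)
    shapes = [_ShapelyPolygon(p).buffer(0) for p in polys]
    outer_idx = [
        i
        for i, s in enumerate(shapes)
        if not any(j != i and shapes[j].contains(s) for j in range(len(shapes)))
    ]
    area = 0.0
    perim = 0.0
    for i in outer_idx:
        a, p = polygon_area_perimeter(polys[i])
        area += a
        perim += p
    return ContourResult(
        polygons=[polys[i] for i in outer_idx],
        area_mm2=area,
        perimeter_mm=perim,
        n_points=n,
        n_components=len(outer_idx),
        degenerate=False,
    )


def bout_table(
    trials: pd.DataFrame, min_points: int = 5, outer_level: float = 0.1
) -> pd.DataFrame:
    """Per-bout table with centroids and contour area/perimeter (mm).

    Bouts under ``min_points`` touches keep their centroid (they count
    toward segmentation and shifts) but get NaN area/perimeter and a
    degenerate flag.
    """
    bouts = spatial_bouts(trials)
    xy = trials.set_index(["mouse_id", "session", "trial"])[["x", "y"]]
    areas, perims, degen = [], [], []
    for _, b in bouts.iterrows():
        pts_px = xy.loc[
            [(b["mouse_id"], b["session"], t) for t in b["trials"]]
        ].to_numpy(dtype=float)
        res = bout_density_boundary(
            pts_px * MM_PER_PX, min_points=min_points, outer_level=outer_level
        )
        areas.append(res.area_mm2)
        perims.append(res.perimeter_mm)
        degen.append(res.degenerate)
    out = bouts.drop(columns=["trials"]).copy()
    out["area_mm2"] = areas
    out["perimeter_mm"] = perims
    out["degenerate"] = degen
    return out
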