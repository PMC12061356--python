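"""Bout segmentation, centroid shifts and density-contour geometry."""

import numpy as np
import pandas as pd
import pytest

from touchbandit import (
    CohortConfig,
    TouchGenParams,
    bout_density_boundary,
    centroid_shift_distances,
    episode_counts,
    generate_cohort,
    make_fixture,
    polygon_area_perimeter,
    segment_state_episodes,
    spatial_bouts,
)


def _session(states, sides=None, xs=None, ys=None):
    n = len(states)
    return pd.DataFrame(
        {
            "mouse_id": "m",
            "session": 0,
            "trial": range(n),
            "state": states,
            "side": sides if sides is not None else ["left"] * n,
            "x": xs if xs is not None else np.linspace(100, 200, n),
            "y": ys if ys is not None else np.full(n, 300.0),
        }
    )


def test_constant_session_is_one_episode():
    eps = segment_state_episodes(_session(["exploit"] * 8))
    assert len(eps) == 1
    counts = episode_counts(eps)
    assert counts["n_exploit"].iloc[0] == 1 and counts["n_explore"].iloc[0] == 0


def test_toy_label_run_segments_into_three_episodes():
    eps = segment_state_episodes(
        _session(["explore", "explore", "exploit", "exploit", "explore"])
    )
    assert eps["state"].tolist() == ["explore", "exploit", "explore"]
    assert eps["n_trials"].tolist() == [2, 2, 1]


def test_episode_spans_partition_the_session():
    states = ["explore", "exploit", "exploit", "explore", "explore", "exploit"]
    eps = segment_state_episodes(_session(states))
    covered = [
        t
        for _, e in eps.iterrows()
        for t in range(e["trial_start"], e["trial_end"] + 1)
    ]
    assert sorted(covered) == list(range(len(states)))


def test_episode_counts_alternate(labeled_trials):
    counts = episode_counts(segment_state_episodes(labeled_trials))
    assert (abs(counts["n_explore"] - counts["n_exploit"]) <= 1).all()


def test_explore_episodes_split_by_side():
    df = _session(
        ["explore"] * 4,
        sides=["left", "right", "left", "right"],
        xs=[100, 700, 110, 710],
    )
    bouts = spatial_bouts(df)
    assert len(bouts) == 2  # one left bout, one right bout within the episode
    assert set(bouts["side"]) == {"left", "right"}


def test_centroid_shift_three_four_five():
    df = _session(
        ["exploit"] * 2 + ["explore"] + ["exploit"] * 2,
        xs=[100, 100, 400, 103, 103],
        ys=[300, 300, 300, 304, 304],
    )
    bouts = spatial_bouts(df)
    shifts = centroid_shift_distances(bouts)
    ex = shifts[shifts["state"] == "exploit"]
    assert len(ex) == 1
    assert ex["shift_mm"].iloc[0] == pytest.approx(5 * 0.29)


def test_centroid_shift_identical_centroids_is_zero():
    df = _session(
        ["exploit", "exploit", "explore", "exploit", "exploit"],
        xs=[100, 110, 400, 100, 110],
        ys=[300, 300, 300, 300, 300],
    )
    shifts = centroid_shift_distances(spatial_bouts(df))
    ex = shifts[shifts["state"] == "exploit"]
    assert ex["shift_mm"].iloc[0] == pytest.approx(0.0)


def test_centroid_shift_matches_recomposed_centroids(labeled_trials):
    bouts = spatial_bouts(labeled_trials)
    shifts = centroid_shift_distances(bouts)
    g = bouts[
        (bouts["mouse_id"] == bouts["mouse_id"].iloc[0]) & (bouts["session"] == 0)
    ]
    one = g[(g["state"] == "exploit") & (g["side"] == "left")].sort_values("episode")
    if len(one) >= 2:
        d = np.hypot(
            np.diff(one["centroid_x_px"]), np.diff(one["centroid_y_px"])
        ) * 0.29
        got = shifts[
            (shifts["mouse_id"] == one["mouse_id"].iloc[0])
            & (shifts["session"] == 0)
            & (shifts["state"] == "exploit")
            & (shifts["side"] == "left")
        ]["shift_mm"].to_numpy()
        assert np.allclose(np.sort(got), np.sort(d))
    assert len(shifts) == 0 or (shifts["shift_mm"] >= 0).all()


def test_fewer_than_two_bouts_gives_empty_result():
    shifts = centroid_shift_distances(spatial_bouts(make_fixture("all_exploit")))
    assert len(shifts) == 0


def test_shoelace_unit_square_and_triangle():
    assert polygon_area_perimeter([(0, 0), (1, 0), (1, 1), (0, 1)]) == (1.0, 4.0)
    area, perim = polygon_area_perimeter([(0, 0), (3, 0), (0, 4)])
    assert area == pytest.approx(6.0)
    assert perim == pytest.approx(12.0)


def test_shoelace_orientation_invariance(rng):
    pts = rng.random((6, 2)).cumsum(axis=0)  # simple-ish polygon not required
    hull = pts[np.argsort(np.arctan2(*(pts - pts.mean(0)).T[::-1]))]
    a1, p1 = polygon_area_perimeter(hull)
    a2, p2 = polygon_area_perimeter(hull[::-1])
    assert a1 == pytest.approx(a2) and p1 == pytest.approx(p2)
    with pytest.raises(ValueError):
        polygon_area_perimeter([(0, 0), (1, 1)])


def test_uniform_square_support_area_recovered(rng):
    pts = rng.uniform(0, 20, size=(10_000, 2))
    res = bout_density_boundary(pts)
    assert not res.degenerate
    assert res.area_mm2 == pytest.approx(400.0, rel=0.15)
    assert res.perimeter_mm == pytest.approx(80.0, rel=0.20)


def test_scaling_doubles_perimeter_quadruples_area(rng):
    pts = rng.normal(scale=3.0, size=(2_000, 2))
    r1 = bout_density_boundary(pts)
    r2 = bout_density_boundary(2 * pts)
    assert r2.area_mm2 == pytest.approx(4 * r1.area_mm2, rel=0.25)
    assert r2.perimeter_mm == pytest.approx(2 * r1.perimeter_mm, rel=0.25)


def test_coincident_or_sparse_points_flagged_degenerate():
    assert bout_density_boundary(np.zeros((50, 2))).degenerate
    assert bout_density_boundary(np.random.default_rng(0).random((3, 2))).degenerate


def test_points_lie_within_outer_boundary(rng):
    from shapely.geometry import Point, Polygon

    pts = rng.normal(scale=4.0, size=(800, 2))
    res = bout_density_boundary(pts, outer_level=1e-9)  # all occupied bins
    # one coarsened bin width of slack on each axis
    bw = 2 * max(
        np.diff(np.histogram_bin_edges(pts[:, 0], bins="auto"))[0],
        np.diff(np.histogram_bin_edges(pts[:, 1], bins="auto"))[0],
    )
    union = Polygon()
    for p in res.polygons:
        union = union.union(Polygon(p))
    union = union.buffer(bw)
    assert all(union.contains(Point(p)) for p in pts)


def test_dispersion_increase_grows_mean_bout_area():
    areas = {}
    for sd in (2.0, 6.0):
        cfg = CohortConfig(
            n_per_sex=2,
            n_sessions=2,
            touch=TouchGenParams(exploit_sd_mm=sd, explore_sd_mm=sd * 2),
        )
        trials = generate_cohort(cfg, seed=9).trials
        trials["state"] = trials["true_state"]
        from touchbandit import bout_table

        bt = bout_table(trials)
        areas[sd] = bt["area_mm2"].mean()
    assert areas[6.0] > areas[2.0]
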