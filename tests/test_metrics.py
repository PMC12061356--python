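"""Spatial/temporal precision metrics: worked examples and oracles."""

import numpy as np
import pandas as pd
import pytest

from touchbandit import (
    CohortConfig,
    TouchGenParams,
    center_distance_mm,
    distance_from_center_px,
    exclusion_summary,
    generate_cohort,
    latency_summary,
    mahalanobis_distances,
    mahalanobis_table,
    make_fixture,
    px_to_mm,
    successive_euclidean,
)
from touchbandit.metrics import add_prev_reward, condition_on_prev_reward


def test_center_distance_worked_example():
    assert distance_from_center_px(34) == 366
    assert distance_from_center_px(400) == 0
    assert distance_from_center_px(766) == 366  # symmetry about the midline
    with pytest.raises(ValueError):
        distance_from_center_px(900)


def test_pixel_to_mm_calibration():
    assert px_to_mm(1) == pytest.approx(0.29)
    assert px_to_mm(0) == 0.0
    assert px_to_mm(366) == pytest.approx(106.14)
    assert center_distance_mm(34) == pytest.approx(106.14)
    with pytest.raises(ValueError):
        px_to_mm(-1)


def test_successive_euclidean_three_four_five():
    df = pd.DataFrame(
        {
            "mouse_id": "m",
            "sex": "F",
            "session": 0,
            "trial": [0, 1],
            "side": "left",
            "x": [100.0, 103.0],
            "y": [300.0, 304.0],
            "state": "exploit",
            "reward": [1, 0],
        }
    )
    pairs = successive_euclidean(df)
    assert len(pairs) == 1
    assert pairs["dist_mm"].iloc[0] == pytest.approx(5 * 0.29)
    assert pairs["included"].all()
    assert pairs["prev_reward"].iloc[0] == 1


def test_side_switch_fixture_exclusion_accounting():
    df = make_fixture("side_switch_6")
    pairs = successive_euclidean(df)
    assert len(pairs) == 5
    summary = exclusion_summary(pairs)
    assert summary["n_excluded"] == 1
    assert pairs.loc[~pairs["included"], "exclusion_reason"].tolist() == [
        "side_transition"
    ]
    assert pairs.loc[~pairs["included"], "trial"].tolist() == [3]


def test_exclusion_taxonomy_and_accounting_identity():
    # 6 trials: side switch (t2), state switch (t3), both (t5)
    df = pd.DataFrame(
        {
            "mouse_id": "m",
            "session": 0,
            "trial": range(6),
            "side": ["left", "left", "right", "right", "right", "left"],
            "state": ["explore"] * 2 + ["explore", "exploit", "exploit", "explore"],
            "x": np.linspace(100, 700, 6),
            "y": 300.0,
        }
    )
    pairs = successive_euclidean(df)
    s = exclusion_summary(pairs)
    reasons = pairs["exclusion_reason"].tolist()
    assert reasons == ["none", "side_transition", "state_transition", "none", "both"]
    assert s["n_excluded"] == 3
    assert pairs["included"].sum() + s["n_excluded"] == len(df) - 1
    assert s["pct_excluded"] == pytest.approx(
        s["pct_side_transition"] + s["pct_state_transition"] + s["pct_both"]
    )


def test_pairs_never_span_sessions():
    df = pd.concat(
        [make_fixture("all_exploit"), make_fixture("all_exploit").assign(session=1)]
    ).reset_index(drop=True)
    pairs = successive_euclidean(df)
    assert len(pairs) == 18  # 9 per session, no cross-session pair


def test_identical_touches_have_zero_distance():
    df = make_fixture("all_exploit").assign(x=200.0, y=300.0)
    pairs = successive_euclidean(df)
    assert np.allclose(pairs["dist_mm"], 0.0)
    assert pairs["included"].all()


def test_missing_state_labels_rejected():
    df = make_fixture("side_switch_6").drop(columns=["state"])
    with pytest.raises(ValueError):
        successive_euclidean(df)


def test_mahalanobis_centroid_point_is_zero():
    pts = np.array([[0, 0], [2, 0], [0, 2], [2, 2], [1, 1]], dtype=float)
    d = mahalanobis_distances(pts)
    assert d[-1] == pytest.approx(0.0, abs=1e-12)  # centroid member


def test_mahalanobis_reduces_to_euclidean_under_identity_covariance(rng):
    # construct a cloud with identity sample covariance by whitening
    raw = rng.normal(size=(500, 2))
    raw -= raw.mean(axis=0)
    L = np.linalg.cholesky(np.cov(raw, rowvar=False))
    pts = raw @ np.linalg.inv(L).T
    d = mahalanobis_distances(pts)
    eu = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    assert np.allclose(d, eu, atol=1e-8)


def test_mahalanobis_matches_direct_matrix_algebra():
    pts = np.array(
        [[1.0, 2.0], [3.0, 1.0], [2.5, 4.0], [0.5, 3.0], [4.0, 3.5], [2.0, 0.5]]
    )
    d = mahalanobis_distances(pts)
    c = pts.mean(axis=0)
    inv = np.linalg.inv(np.cov(pts, rowvar=False))
    for i, p in enumerate(pts):
        v = p - c
        assert d[i] == pytest.approx(float(np.sqrt(v @ inv @ v)), rel=1e-12)


def test_mahalanobis_degenerate_group_skipped():
    with pytest.raises(ValueError):
        mahalanobis_distances(np.array([[0.0, 0.0], [1.0, 1.0]]))
    with pytest.raises(np.linalg.LinAlgError):
        mahalanobis_distances(np.column_stack([np.arange(5.0), np.arange(5.0)]))
    # table-level: collinear group produces NaN rows, others still computed
    df = make_fixture("all_exploit").assign(y=300.0)
    out = mahalanobis_table(df, split_by_state=True)
    assert out["mahal"].isna().all()


def test_prev_reward_conditioning_and_permutation(rng):
    cfg = CohortConfig(
        n_per_sex=2,
        n_sessions=2,
        touch=TouchGenParams(post_reward_mult=0.5),
    )
    trials = generate_cohort(cfg, seed=3).trials
    trials["state"] = trials["true_state"]
    pairs = successive_euclidean(trials)
    inc = pairs[pairs["included"]]
    by = inc.groupby("prev_reward")["dist_mm"].mean()
    assert by[1] < by[0]  # planted post-reward shrinkage
    # shuffling the labels destroys the difference
    gaps = []
    for _ in range(50):
        perm = inc.assign(prev_reward=rng.permutation(inc["prev_reward"].to_numpy()))
        byp = perm.groupby("prev_reward")["dist_mm"].mean()
        gaps.append(byp[0] - byp[1])
    assert (by[0] - by[1]) > np.quantile(gaps, 0.99)


def test_condition_on_prev_reward_flags_empty_cell(caplog):
    df = add_prev_reward(make_fixture("all_exploit").assign(reward=1))
    df["val"] = 1.0
    with caplog.at_level("WARNING"):
        res = condition_on_prev_reward(df, "val")
    assert (res["prev_reward"] == 1).all()
    assert "no observations" in caplog.text


def test_latency_summary():
    df = make_fixture("all_exploit").assign(rt=1.0)
    out = latency_summary(df)
    assert out["mean"].iloc[0] == pytest.approx(1.0)
    single = make_fixture("worked_example").assign(rt=2.5)
    assert latency_summary(single)["mean"].iloc[0] == pytest.approx(2.5)
    with pytest.raises(ValueError):
        latency_summary(df.assign(rt=-1.0))


def test_planted_latency_shift_recovered(labeled_trials):
    out = latency_summary(labeled_trials)
    wide = out.pivot_table(index="mouse_id", columns="state", values="mean")
    assert (wide["exploit"] < wide["explore"]).all()
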