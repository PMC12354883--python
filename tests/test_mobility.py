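"""Smallest enclosing circle and mobile/immobilized classification."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from smforce import (
    MotionModel,
    SyntheticScenario,
    TrajectoryDataset,
    bound_fraction,
    classify_mobility,
    generate_force_dataset,
    smallest_enclosing_circle,
)


def brute_force_sec(points):
    """Oracle: try all circles through 2 and 3 support points."""
    pts = np.asarray(points, dtype=float)

    def contains_all(center, r):
        return np.all(np.hypot(*(pts - center).T) <= r + 1e-9 * (1 + r))

    best = (None, np.inf)
    if len(pts) == 1:
        return pts[0], 0.0
    for a, b in combinations(range(len(pts)), 2):
        c = 0.5 * (pts[a] + pts[b])
        r = np.hypot(*(pts[a] - c))
        if r < best[1] and contains_all(c, r):
            best = (c, r)
    for a, b, c3 in combinations(range(len(pts)), 3):
        p, q, s = pts[a], pts[b], pts[c3]
        d = 2 * (p[0] * (q[1] - s[1]) + q[0] * (s[1] - p[1]) + s[0] * (p[1] - q[1]))
        if abs(d) < 1e-14:
            continue
        p2, q2, s2 = (p * p).sum(), (q * q).sum(), (s * s).sum()
        ux = (p2 * (q[1] - s[1]) + q2 * (s[1] - p[1]) + s2 * (p[1] - q[1])) / d
        uy = (p2 * (s[0] - q[0]) + q2 * (p[0] - s[0]) + s2 * (q[0] - p[0])) / d
        center = np.array([ux, uy])
        r = np.hypot(*(p - center))
        if r < best[1] and contains_all(center, r):
            best = (center, r)
    return best


class TestSmallestEnclosingCircle:
    def test_single_point(self):
        center, r = smallest_enclosing_circle([[1.0, 2.0]])
        assert r == 0.0 and np.allclose(center, [1.0, 2.0])

    def test_two_points_diameter(self):
        center, r = smallest_enclosing_circle([[0.0, 0.0], [2.0, 0.0]])
        assert r == pytest.approx(1.0)
        assert np.allclose(center, [1.0, 0.0])

    def test_equilateral_triangle_circumradius(self):
        pts = [[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]]
        _, r = smallest_enclosing_circle(pts)
        assert r == pytest.approx(1 / np.sqrt(3), abs=1e-12)

    def test_contains_all_points(self, rng):
        pts = rng.normal(size=(50, 2))
        center, r = smallest_enclosing_circle(pts)
        assert np.all(np.hypot(*(pts - center).T) <= r + 1e-9)

    def test_deterministic(self, rng):
        pts = rng.normal(size=(30, 2))
        assert smallest_enclosing_circle(pts)[1] == smallest_enclosing_circle(pts)[1]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(777)
        for _ in range(250):
            n = rng.integers(1, 13)
            pts = rng.uniform(-1, 1, size=(n, 2))
            _, r = smallest_enclosing_circle(pts)
            _, r_oracle = brute_force_sec(pts)
            assert r == pytest.approx(r_oracle, abs=1e-9)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            smallest_enclosing_circle(np.empty((0, 2)))


def _static_track(tid, n, jitter, rng, t0=0.0):
    return pd.DataFrame({
        "track_id": tid,
        "frame": np.arange(n),
        "time_s": t0 + np.arange(n) * 1.0,
        "x_um": rng.normal(0, jitter, n),
        "y_um": rng.normal(0, jitter, n),
    })


class TestClassifyMobility:
    def test_static_track_immobilized(self, rng):
        ds = TrajectoryDataset(_static_track(0, 11, 0.01, rng))
        labels = classify_mobility(ds)
        assert labels["label"].iloc[0] == "immobilized"

    def test_short_track_labeled_too_short(self, rng):
        ds = TrajectoryDataset(_static_track(0, 4, 0.01, rng))
        labels = classify_mobility(ds)
        assert labels["label"].iloc[0] == "too_short"

    def test_reduced_radius_definition(self, rng):
        ds = TrajectoryDataset(_static_track(0, 11, 0.05, rng))
        row = classify_mobility(ds).iloc[0]
        assert row["reduced_radius"] == pytest.approx(
            row["radius_um"] / np.sqrt(row["duration_s"])
        )

    def test_brownian_tracks_classified_mobile(self):
        # D = 0.7 um^2/s, 20 frames at 0.1 s: mobile with prob > 0.95
        ds = generate_force_dataset(
            SyntheticScenario(n_tracks=500, mean_track_length=20, seed=31),
            motion=MotionModel(D_mobile=0.7, frame_interval=0.1),
        )
        labels = classify_mobility(ds)
        classified = labels[labels["label"] != "too_short"]
        assert (classified["label"] == "mobile").mean() > 0.95

    def test_zero_duration_immobilized_by_convention(self):
        df = pd.DataFrame({
            "track_id": 0, "frame": np.arange(5), "time_s": np.zeros(5),
            "x_um": np.zeros(5), "y_um": np.zeros(5),
        })
        labels = classify_mobility(TrajectoryDataset(df))
        assert labels["label"].iloc[0] == "immobilized"


class TestBoundFraction:
    def _labels(self, labels_list):
        return pd.DataFrame({
            "track_id": range(len(labels_list)), "label": labels_list,
        })

    def test_all_immobilized(self):
        res = bound_fraction(self._labels(["immobilized"] * 5), n_boot=0)
        assert res.fraction == 1.0

    def test_too_short_excluded_from_denominator(self):
        res = bound_fraction(
            self._labels(["immobilized", "mobile", "too_short", "too_short"]),
            n_boot=0,
        )
        assert res.n_classified == 2 and res.fraction == 0.5

    def test_label_swap_symmetry(self):
        lab = ["immobilized"] * 3 + ["mobile"] * 7
        swapped = ["mobile" if x == "immobilized" else "immobilized" for x in lab]
        p = bound_fraction(self._labels(lab), n_boot=0).fraction
        q = bound_fraction(self._labels(swapped), n_boot=0).fraction
        assert p == pytest.approx(1 - q)

    def test_all_too_short_errors(self):
        with pytest.raises(ValueError):
            bound_fraction(self._labels(["too_short"] * 3))

    def test_generator_truth_recovery(self):
        ds = generate_force_dataset(
            SyntheticScenario(n_tracks=300, phi_immobile=0.3, mean_track_length=15,
                              seed=44)
        )
        labels = classify_mobility(ds)
        res = bound_fraction(labels, n_boot=500, seed=9)
        assert abs(res.fraction - 0.3) < 3 * max(res.bootstrap.se, 0.01)

    def test_conditioning_on_immobilized_recovers_force_statistics(
        self, mixture_dataset, no_cell_dataset
    ):
        # integration: force analysis restricted to the immobilized class
        # reproduces the restriction to generator-truth bound tracks
        from smforce import compute_threshold, high_force_fraction

        thr = compute_threshold(no_cell_dataset.data["efficiency"].to_numpy())
        labels = classify_mobility(mixture_dataset)
        imm_ids = set(labels.loc[labels["label"] == "immobilized", "track_id"])
        df = mixture_dataset.data
        truth_ids = set(df.loc[~df["truth_mobile"], "track_id"])
        eff_imm = df[df["track_id"].isin(imm_ids)]["efficiency"].to_numpy()
        eff_truth = df[df["track_id"].isin(truth_ids)]["efficiency"].to_numpy()
        f_imm = high_force_fraction(eff_imm, thr).fraction_point
        f_truth = high_force_fraction(eff_truth, thr).fraction_point
        # classification errors are few; fractions agree closely
        assert f_imm == pytest.approx(f_truth, abs=0.1)
        assert f_imm > 0.15  # force events concentrate in the bound class
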