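"""FRET computation, filtering contracts and the single-emitter filter."""

import numpy as np
import pandas as pd
import pytest

from smforce import (
    FretCorrections,
    TrajectoryDataset,
    compute_fret,
    filter_tracks,
    single_emitter_filter,
)
from smforce.preprocessing import count_bleaching_steps


def make_ds(rows):
    df = pd.DataFrame(rows)
    defaults = {"time_s": 0.0, "x_um": 0.0, "y_um": 0.0}
    for k, v in defaults.items():
        if k not in df.columns:
            df[k] = v
    if "time_s" not in rows[0]:
        df["time_s"] = df["frame"] * 0.1
    return TrajectoryDataset(df)


class TestComputeFret:
    @pytest.mark.parametrize(
        "donor, acceptor, expected",
        [(100.0, 100.0, 0.5), (30.0, 70.0, 0.7)],
    )
    def test_identity_corrections_give_proximity_ratio(self, donor, acceptor,
                                                       expected):
        ds = make_ds([{"track_id": 0, "frame": 0, "i_donor": donor,
                       "i_acceptor": acceptor}])
        out = compute_fret(ds)
        assert out.data["efficiency"].iloc[0] == pytest.approx(expected)

    def test_bleedthrough_correction(self):
        # donor 100, acceptor 60, bleedthrough 0.1 -> corrected 50, E = 1/3
        ds = make_ds([{"track_id": 0, "frame": 0, "i_donor": 100.0,
                       "i_acceptor": 60.0}])
        out = compute_fret(ds, FretCorrections(bleedthrough=0.1))
        assert out.data["efficiency"].iloc[0] == pytest.approx(1 / 3, abs=1e-4)

    def test_stoichiometry_with_alex_channel(self):
        ds = make_ds([{"track_id": 0, "frame": 0, "i_donor": 100.0,
                       "i_acceptor": 100.0, "i_acceptor_aex": 200.0}])
        out = compute_fret(ds)
        assert out.data["stoichiometry"].iloc[0] == pytest.approx(0.5)

    def test_negative_corrected_intensity_flagged_not_dropped(self):
        ds = make_ds([{"track_id": 0, "frame": 0, "i_donor": 100.0,
                       "i_acceptor": 5.0}])
        out = compute_fret(ds, FretCorrections(bleedthrough=0.1))
        assert len(out.data) == 1
        assert any("negative corrected" in line for line in out.log)

    def test_zero_total_dropped_with_log(self):
        ds = make_ds([
            {"track_id": 0, "frame": 0, "i_donor": 0.0, "i_acceptor": 0.0},
            {"track_id": 0, "frame": 1, "i_donor": 50.0, "i_acceptor": 50.0},
        ])
        out = compute_fret(ds)
        assert len(out.data) == 1
        assert any("zero" in line for line in out.log)

    def test_matches_proximity_ratio_on_synthetic_data(self, no_cell_dataset):
        out = compute_fret(no_cell_dataset)
        df = out.data
        expected = df["i_acceptor"] / (df["i_acceptor"] + df["i_donor"])
        assert np.allclose(df["efficiency"], expected)


class TestFilterTracks:
    def _two_close_tracks(self, dist):
        rows = []
        for tid, x in ((0, 0.0), (1, dist)):
            for fr in range(6):
                rows.append({"track_id": tid, "frame": fr, "time_s": fr * 0.1,
                             "x_um": x, "y_um": 0.0, "efficiency": 0.8})
        return TrajectoryDataset(pd.DataFrame(rows))

    def test_proximity_removes_both_partners(self):
        ds = self._two_close_tracks(0.2)
        out = filter_tracks(ds, min_length=1, neighbor_radius=0.5,
                            efficiency_range=None, stoichiometry_range=None)
        assert out.data.empty

    def test_zero_radius_is_vacuous(self):
        ds = self._two_close_tracks(0.2)
        out = filter_tracks(ds, min_length=1, neighbor_radius=0.0,
                            efficiency_range=None, stoichiometry_range=None)
        assert len(out.data) == 12

    def test_short_tracks_removed(self):
        rows = [{"track_id": 0, "frame": f, "time_s": f * 0.1, "x_um": 0.0,
                 "y_um": 0.0, "efficiency": 0.8} for f in range(4)]
        rows += [{"track_id": 1, "frame": f, "time_s": f * 0.1, "x_um": 5.0,
                  "y_um": 5.0, "efficiency": 0.8} for f in range(5)]
        out = filter_tracks(TrajectoryDataset(pd.DataFrame(rows)), min_length=5,
                            neighbor_radius=0.0)
        assert out.data["track_id"].unique().tolist() == [1]

    def test_efficiency_window(self):
        rows = [{"track_id": 0, "frame": f, "time_s": f * 0.1, "x_um": 0.0,
                 "y_um": 0.0, "efficiency": e}
                for f, e in enumerate([0.5, 2.0, -0.9, 0.8, 0.1])]
        out = filter_tracks(TrajectoryDataset(pd.DataFrame(rows)), min_length=1,
                            neighbor_radius=0.0, efficiency_range=(-0.5, 1.5))
        assert len(out.data) == 3

    def test_order_insensitive_on_independent_rules(self):
        # far-apart tracks: proximity never fires, so proximity+length in
        # either order gives the same result
        rows = []
        for tid, npts in ((0, 3), (1, 8)):
            for f in range(npts):
                rows.append({"track_id": tid, "frame": f, "time_s": f * 0.1,
                             "x_um": tid * 10.0, "y_um": 0.0, "efficiency": 0.8})
        ds = TrajectoryDataset(pd.DataFrame(rows))
        a = filter_tracks(filter_tracks(ds, min_length=1, neighbor_radius=0.5),
                          min_length=5, neighbor_radius=0.0)
        b = filter_tracks(filter_tracks(ds, min_length=5, neighbor_radius=0.0),
                          min_length=1, neighbor_radius=0.5)
        pd.testing.assert_frame_equal(a.data.reset_index(drop=True),
                                      b.data.reset_index(drop=True))

    def test_removal_counts_logged(self):
        ds = self._two_close_tracks(0.2)
        out = filter_tracks(ds, min_length=1, neighbor_radius=0.5)
        assert any("proximity" in line and "12" in line for line in out.log)


class TestSingleEmitterFilter:
    def _track(self, tid, intensities):
        return [{"track_id": tid, "frame": f, "time_s": f * 0.1, "x_um": 0.0,
                 "y_um": 0.0, "i_donor": v / 2, "i_acceptor": v / 2}
                for f, v in enumerate(intensities)]

    def test_single_step_bleach_kept(self, rng):
        trace = np.r_[np.full(10, 1000.0), np.full(10, 5.0)]
        trace += rng.normal(0, 10, trace.size)
        assert count_bleaching_steps(trace) == 1
        ds = TrajectoryDataset(pd.DataFrame(self._track(0, trace)))
        assert not single_emitter_filter(ds).data.empty

    def test_two_step_staircase_removed(self, rng):
        trace = np.r_[np.full(8, 2000.0), np.full(8, 1000.0), np.full(8, 5.0)]
        trace += rng.normal(0, 10, trace.size)
        assert count_bleaching_steps(trace) == 2
        ds = TrajectoryDataset(pd.DataFrame(self._track(0, trace)))
        out = single_emitter_filter(ds)
        assert out.data.empty
        assert any("removed 1" in line for line in out.log)

    def test_stepless_noisy_trace_kept(self, rng):
        trace = 1000.0 + rng.normal(0, 30, 25)
        assert count_bleaching_steps(trace) == 0
        ds = TrajectoryDataset(pd.DataFrame(self._track(0, trace)))
        assert len(single_emitter_filter(ds).data) == 25

    def test_upward_step_not_counted_as_bleach(self, rng):
        trace = np.r_[np.full(10, 500.0), np.full(10, 1500.0)]
        trace += rng.normal(0, 10, trace.size)
        assert count_bleaching_steps(trace) == 0

    def test_short_tracks_pass_with_log(self):
        ds = TrajectoryDataset(pd.DataFrame(self._track(0, [100.0, 90.0])))
        out = single_emitter_filter(ds)
        assert len(out.data) == 2
        assert any("too short" in line for line in out.log)
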