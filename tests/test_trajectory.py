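"""Track cleaning, QC, visit segmentation and session summaries."""

import numpy as np
import pandas as pd
import pytest

from thermodrift import synthetic, trajectory
from thermodrift.trajectory import (
    ANIMAL_KEYPOINTS,
    CORNER_KEYPOINTS,
    TOP_KEYPOINTS,
    ChamberGeometry,
    KeypointTrack,
    SessionRejected,
)


def toy_track(n_frames=100, frame_rate=10.0, x_px=400.0, y_px=300.0, likelihood=1.0):
    """Minimal track: all animal keypoints coincident, reference points static."""
    cols = {}
    for kp in ANIMAL_KEYPOINTS:
        cols[(kp, "x")] = np.full(n_frames, x_px)
        cols[(kp, "y")] = np.full(n_frames, y_px)
        cols[(kp, "likelihood")] = np.full(n_frames, likelihood)
    for kp, (px, py) in zip(CORNER_KEYPOINTS, [(100, 100), (700, 100), (100, 500), (700, 500)]):
        cols[(kp, "x")] = np.full(n_frames, float(px))
        cols[(kp, "y")] = np.full(n_frames, float(py))
        cols[(kp, "likelihood")] = np.full(n_frames, 0.999)
    for kp, (px, py) in zip(TOP_KEYPOINTS, [(100, 600), (700, 600), (120, 600), (680, 600)]):
        cols[(kp, "x")] = np.full(n_frames, float(px))
        cols[(kp, "y")] = np.full(n_frames, float(py))
        cols[(kp, "likelihood")] = np.full(n_frames, 0.999)
    data = pd.DataFrame(cols, index=pd.RangeIndex(n_frames, name="frame")).sort_index(axis=1)
    return KeypointTrack(data=data, frame_rate=frame_rate)


@pytest.fixture(scope="module")
def one_session():
    cfg = synthetic.BehaviorSimConfig(
        n_animals_per_genotype=1,
        genotypes={"wildtype": synthetic.DEFAULT_GENOTYPES["wildtype"]},
        seed=21,
    )
    sample = synthetic.gen_behavior_sessions(cfg, make_tracks=True)
    animal = sample.visits["animal"].iloc[0]
    return cfg, sample.visits, sample.tracks[animal]


class TestCleanTrack:
    def test_perfect_track_is_unchanged(self):
        tr = toy_track()
        out = trajectory.clean_track(tr)
        pd.testing.assert_frame_equal(out.data, tr.data)

    def test_missing_fraction_rule_is_strict(self):
        # 26% dropout is rejected, 24% accepted (rule: > 25% missing)
        base = dict(n_animals_per_genotype=1, genotypes={"wildtype": synthetic.DEFAULT_GENOTYPES["wildtype"]}, seed=7)
        tr26 = list(synthetic.gen_behavior_sessions(synthetic.BehaviorSimConfig(dropout_prob=0.26, **base), True).tracks.values())[0]
        with pytest.raises(SessionRejected, match="missing fraction"):
            trajectory.clean_track(tr26)
        tr24 = list(synthetic.gen_behavior_sessions(synthetic.BehaviorSimConfig(dropout_prob=0.24, **base), True).tracks.values())[0]
        trajectory.clean_track(tr24)  # accepted

    def test_single_missing_frame_interpolates_linearly(self):
        tr = toy_track(n_frames=3)
        tr.data[("snout", "x")] = [1.0, 99.0, 3.0]
        tr.data[("snout", "likelihood")] = [1.0, 0.1, 1.0]
        out = trajectory.clean_track(tr)
        assert out.data[("snout", "x")].iloc[1] == pytest.approx(2.0)

    def test_all_missing_keypoint_rejects(self):
        tr = toy_track()
        tr.data[("tail_tip", "likelihood")] = 0.0
        with pytest.raises(SessionRejected, match="tail_tip"):
            trajectory.clean_track(tr)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            trajectory.clean_track(toy_track(), likelihood_thresh=1.5)


class TestClimbingQC:
    @pytest.mark.parametrize("frac,expected", [(0.96, True), (0.95, False)])
    def test_strict_threshold(self, frac, expected):
        cfg = synthetic.BehaviorSimConfig(
            n_animals_per_genotype=1,
            genotypes={"wildtype": synthetic.DEFAULT_GENOTYPES["wildtype"]},
            seed=6,
            climbing_frac=frac,
            dropout_prob=0.0,
        )
        tr = list(synthetic.gen_behavior_sessions(cfg, True).tracks.values())[0]
        assert trajectory.qc_climbing(tr) is expected

    def test_floor_session_not_flagged(self):
        assert trajectory.qc_climbing(toy_track()) is False

    def test_missing_reference_points_error(self):
        tr = toy_track()
        tr.data = tr.data.drop(columns=[("top_bl", "x"), ("top_bl", "y"), ("top_bl", "likelihood")])
        with pytest.raises(ValueError, match="top"):
            trajectory.qc_climbing(tr)


class TestToPosition:
    def test_centroid_is_arithmetic_mean(self):
        tr = toy_track(n_frames=40, frame_rate=10.0)
        for kp, (x, y) in zip(trajectory.POSITION_KEYPOINTS, [(0, 0), (0, 2), (2, 0), (2, 2)]):
            tr.data[(kp, "x")] = 100.0 + 600.0 * x / 2
            tr.data[(kp, "y")] = 100.0 + 400.0 * y / 2
        pos = trajectory.to_position(tr, session_length=4)
        assert np.allclose(pos["x"], 0.5)
        assert np.allclose(pos["y"], 0.5)

    def test_downsampling_to_one_hz(self):
        tr = toy_track(n_frames=36_000, frame_rate=20.0)
        pos = trajectory.to_position(tr, session_length=1800)
        assert len(pos) == 1800

    def test_camera_shift_invariance(self):
        tr = toy_track(n_frames=40, frame_rate=10.0)
        pos0 = trajectory.to_position(tr, session_length=4)
        shifted = toy_track(n_frames=40, frame_rate=10.0)
        for kp in shifted.keypoints:
            shifted.data[(kp, "x")] += 37.0
            shifted.data[(kp, "y")] -= 12.0
        pos1 = trajectory.to_position(shifted, session_length=4)
        np.testing.assert_allclose(pos1["x"], pos0["x"], atol=1e-12)
        np.testing.assert_allclose(pos1["y"], pos0["y"], atol=1e-12)

    def test_short_session_rejected(self):
        tr = toy_track(n_frames=100, frame_rate=10.0)
        with pytest.raises(SessionRejected, match="shorter"):
            trajectory.to_position(tr, session_length=1800)


def _pos_frame(xs):
    return pd.DataFrame({"time": np.arange(len(xs), dtype=float), "x": xs, "y": 0.5})


class TestSegmentVisits:
    def test_constructed_alternation(self):
        x = np.concatenate([np.full(60, 0.2), np.full(120, 0.8), np.full(60, 0.2)])
        visits = trajectory.segment_visits(_pos_frame(x))
        assert list(visits["chamber"]) == ["neutral", "test", "neutral"]
        assert list(visits["duration"]) == [60.0, 120.0, 60.0]
        assert list(visits["censored"]) == [False, False, True]
        assert visits.attrs["crossings"] == 2

    def test_whole_session_single_chamber(self):
        visits = trajectory.segment_visits(_pos_frame(np.full(1800, 0.2)))
        assert len(visits) == 1
        assert visits["duration"].iloc[0] == 1800.0
        assert visits.attrs["crossings"] == 0

    def test_tunnel_samples_attach_to_preceding_visit(self):
        x = np.concatenate([np.full(10, 0.2), np.full(3, 0.5), np.full(10, 0.8)])
        visits = trajectory.segment_visits(_pos_frame(x))
        assert list(visits["duration"]) == [13.0, 10.0]

    def test_all_tunnel_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="tunnel"):
            visits = trajectory.segment_visits(_pos_frame(np.full(30, 0.5)))
        assert len(visits) == 0

    def test_generator_round_trip(self, one_session):
        cfg, truth, track = one_session
        visits = trajectory.segment_visits(trajectory.to_position(trajectory.clean_track(track)), cfg.geometry)
        gt = truth.reset_index(drop=True)
        assert len(visits) == len(gt)
        assert np.abs(visits["duration"].to_numpy() - gt["duration"].to_numpy()).max() <= 1.0

    def test_frame_rate_invariance(self):
        base = dict(n_animals_per_genotype=1, genotypes={"wildtype": synthetic.DEFAULT_GENOTYPES["wildtype"]}, seed=33, dropout_prob=0.0, keypoint_noise_sd=0.001)
        counts = []
        for fr in (20.0, 30.0):
            cfg = synthetic.BehaviorSimConfig(frame_rate=fr, **base)
            sample = synthetic.gen_behavior_sessions(cfg, True)
            track = list(sample.tracks.values())[0]
            visits = trajectory.segment_visits(trajectory.to_position(trajectory.clean_track(track)), cfg.geometry)
            counts.append(len(visits))
        assert counts[0] == counts[1]


class TestSummaries:
    def test_full_test_chamber_session(self):
        visits = trajectory.segment_visits(_pos_frame(np.full(1800, 0.8)))
        s = trajectory.summarize_session(visits)
        assert np.allclose(s.preference["frac_test"], 1.0)
        assert len(s.preference) == 10

    def test_bin_fractions_sum_to_one(self, one_session):
        cfg, truth, track = one_session
        visits = trajectory.segment_visits(trajectory.to_position(trajectory.clean_track(track)), cfg.geometry)
        s = trajectory.summarize_session(visits)
        np.testing.assert_allclose(s.preference["frac_test"] + s.preference["frac_neutral"], 1.0)

    def test_rolling_statistics_match_hand_computation(self):
        # six visits with starts 0, 40, 110, 200, 260, 500 and durations
        # 40, 70, 90, 60, 240, 1300
        visits = pd.DataFrame(
            {
                "chamber": ["neutral", "test", "neutral", "test", "neutral", "test"],
                "start": [0.0, 40.0, 110.0, 200.0, 260.0, 500.0],
                "end": [40.0, 110.0, 200.0, 260.0, 500.0, 1800.0],
                "duration": [40.0, 70.0, 90.0, 60.0, 240.0, 1300.0],
                "censored": [False] * 5 + [True],
            }
        )
        visits.attrs["crossings"] = 5
        s = trajectory.summarize_session(visits)
        r = s.rolling.set_index("window_start")
        # window [0, 180): visits starting at 0, 40, 110 -> mean (40+70+90)/3
        assert r.loc[0.0, "mean_visit_length"] == pytest.approx(200.0 / 3)
        assert r.loc[0.0, "crossings"] == 2  # visits 2 and 3 start inside
        # window [120, 300): visits starting at 200, 260 -> mean (60+240)/2
        assert r.loc[120.0, "mean_visit_length"] == pytest.approx(150.0)
        # window [600, 780): no visit starts -> NaN
        assert np.isnan(r.loc[600.0, "mean_visit_length"])

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            trajectory.summarize_session(pd.DataFrame(columns=["chamber", "start", "end", "duration", "censored"]))


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        tr = toy_track(n_frames=20)
        tr.to_csv(tmp_path / "t.csv")
        back = KeypointTrack.from_csv(tmp_path / "t.csv", frame_rate=tr.frame_rate)
        pd.testing.assert_frame_equal(back.data[tr.data.columns], tr.data)

    def test_hdf5_round_trip(self, tmp_path):
        tr = toy_track(n_frames=20)
        tr.to_hdf5(tmp_path / "t.h5", name="s1")
        back = KeypointTrack.from_hdf5(tmp_path / "t.h5", name="s1")
        pd.testing.assert_frame_equal(back.data[tr.data.columns], tr.data)

    def test_likelihood_validation(self):
        tr = toy_track(n_frames=5)
        tr.data[("snout", "likelihood")] = 1.4
        with pytest.raises(ValueError, match="likelihood"):
            KeypointTrack(data=tr.data, frame_rate=10.0)
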