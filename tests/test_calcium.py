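"""Trace pipeline: normalisation, phase split, classification, onsets, FOV stats."""

import numpy as np
import pandas as pd
import pytest
from sklearn.exceptions import NotFittedError
from sklearn.metrics import balanced_accuracy_score

from thermodrift import calcium as ca
from thermodrift import synthetic
from thermodrift.calcium import Epoch, StimulusTrace


@pytest.fixture(scope="module")
def trained_classifier():
    X, y, rate = synthetic.labelled_training_set(n_traces=1000, seed=11)
    clf = ca.train_responder_classifier(X[:700], y[:700], rate)
    return clf, X[700:], y[700:], rate


@pytest.fixture(scope="module")
def recording():
    cfg = synthetic.CalciumSimConfig(seed=3)
    s = synthetic.gen_calcium_dataset(cfg)
    corrected = ca.neuropil_correct(s.fset.F, s.fset.Fneu, cfg.neuropil_gain)
    by_epoch = ca.dff(corrected, cfg.sample_rate, "first-10-frames-per-stimulus", epochs=s.fset.epochs)
    return cfg, s, corrected, by_epoch


class TestNeuropilCorrection:
    def test_zero_coefficient_is_identity(self):
        F = np.random.default_rng(0).random((3, 10))
        np.testing.assert_array_equal(ca.neuropil_correct(F, F * 2, r=0.0), F)

    def test_seventy_percent_rule(self):
        out = ca.neuropil_correct(np.array([[100.0]]), np.array([[50.0]]), r=0.7)
        assert out[0, 0] == pytest.approx(65.0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            ca.neuropil_correct(np.zeros((2, 5)), np.zeros((3, 5)))
        with pytest.raises(ValueError, match="r must"):
            ca.neuropil_correct(np.zeros((2, 5)), np.zeros((2, 5)), r=1.0)


class TestDff:
    def test_constant_trace_normalises_to_zero(self):
        out = ca.dff(np.full((2, 100), 50.0), sample_rate=10.0)
        assert np.allclose(out.data, 0.0)
        assert out.valid.all()

    def test_thirty_percent_peak(self):
        F = np.full((1, 200), 100.0)
        F[0, 150] = 130.0
        out = ca.dff(F, sample_rate=10.0)
        assert out.data[0, 150] == pytest.approx(0.30)

    def test_clip_bounds_match_sort_based_percentiles(self):
        rng = np.random.default_rng(1)
        F = 100.0 + rng.normal(0, 10, (20, 500))
        out = ca.dff(F, sample_rate=10.0, clip_percentiles=(0.1, 99.9))
        raw = ca.dff(F, sample_rate=10.0)
        # independent oracle: linear-interpolated order statistics on the sorted values
        flat = np.sort(raw.data.ravel())
        n = flat.size

        def q(p):
            h = (n - 1) * p / 100.0
            lo = int(np.floor(h))
            return flat[lo] + (h - lo) * (flat[min(lo + 1, n - 1)] - flat[lo])

        assert out.data.min() == pytest.approx(q(0.1))
        assert out.data.max() == pytest.approx(q(99.9))

    def test_non_positive_f0_flags_cell_invalid(self):
        F = np.vstack([np.full(100, 50.0), np.full(100, -1.0)])
        out = ca.dff(F, sample_rate=10.0)
        assert out.valid.tolist() == [True, False]
        assert np.allclose(out.data[1], 0.0)

    def test_per_stimulus_convention_windows(self):
        F = np.full((1, 1000), 100.0)
        epochs = [Epoch("warm1", start=40.0, end=65.0, plateau=34.0)]
        out = ca.dff(F, sample_rate=10.0, convention="first-10-frames-per-stimulus", epochs=epochs)
        assert set(out) == {"warm1"}
        tr = out["warm1"]
        assert tr.time[0] == pytest.approx(30.0)  # 10 s pre-stimulus context
        assert tr.time[-1] == pytest.approx(64.9)

    def test_unknown_convention_errors(self):
        with pytest.raises(ValueError, match="convention"):
            ca.dff(np.zeros((1, 10)), 10.0, convention="whole-trace")


def ramp_plateau_trace(ramp_s=10.0, plateau_s=15.0, rate=10.0, base=32.0, plateau=37.0, pre_s=30.0, post_s=30.0, noise=0.0, seed=0):
    t = np.arange(int((pre_s + ramp_s + plateau_s + post_s) * rate)) / rate
    temp = np.full(t.size, base)
    ramp = (t >= pre_s) & (t < pre_s + ramp_s)
    temp[ramp] = base + (plateau - base) * (t[ramp] - pre_s) / ramp_s
    temp[t >= pre_s + ramp_s] = plateau
    if noise:
        temp = temp + np.random.default_rng(seed).normal(0, noise, t.size)
    stim = StimulusTrace(time=t, temp=temp, sample_rate=rate)
    epoch = Epoch("warm1", start=pre_s, end=pre_s + ramp_s + plateau_s, plateau=plateau)
    return stim, epoch, pre_s + ramp_s


class TestPhaseSegmentation:
    def test_ideal_ramp_boundary_at_ramp_end(self):
        stim, epoch, ramp_end = ramp_plateau_trace()
        (split,) = ca.segment_phases(stim, [epoch])
        assert abs(split.boundary - ramp_end) <= 1.0 / stim.sample_rate + 1e-9

    def test_offset_invariance(self):
        stim, epoch, _ = ramp_plateau_trace()
        (a,) = ca.segment_phases(stim, [epoch])
        stim2 = StimulusTrace(time=stim.time, temp=stim.temp + 7.0, sample_rate=stim.sample_rate)
        (b,) = ca.segment_phases(stim2, [epoch])
        assert a.boundary == pytest.approx(b.boundary)

    def test_noisy_boundary_accuracy(self):
        errs = []
        for seed in range(30):
            stim, epoch, ramp_end = ramp_plateau_trace(noise=0.05, seed=seed)
            (split,) = ca.segment_phases(stim, [epoch])
            errs.append(abs(split.boundary - ramp_end))
        assert max(errs) < 0.5

    def test_flat_trace_errors(self):
        stim, epoch, _ = ramp_plateau_trace()
        flat = StimulusTrace(time=stim.time, temp=np.full(stim.time.size, 32.0), sample_rate=stim.sample_rate)
        with pytest.raises(ValueError, match="peak"):
            ca.segment_phases(flat, [epoch])

    def test_phase_of_labels(self):
        stim, epoch, ramp_end = ramp_plateau_trace()
        (split,) = ca.segment_phases(stim, [epoch])
        assert split.phase_of(epoch.start + 1.0) == "dynamic"
        assert split.phase_of(epoch.end - 1.0) == "static"


class TestClassifier:
    def test_held_out_balanced_accuracy(self, trained_classifier):
        clf, Xte, yte, rate = trained_classifier
        acc = balanced_accuracy_score(yte, clf.predict(Xte, rate))
        assert acc >= 0.95

    def test_untrained_model_errors(self):
        with pytest.raises(NotFittedError):
            ca.ResponderClassifier().predict(np.zeros((2, 140)))

    def test_no_responders_means_no_calls(self, trained_classifier):
        clf, *_ = trained_classifier
        cfg = synthetic.CalciumSimConfig(n_cells=150, frac_responders=0.0, seed=19, include_agonists=False)
        s = synthetic.gen_calcium_dataset(cfg)
        corrected = ca.neuropil_correct(s.fset.F, s.fset.Fneu, cfg.neuropil_gain)
        by_epoch = ca.dff(corrected, cfg.sample_rate, "first-10-frames-per-stimulus", epochs=s.fset.epochs)
        calls = ca.classify_responders(by_epoch, s.fset.epochs, clf)
        assert calls["responder"].sum() == 0

    def test_identical_inputs_identical_calls(self, recording, trained_classifier):
        cfg, s, corrected, by_epoch = recording
        clf, *_ = trained_classifier
        a = ca.classify_responders(by_epoch, s.fset.epochs, clf)
        b = ca.classify_responders(by_epoch, s.fset.epochs, clf)
        pd.testing.assert_frame_equal(a, b)

    def test_capsaicin_only_cell_flags(self, trained_classifier):
        clf, *_ = trained_classifier
        cfg = synthetic.CalciumSimConfig(n_cells=100, frac_responders=0.0, frac_capsaicin=1.0, seed=23)
        s = synthetic.gen_calcium_dataset(cfg)
        corrected = ca.neuropil_correct(s.fset.F, s.fset.Fneu, cfg.neuropil_gain)
        by_epoch = ca.dff(corrected, cfg.sample_rate, "first-10-frames-per-stimulus", epochs=s.fset.epochs)
        table = ca.build_responder_table(by_epoch, s.fset.epochs, clf)
        cells = table.drop_duplicates("cell")
        assert cells["capsaicin"].all()
        assert not cells["warm_sensitive"].any()


class TestOnsets:
    def test_step_onset_at_step_sample(self):
        rate = 4.0
        t = np.arange(0, 40, 1 / rate)
        tr = np.zeros(t.size)
        epoch = Epoch("warm1", start=10.0, end=35.0, plateau=34.0)
        tr[t >= 15.0] = 1.0
        assert ca.onset_time(tr, t, epoch) == pytest.approx(15.0, abs=1 / rate)

    def test_linear_ramp_onset_at_ten_percent_of_epoch(self):
        rate = 10.0
        t = np.arange(0, 40, 1 / rate)
        epoch = Epoch("warm1", start=10.0, end=30.0, plateau=34.0)
        tr = np.clip((t - epoch.start) / (epoch.end - epoch.start), 0, None)
        onset = ca.onset_time(tr, t, epoch)
        assert onset == pytest.approx(epoch.start + 0.1 * (epoch.end - epoch.start), abs=2 / rate)

    def test_non_positive_trace_errors(self):
        t = np.arange(0, 40, 0.25)
        epoch = Epoch("warm1", start=10.0, end=30.0)
        with pytest.raises(ValueError, match="responder"):
            ca.onset_time(np.full(t.size, -0.1), t, epoch)

    def test_generator_dynamic_cells_labelled_dynamic(self, recording, trained_classifier):
        cfg, s, corrected, by_epoch = recording
        clf, *_ = trained_classifier
        splits = ca.segment_phases(s.fset.stim, s.fset.epochs)
        table = ca.build_responder_table(by_epoch, s.fset.epochs, clf, splits)
        truth_dyn = s.truth[s.truth["responder"] & (s.truth["onset_phase"] == "dynamic")]["cell"]
        sub = table[table["responder"] & table["cell"].isin(set(truth_dyn))]
        assert len(sub) > 0
        assert (sub["onset_phase"] == "dynamic").mean() >= 0.90

    def test_gain_invariance_of_dff_onset_chain(self, recording):
        cfg, s, corrected, _ = recording
        epochs = s.fset.epochs
        ep = next(e for e in epochs if e.thermal)
        cell = int(s.truth[s.truth["responder"]]["cell"].iloc[0])
        onsets = []
        for gain in (1.0, 3.7):
            by = ca.dff(
                ca.neuropil_correct(s.fset.F * gain, s.fset.Fneu * gain, cfg.neuropil_gain),
                cfg.sample_rate,
                "first-10-frames-per-stimulus",
                epochs=epochs,
            )
            tr = by[ep.label]
            onsets.append(ca.onset_time(tr.data[cell], tr.time, ep))
        assert onsets[0] == pytest.approx(onsets[1])


class TestHeatmapOrderAndFOV:
    def test_early_signal_ranks_first_and_oracle_agreement(self):
        rng = np.random.default_rng(2)
        data = rng.random((10, 100)) * 0.1
        data[3, 0] = 50.0  # all of cell 3's signal in the first frame
        tr = ca.DFFTrace(data=data, time=np.arange(100.0), sample_rate=1.0, convention="first-10-s", valid=np.ones(10, bool))
        order = ca.heatmap_order(tr)
        assert order[0] == 3
        # brute-force oracle
        crossing = []
        for row in data:
            cs, tot, j = 0.0, row.sum(), None
            for i, v in enumerate(row):
                cs += v
                if cs >= 0.1 * tot:
                    j = i
                    break
            crossing.append(np.inf if tot <= 0 else j)
        np.testing.assert_array_equal(order, np.argsort(crossing, kind="stable"))

    def test_ties_keep_original_order_and_nonpositive_last(self):
        data = np.vstack([np.ones(10), np.ones(10), -np.ones(10)])
        tr = ca.DFFTrace(data=data, time=np.arange(10.0), sample_rate=1.0, convention="first-10-s", valid=np.ones(3, bool))
        assert ca.heatmap_order(tr).tolist() == [0, 1, 2]

    def test_responder_proportion(self, recording, trained_classifier):
        cfg, s, corrected, by_epoch = recording
        clf, *_ = trained_classifier
        table = ca.build_responder_table(by_epoch, s.fset.epochs, clf)
        stats = ca.fov_stats(table, n_viable=100, dff_by_epoch=by_epoch, epochs=s.fset.epochs)
        row = stats.per_stimulus.set_index("stimulus").loc["warm1"]
        assert row["proportion"] == pytest.approx(row["n_responders"] / 100)

    def test_auc_geometry(self):
        # triangular pulse of base 10 s and height 2 inside the epoch
        rate = 10.0
        t = np.arange(0, 60, 1 / rate)
        tr = np.zeros(t.size)
        tri = (t >= 20) & (t <= 30)
        tr[tri] = 2.0 * (1 - np.abs(t[tri] - 25.0) / 5.0)
        epoch = Epoch("warm1", start=15.0, end=40.0, plateau=34.0)
        sel = (t >= epoch.start) & (t <= epoch.end)
        auc = np.trapezoid(tr[sel], dx=1 / rate)
        assert auc == pytest.approx(0.5 * 10.0 * 2.0, rel=1e-3)
        assert np.trapezoid(np.zeros(sel.sum()), dx=1 / rate) == 0.0

    def test_zero_viable_cells_errors(self, recording):
        cfg, s, corrected, by_epoch = recording
        with pytest.raises(ValueError, match="viable"):
            ca.fov_stats(pd.DataFrame(columns=["cell", "stimulus", "responder", "warm_sensitive"]), 0, by_epoch, s.fset.epochs)

    def test_nonresponding_cells_excluded_from_table(self, recording, trained_classifier):
        cfg, s, corrected, by_epoch = recording
        clf, *_ = trained_classifier
        table = ca.build_responder_table(by_epoch, s.fset.epochs, clf)
        per_cell = table.groupby("cell")[["responder", "capsaicin", "kcl_viable"]].any()
        # every listed cell responded to at least one applied stimulus
        assert (per_cell["responder"] | per_cell["capsaicin"]).all()
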