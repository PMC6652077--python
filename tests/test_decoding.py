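"""Subwindow grid, FIR filtering, CV decoding, selection, chance threshold."""

import numpy as np
import pytest

from covertbci import (bandpass_fir, chance_threshold, decode_combined,
                       decode_subwindow, make_grid, select_subwindows)
from covertbci.decoding import (AccuracyMap, WindowDecoder, _balanced_folds,
                                _fir_kernel, accuracy_map, predict,
                                train_classifier)
from covertbci.epochs import EpochSet
from covertbci.simulate import SimulationConfig, generate_subject, null_config

from conftest import binomial_band, make_epochs


class TestGrid:
    def test_default_grid_has_138_tiles(self):
        g = make_grid((0, 1200), (4, 50), 200, 2)
        assert len(g) == 138 and g.n_time == 6 and g.n_freq == 23
        # exact non-overlapping cover in time-major order
        assert g.windows[0] == (0, 200, 4, 6)
        assert g.windows[22] == (0, 200, 48, 50)
        assert g.windows[-1] == (1000, 1200, 48, 50)
        assert len(set(g.windows)) == 138

    def test_single_tile(self):
        assert len(make_grid((0, 200), (4, 6), 200, 2)) == 1

    def test_non_dividing_step_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            make_grid((0, 1200), (4, 50), 250, 2)


class TestBandpassFIR:
    def test_band_center_sinusoid_preserved(self, rng):
        fs, f0 = 500.0, 11.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * f0 * t)
        ep = make_epochs(rng, n_trials=2, n_channels=4, n_samples=3000, fs=fs)
        ep.data[:] = x
        out = bandpass_fir(ep, 10, 12)
        core = slice(512, -512)
        rms_in = np.sqrt(np.mean(x[core] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 0, core] ** 2))
        assert rms_out == pytest.approx(rms_in, rel=0.05)

    def test_out_of_band_sinusoid_attenuated_20db(self, rng):
        fs = 500.0
        t = np.arange(3000) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        ep = make_epochs(rng, n_trials=1, n_channels=4, n_samples=3000, fs=fs)
        ep.data[:] = x
        out = bandpass_fir(ep, 20, 22)
        core = slice(512, -512)
        ratio = (np.sqrt(np.mean(out.data[0, 0, core] ** 2))
                 / np.sqrt(np.mean(x[core] ** 2)))
        assert 20 * np.log10(ratio) < -20

    def test_impulse_response_symmetric_linear_phase(self):
        taps = _fir_kernel(10, 12, 500.0, 512)
        assert taps.size == 513
        np.testing.assert_allclose(taps, taps[::-1], atol=1e-15)

    def test_band_above_nyquist_rejected(self, noise_epochs):
        with pytest.raises(ValueError, match="band"):
            bandpass_fir(noise_epochs, 200, 260)

    def test_zero_phase_no_delay(self, rng):
        # a burst at a known time stays centered after filtering
        fs = 500.0
        n = 3000
        ep = make_epochs(rng, n_trials=1, n_channels=4, n_samples=n, fs=fs)
        t = np.arange(n) / fs
        env = np.exp(-((t - 3.0) ** 2) / (2 * 0.1**2))
        ep.data[:] = env * np.sin(2 * np.pi * 11 * t)
        out = bandpass_fir(ep, 10, 12)
        assert abs(int(np.argmax(np.abs(out.data[0, 0])))
                   - int(np.argmax(np.abs(ep.data[0, 0])))) < 25


class TestChanceThreshold:
    def test_printed_threshold_for_ten_test_trials(self):
        assert chance_threshold(10, 0.05) == 0.75

    def test_exact_enumeration_small_n(self):
        # P(X >= 9 | Bin(10, .5)) ~ 0.0107 < 0.05, P(X >= 8) ~ 0.055
        assert chance_threshold(5, 0.05) == 0.9

    def test_threshold_approaches_half_for_large_n(self):
        assert chance_threshold(50000, 0.05) < 0.51

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            chance_threshold(0)
        with pytest.raises(ValueError):
            chance_threshold(10, 1.5)


class TestFolds:
    def test_per_class_balanced_folds(self, rng):
        labels = np.array(["yes"] * 100 + ["no"] * 100)
        folds = _balanced_folds(labels, 10, seed=0)
        assert len(folds) == 10
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(200))
        for f in folds:
            assert np.sum(labels[f] == "yes") == 10
            assert np.sum(labels[f] == "no") == 10

    def test_insufficient_class_count_rejected(self):
        labels = np.array(["yes"] * 5 + ["no"] * 50)
        with pytest.raises(ValueError, match="counts"):
            _balanced_folds(labels, 10, seed=0)


@pytest.fixture(scope="module")
def planted_subject():
    return generate_subject(SimulationConfig(n_trials_per_class=30, seed=31), 0)


class TestDecodeSubwindow:
    def test_result_aggregates_folds(self, planted_subject):
        res = decode_subwindow(planted_subject, (1000, 1200, 10, 12), seed=0)
        assert res.per_fold_accuracy.shape == (10,)
        assert res.mean_accuracy == pytest.approx(
            res.per_fold_accuracy.mean(), abs=1e-12)
        assert res.n_test_per_class == 3.0
        assert 0 <= res.sensitivity <= 1 and 0 <= res.specificity <= 1

    def test_seed_reproducibility(self, planted_subject):
        a = decode_subwindow(planted_subject, (1000, 1200, 10, 12), seed=7)
        b = decode_subwindow(planted_subject, (1000, 1200, 10, 12), seed=7)
        np.testing.assert_array_equal(a.per_fold_accuracy, b.per_fold_accuracy)

    def test_balanced_accuracy_identity(self, planted_subject):
        res = decode_subwindow(planted_subject, (1000, 1200, 10, 12), seed=0)
        # folds exactly balanced -> accuracy = (sens + spec) / 2
        assert res.mean_accuracy == pytest.approx(
            (res.sensitivity + res.specificity) / 2, abs=1e-9)

    def test_strong_no_only_oscillation_is_separable(self):
        from covertbci.simulate import EffectSpec

        eff = (EffectSpec((9.0, 12.0), (300.0, 1200.0),
                          "right_centroparietal", 30.0, 0.0),)
        cfg = SimulationConfig(n_subjects=2, n_trials_per_class=50, seed=32,
                               effects=eff)
        acc = np.mean([
            decode_subwindow(generate_subject(cfg, i), (1000, 1200, 10, 12),
                             seed=0).mean_accuracy
            for i in range(2)
        ])
        assert acc >= 0.95

    def test_no_leakage_on_null_data(self, rng):
        # many channels, few trials: an implementation that fits CSP on all
        # trials (test folds included) overfits far above chance here
        ep = make_epochs(rng, n_trials=40, n_channels=16, n_samples=200)
        res = decode_subwindow(ep, (-100, 300, 8, 10), seed=3)
        lo, hi = binomial_band(40, conf=0.999)
        assert lo <= res.mean_accuracy <= hi


class TestCombined:
    def test_single_window_matches_subwindow_contract(self):
        ep = generate_subject(SimulationConfig(n_trials_per_class=20, seed=33), 0)
        w = (1000, 1200, 10, 12)
        a = decode_subwindow(ep, w, seed=5)
        b = decode_combined(ep, [w], seed=5)
        np.testing.assert_array_equal(a.per_fold_accuracy, b.per_fold_accuracy)

    def test_empty_selection_rejected(self, noise_epochs):
        with pytest.raises(ValueError, match="at least one"):
            decode_combined(noise_epochs, [])

    def test_combined_feature_dimension_is_4_per_window(self):
        from covertbci.csp import CSP
        from covertbci.decoding import CLASS_ORDER, _window_block

        ep = generate_subject(SimulationConfig(n_trials_per_class=15, seed=34), 0)
        windows = [(1000, 1200, 10, 12), (800, 1000, 10, 12), (200, 400, 6, 8)]
        feats = []
        for w in windows:
            block = _window_block(ep, w, 512)
            feats.append(CSP(m=2, class_order=CLASS_ORDER)
                         .fit(block, ep.labels).transform(block))
        combined = np.hstack(feats)
        assert feats[0].shape[1] == 4
        assert combined.shape[1] == 12


class TestSelection:
    def _amap(self, means):
        g = make_grid((0, 1200), (4, 6), 200, 2)   # 6 windows
        per_subject = np.tile(means, (1, 1))
        return AccuracyMap(g, per_subject)

    def test_constant_map_selects_nothing(self):
        assert select_subwindows(self._amap(np.full(6, 0.7))) == []

    def test_single_spike_selected_alone(self):
        means = np.full(6, 0.6)
        means[3] = 0.99
        amap = self._amap(means)
        sel = select_subwindows(amap)
        assert sel == [amap.grid.windows[3]]

    def test_absolute_floor_applies(self):
        means = np.array([0.5, 0.5, 0.5, 0.5, 0.5, 0.74])
        amap = self._amap(means)
        assert select_subwindows(amap, floor=0.75) == []
        assert select_subwindows(amap, floor=0.70) == [amap.grid.windows[5]]


class TestClassifier:
    def test_separable_toy_set_fit(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array(["yes"] * 20 + ["no"] * 20)
        clf = train_classifier(X, y)
        assert np.mean(predict(clf, X) == y) == 1.0

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(ValueError, match="single class"):
            train_classifier(rng.standard_normal((10, 2)), ["yes"] * 10)

    def test_duplicated_training_set_consistent(self, rng):
        # well-separated classes: no active slack, so duplication cannot move
        # the decision boundary
        X = np.vstack([rng.normal(-3, 0.3, (15, 4)), rng.normal(3, 0.3, (15, 4))])
        y = np.array(["yes"] * 15 + ["no"] * 15)
        Xq = rng.standard_normal((10, 4))
        a = predict(train_classifier(X, y), Xq)
        b = predict(train_classifier(np.vstack([X, X]), np.concatenate([y, y])), Xq)
        np.testing.assert_array_equal(a, b)

    def test_shuffled_labels_decode_at_chance(self, rng):
        X = rng.standard_normal((200, 4))
        y = rng.permutation(np.array(["yes", "no"] * 100))
        clf = train_classifier(X[:150], y[:150])
        acc = np.mean(predict(clf, X[150:]) == y[150:])
        lo, hi = binomial_band(50, conf=0.999)
        assert lo <= acc <= hi


class TestAccuracyMap:
    def test_single_subject_single_window_matches_decode(self):
        ep = generate_subject(SimulationConfig(n_trials_per_class=15, seed=35), 0)
        g = make_grid((1000, 1200), (10, 12), 200, 2)
        amap = accuracy_map([ep], g, seed=4)
        assert amap.per_subject.shape == (1, 1)
        assert amap.mean[0] == amap.results[0][0].mean_accuracy
        assert 0 <= amap.mean[0] <= 1

    def test_null_subject_map_hovers_at_chance(self):
        cfg = null_config(SimulationConfig(n_trials_per_class=15, seed=36))
        ep = generate_subject(cfg, 0)
        g = make_grid((800, 1200), (8, 12), 200, 2)   # 4 windows
        amap = accuracy_map([ep], g, seed=4)
        lo, hi = binomial_band(30 * 4, conf=0.999)
        assert lo <= amap.mean.mean() <= hi
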