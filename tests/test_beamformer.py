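"""LCMV beamformer algebra, classification and channel selection."""

import numpy as np
import pandas as pd
import pytest

from opmbci.beamformer import (
    BeamformerModel,
    ChannelSelectionResult,
    build_pattern_and_covariance,
    classify_erp,
    classify_ssvep,
    crossval_erp,
    crossval_ssvep,
    greedy_forward_selection,
    score,
    ssvep_subset_scorer,
    train_beamformer,
    train_erp_model,
    train_ssvep_model,
)
from opmbci.containers import EpochSet, SensorLayout, TargetLayout


def kkt_lcmv(a, sigma):
    """Independent oracle: minimise v S v' s.t. a.v = 1 via the KKT system."""
    mn = a.size
    kkt = np.zeros((mn + 1, mn + 1))
    kkt[:mn, :mn] = 2.0 * sigma
    kkt[:mn, mn] = a
    kkt[mn, :mn] = a
    rhs = np.zeros(mn + 1)
    rhs[mn] = 1.0
    return np.linalg.solve(kkt, rhs)[:mn]


def _random_spd(rng, d, alpha=0.95):
    x = rng.normal(size=(4 * d, d))
    return alpha * np.cov(x, rowvar=False) + (1 - alpha) * np.eye(d)


class TestPatternAndCovariance:
    def test_alpha_zero_gives_identity(self):
        rng = np.random.default_rng(0)
        segs = rng.normal(size=(10, 2, 5))
        _, s_hat = build_pattern_and_covariance(segs, segs, alpha=0.0)
        np.testing.assert_allclose(s_hat, np.eye(10))

    def test_identical_segments(self):
        seg = np.arange(6.0).reshape(2, 3)
        segs = np.tile(seg, (7, 1, 1))
        a, s_hat = build_pattern_and_covariance(segs, segs, alpha=0.95)
        np.testing.assert_allclose(a, seg.ravel())  # channel-major
        np.testing.assert_allclose(s_hat, 0.05 * np.eye(6), atol=1e-12)

    def test_regularised_covariance_is_spd(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            segs = rng.normal(size=(rng.integers(3, 20), 2, 4))
            _, s_hat = build_pattern_and_covariance(segs, segs, alpha=0.95)
            np.testing.assert_allclose(s_hat, s_hat.T)
            assert np.linalg.eigvalsh(s_hat).min() >= 0.05 - 1e-9


class TestLcmvWeights:
    def test_identity_covariance_closed_form(self):
        a = np.array([1.0, 2.0, 2.0])
        w = train_beamformer(a, np.eye(3))
        np.testing.assert_allclose(w, a / 9.0)
        assert w @ (3.5 * a) == pytest.approx(3.5)

    def test_unit_gain_on_random_problems(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            d = rng.integers(2, 13)
            a = rng.normal(size=d)
            w = train_beamformer(a, _random_spd(rng, d))
            assert abs(a @ w - 1.0) < 1e-9

    def test_matches_constrained_minimizer(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            d = rng.integers(2, 13)
            a = rng.normal(size=d)
            sigma = _random_spd(rng, d)
            w = train_beamformer(a, sigma)
            v = kkt_lcmv(a, sigma)
            assert np.linalg.norm(w - v) / np.linalg.norm(v) < 1e-6
            # the oracle's variance is a true minimum
            assert w @ sigma @ w == pytest.approx(v @ sigma @ v, rel=1e-9)

    def test_alpha_one_equals_unregularized(self):
        rng = np.random.default_rng(4)
        d = 8
        a = rng.normal(size=d)
        sigma = _random_spd(rng, d, alpha=1.0) + 0.5 * np.eye(d)
        segs = None  # direct algebra below
        num = np.linalg.solve(sigma, a)
        w_direct = num / (a @ num)
        w = train_beamformer(a, sigma)
        assert np.linalg.norm(w - w_direct) / np.linalg.norm(w_direct) < 1e-6

    def test_zero_pattern_rejected(self):
        with pytest.raises(ValueError):
            train_beamformer(np.zeros(4), np.eye(4))


def _ssvep_toy_epochs(layout, target_layout, reps, amp, noise_sd, seed, fs=150.0,
                      n=600):
    """Directly constructed decoder-rate epochs (no continuous pipeline)."""
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    rows, data = [], []
    for rep in range(reps):
        for tg in range(9):
            f = target_layout.frequency_hz[tg]
            ph = target_layout.phase_rad[tg]
            osc = amp * np.cos(2 * np.pi * f * t + ph)
            gains = np.linspace(1.0, 0.2, layout.n_channels)
            x = np.outer(gains, osc) + rng.normal(size=(layout.n_channels, n)) * noise_sd
            data.append(x)
            rows.append((0, tg, float(f), float(ph)))
    labels = pd.DataFrame(rows, columns=["sample", "target", "frequency_hz",
                                         "phase_rad"])
    return EpochSet(data=np.stack(data), fs_hz=fs, t0_ms=0.0, labels=labels,
                    layout=layout)


class TestScoringAndClassification:
    def test_own_pattern_scores_unity(self, ssvep_model):
        # a one-segment epoch equal to the activation pattern must score
        # exactly 1 (unit-gain constraint), its negation exactly -1
        no_discard = BeamformerModel(
            paradigm="ssvep", targets=ssvep_model.targets,
            channel_names=ssvep_model.channel_names,
            fs_hz=ssvep_model.fs_hz, alpha=ssvep_model.alpha,
        )
        for i, tb in enumerate(ssvep_model.targets):
            epoch = tb.pattern.reshape(ssvep_model.n_channels, tb.n_samples)
            assert score(epoch, no_discard, i) == pytest.approx(1.0, abs=1e-9)
            assert score(-epoch, no_discard, i) == pytest.approx(-1.0, abs=1e-9)

    def test_score_is_linear(self, ssvep_model):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(ssvep_model.n_channels, 600))
        y = rng.normal(size=(ssvep_model.n_channels, 600))
        for i in (0, 4, 8):
            lhs = score(2.0 * x - 0.5 * y, ssvep_model, i)
            rhs = 2.0 * score(x, ssvep_model, i) - 0.5 * score(y, ssvep_model, i)
            assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_tiled_pattern_classified_as_its_target(self, ssvep_model):
        tb = ssvep_model.targets[3]
        pattern = tb.pattern.reshape(ssvep_model.n_channels, tb.n_samples)
        epoch = np.tile(pattern, (1, 600 // tb.n_samples + 1))[:, :600]
        pred, scores = classify_ssvep(epoch, ssvep_model)
        assert pred == 3

    def test_erp_pattern_candidate_wins(self, erp_epochs):
        model = train_erp_model(erp_epochs)
        a = model.targets[0].pattern.reshape(erp_epochs.n_channels, -1)
        labels = pd.DataFrame({
            "sample": np.zeros(9, int),
            "stimulated": np.arange(9),
            "cued": np.zeros(9, int),
        })
        data = np.zeros((9, erp_epochs.n_channels, erp_epochs.n_samples))
        data[6] = a
        trial = EpochSet(data=data, fs_hz=erp_epochs.fs_hz,
                         t0_ms=erp_epochs.t0_ms, labels=labels,
                         layout=erp_epochs.layout)
        pred, scores = classify_erp(trial, model, k_reps=1)
        assert pred == 6
        assert scores[6] == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_repetitions_raise(self, erp_epochs):
        model = train_erp_model(erp_epochs)
        one_trial = erp_epochs.select_epochs(
            erp_epochs.labels["trial"].to_numpy() == 0
        )
        with pytest.raises(ValueError, match="fewer than"):
            classify_erp(one_trial, model, k_reps=6)


class TestCrossValidation:
    def test_separable_data_reaches_100_percent(self, target_layout):
        layout = SensorLayout.grid(1, 3)
        ep = _ssvep_toy_epochs(layout, target_layout, reps=4, amp=5.0,
                               noise_sd=0.05, seed=0)
        _, acc = crossval_ssvep(ep, target_layout, k_folds=4, seed=0)
        assert acc == 1.0

    def test_confusion_total_equals_epoch_count(self, target_layout):
        layout = SensorLayout.grid(1, 3)
        ep = _ssvep_toy_epochs(layout, target_layout, reps=4, amp=1.0,
                               noise_sd=2.0, seed=1)
        cm, _ = crossval_ssvep(ep, target_layout, k_folds=4, seed=0)
        assert cm.n_predictions == ep.n_epochs

    def test_too_few_per_class_rejected(self, target_layout):
        layout = SensorLayout.grid(1, 3)
        ep = _ssvep_toy_epochs(layout, target_layout, reps=2, amp=1.0,
                               noise_sd=1.0, seed=2)
        with pytest.raises(ValueError, match="at least"):
            crossval_ssvep(ep, target_layout, k_folds=4)

    def test_erp_accuracy_grows_with_repetitions(self, noisy_erp_epochs):
        accs = [crossval_erp(noisy_erp_epochs, k_folds=5, k_reps=k, seed=0)[1]
                for k in (1, 3, 5)]
        assert accs[2] >= accs[0]
        assert accs[2] >= 0.8  # five repetitions decode reliably


class TestGreedySelection:
    def test_informative_channel_selected_first(self, target_layout):
        base = SensorLayout.grid(1, 4)
        for seed in range(3):
            ep = _ssvep_toy_epochs(base, target_layout, reps=4, amp=4.0,
                                   noise_sd=1.0, seed=10 + seed)
            # only channel 0 keeps its response; the rest become pure noise
            data = ep.data.copy()
            rng = np.random.default_rng(99 + seed)
            data[:, 1:] = rng.normal(size=data[:, 1:].shape)
            noisy = ep.copy_with(data=data)
            scorer = ssvep_subset_scorer(noisy, target_layout, k_folds=4, seed=0)
            sel = greedy_forward_selection(list(base.channel_names), scorer,
                                           max_channels=1)
            assert sel.selected[0] == base.channel_names[0]

    def test_perfect_score_terminates(self):
        sel = greedy_forward_selection(
            ["a", "b", "c"], lambda names: 1.0 if "b" in names else 0.5
        )
        assert sel.termination_reason == "perfect"
        assert sel.selected == ["b"]
        assert sel.accuracy_trace == [1.0]

    def test_stops_without_improvement_and_trace_increases(self):
        gains = {"a": 0.6, "b": 0.4, "c": 0.0}

        def scorer(names):
            return min(sum(gains[n] for n in names), 0.9)

        sel = greedy_forward_selection(["a", "b", "c"], scorer)
        assert sel.selected == ["a", "b"]
        assert sel.accuracy_trace == [0.6, 0.9]
        assert sel.termination_reason == "no_improvement"
        assert all(x < y for x, y in zip(sel.accuracy_trace, sel.accuracy_trace[1:]))

    def test_duplicate_selection_rejected(self):
        with pytest.raises(ValueError):
            ChannelSelectionResult(["a", "a"], [0.5, 0.6], "exhausted")


class TestModelRoundTrip:
    def test_json_serialization_preserves_weights(self, ssvep_model):
        clone = BeamformerModel.from_json(ssvep_model.to_json())
        assert clone.paradigm == "ssvep"
        assert clone.channel_names == ssvep_model.channel_names
        for a, b in zip(clone.targets, ssvep_model.targets):
            np.testing.assert_allclose(a.weights, b.weights)
            np.testing.assert_allclose(a.pattern, b.pattern)
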