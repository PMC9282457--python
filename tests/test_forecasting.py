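"""Feature layouts, windowing, patient-level splits and the LSTM."""

import numpy as np
import pytest

from daymark import (
    FEATURE_SETS,
    LSTMClassifier,
    LSTMConfig,
    build_feature_rows,
    make_samples,
    predict,
    roc_auc,
    split_patients,
    train_forecaster,
)
from daymark.data import build_day_grid
from daymark.events import LabelSet
from daymark.forecasting import ForecastSample, pad_windows

from conftest import toy_tables


def _panel(answers_by_day):
    days = list(range(len(answers_by_day)))
    statuses = ["no_alcohol"] * len(days)
    q, s = toy_tables(days, answers_by_day, statuses)
    return build_day_grid(q, s, "p1")


class TestFeatureRows:
    def test_raw22_full_day(self):
        from daymark.coding import QUESTIONS

        panel = _panel([{q: 100 for q in QUESTIONS}])
        rows = build_feature_rows(panel, None, "raw22")
        np.testing.assert_allclose(rows[0, :11], 1.0)
        np.testing.assert_allclose(rows[0, 11:], 1.0)

    def test_raw22_silent_day_all_zero(self):
        panel = _panel([{"Sleep": 50}, {}])
        rows = build_feature_rows(panel, None, "raw22")
        np.testing.assert_allclose(rows[1], 0.0)

    def test_avg4_motsc_only_day(self):
        panel = _panel([{"Motivation": 100, "SelfConf": 50}])
        rows = build_feature_rows(panel, None, "avg4")
        np.testing.assert_allclose(rows[0], [0.75, 1.0, 0.0, 0.0])

    def test_biomarker2_requires_series(self):
        panel = _panel([{"Sleep": 50}])
        with pytest.raises(ValueError, match="biomarker2"):
            build_feature_rows(panel, None, "biomarker2")

    def test_feature_widths(self):
        panel = _panel([{"Sleep": 50}])
        for name, spec in FEATURE_SETS.items():
            if name == "biomarker2":
                continue
            assert build_feature_rows(panel, None, spec).shape == (1, spec.n_features)


def _labelset(n, positives=(), undefined_tail=0):
    labels = np.zeros(n, dtype=int)
    labels[list(positives)] = 1
    defined = np.ones(n, dtype=bool)
    if undefined_tail:
        defined[-undefined_tail:] = False
    return LabelSet(look_ahead=(1, 3), labels=labels, defined=defined)


class TestSamples:
    def test_insufficient_history_skipped(self):
        feats = np.ones((10, 2))
        ls = _labelset(10)
        eligible = np.zeros(10, dtype=bool)
        eligible[5] = True
        assert make_samples(feats, ls, eligible) == []

    def test_minimum_history_boundary(self):
        feats = np.arange(20, dtype=float).reshape(10, 2)
        ls = _labelset(10)
        eligible = np.ones(10, dtype=bool)
        samples = make_samples(feats, ls, eligible)
        assert [s.t for s in samples] == list(range(6, 10))
        assert len(samples[0].window) == 7

    def test_long_history_truncated_to_max(self):
        feats = np.arange(101, dtype=float)[:, None]
        ls = _labelset(101)
        eligible = np.zeros(101, dtype=bool)
        eligible[100] = True
        (s,) = make_samples(feats, ls, eligible)
        assert len(s.window) == 93
        assert s.window[-1, 0] == 100 and s.window[0, 0] == 8

    def test_no_temporal_leakage(self):
        """Every feature row in a window is dated at or before the anchor."""
        feats = np.arange(50, dtype=float)[:, None]  # feature value == day
        ls = _labelset(50)
        eligible = np.ones(50, dtype=bool)
        for s in make_samples(feats, ls, eligible):
            assert s.window.max() == s.t

    def test_all_ineligible_patient(self):
        feats = np.ones((30, 2))
        assert make_samples(feats, _labelset(30), np.zeros(30, dtype=bool)) == []

    def test_padding_mask_layout(self):
        samples = [
            ForecastSample("p", 9, np.ones((10, 2)), 1),
            ForecastSample("p", 6, np.ones((7, 2)), 0),
        ]
        X, mask, y = pad_windows(samples, max_hist=12)
        assert X.shape == (2, 12, 2)
        assert mask[0].tolist() == [0, 0] + [1] * 10
        assert mask[1].tolist() == [0] * 5 + [1] * 7
        assert y.tolist() == [1, 0]


class TestSplit:
    def test_counts_mode_exact_sizes(self):
        ids = [f"p{i}" for i in range(751)]
        part = split_patients(ids, seed=1, counts=(527, 112, 112))
        sizes = {p: sum(v == p for v in part.values()) for p in set(part.values())}
        assert sizes == {"train": 527, "validation": 112, "test": 112}

    def test_deterministic_given_seed(self):
        ids = [f"p{i}" for i in range(40)]
        assert split_patients(ids, seed=3) == split_patients(ids, seed=3)
        assert split_patients(ids, seed=3) != split_patients(ids, seed=4)

    def test_partitions_disjoint_and_exhaustive(self):
        ids = [f"p{i}" for i in range(101)]
        part = split_patients(ids, seed=0)
        assert set(part) == set(ids)  # every patient in exactly one partition

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_patients(["a", "b", "c"], fractions=(0.5, 0.2, 0.2))


def _toy_sequences(n, seed, signal=True):
    """Sequences whose mean level determines the label when signal=True."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        y = int(rng.random() < 0.4)
        level = (0.7 if y else 0.3) if signal else 0.5
        L = int(rng.integers(7, 20))
        w = np.clip(rng.normal(level, 0.1, size=(L, 2)), 0, 1)
        samples.append(ForecastSample(f"p{i}", L - 1, w, y))
    return samples


class TestLSTM:
    def test_gradients_match_finite_differences(self):
        cfg = LSTMConfig(n_features=2, hidden=4, dropout=0.0, seed=3, dtype="float64")
        model = LSTMClassifier(cfg)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 6, 2))
        mask = np.ones((5, 6))
        mask[0, :3] = 0
        y = np.array([0, 1, 1, 0, 1.0])
        w = np.ones(5)
        p, cache = model.forward(X, mask)
        grads = model.backward(cache, y, w)
        eps = 1e-6
        for k in ("Wx", "Wh", "b", "w_out"):
            P = getattr(model, k)
            it = np.nditer(P, flags=["multi_index"])
            for _ in range(min(P.size, 10)):
                ix = it.multi_index
                old = P[ix]
                P[ix] = old + eps
                l1 = model.loss(model.forward(X, mask)[0], y, w)
                P[ix] = old - eps
                l2 = model.loss(model.forward(X, mask)[0], y, w)
                P[ix] = old
                assert abs((l1 - l2) / (2 * eps) - grads[k][ix]) < 1e-7
                it.iternext()

    def test_learns_separable_sequences(self):
        train = _toy_sequences(400, seed=1)
        val = _toy_sequences(100, seed=2)
        cfg = LSTMConfig(n_features=2, hidden=8, max_epochs=50, patience=10, seed=0)
        model = train_forecaster(train, val, cfg, max_hist=20)
        probs = predict(model, train, max_hist=20)
        assert roc_auc(probs, [s.label for s in train]) > 0.95

    def test_training_deterministic_for_seed(self):
        train = _toy_sequences(100, seed=1)
        val = _toy_sequences(40, seed=2)
        cfg = LSTMConfig(n_features=2, hidden=4, max_epochs=3, seed=9)
        m1 = train_forecaster(train, val, cfg, max_hist=20)
        m2 = train_forecaster(train, val, cfg, max_hist=20)
        np.testing.assert_array_equal(m1.Wx, m2.Wx)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)

    def test_single_class_training_rejected(self):
        train = [s for s in _toy_sequences(50, seed=1) if s.label == 1]
        val = _toy_sequences(20, seed=2)
        cfg = LSTMConfig(n_features=2, hidden=4, max_epochs=2, seed=0)
        with pytest.raises(ValueError, match="single class"):
            train_forecaster(train, val, cfg, max_hist=20)

    def test_predict_contracts(self):
        train = _toy_sequences(100, seed=1)
        val = _toy_sequences(40, seed=2)
        cfg = LSTMConfig(n_features=2, hidden=4, max_epochs=2, seed=0)
        model = train_forecaster(train, val, cfg, max_hist=20)
        probs = predict(model, val, max_hist=20)
        assert np.all((probs >= 0) & (probs <= 1))
        dup = predict(model, [val[0], val[0]], max_hist=20)
        assert dup[0] == dup[1]
        assert predict(model, [], max_hist=20).size == 0
        bad = [ForecastSample("p", 8, np.ones((9, 5)), 0)]
        with pytest.raises(ValueError, match="features"):
            predict(model, bad, max_hist=20)
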