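"""Neural net mechanics and the ML-predictor pipeline pieces."""

import itertools

import numpy as np
import pandas as pd
import pytest

from lobesia.core import FlightPeak
from lobesia.ml import (
    PUBLISHED_BEST_CONFIG,
    LabeledDataset,
    SearchSpace,
    WindowSet,
    balance_dataset,
    build_dataset,
    feature_groups,
    peaks_from_probabilities,
    predict_peak_doys,
    rank_relevance,
    search_and_train,
    split_by_group,
)
from lobesia.nn import FeedForwardNet, LayerSpec


def _toy_window_sets(n_groups=10, n_days=60, seed=0, peak_feature=True):
    """Window sets where column 0 spikes on the (known) peak day."""
    rng = np.random.default_rng(seed)
    sets, peaks = [], []
    names = ["sig_d1", "noise_d1", "longitude", "latitude"]
    for i in range(n_groups):
        doys = np.arange(100, 100 + n_days)
        peak = int(rng.integers(100, 100 + n_days))
        X = rng.normal(0, 1, (n_days, 4))
        if peak_feature:
            X[:, 0] = -1.0
            X[doys == peak, 0] = 3.0
        sets.append(WindowSet(f"s{i}", 2009, X, doys, names))
        peaks.append(FlightPeak(f"s{i}", 2009, 1, peak))
    return sets, peaks


class TestNet:
    def test_published_architecture_is_buildable(self):
        net = FeedForwardNet(100, list(PUBLISHED_BEST_CONFIG.layers), seed=0)
        assert [(l.units, l.activation) for l in net.layers] == [
            (96, "linear"),
            (336, "selu"),
            (64, "linear"),
            (144, "selu"),
        ]
        probs = net.predict_proba(np.random.default_rng(0).normal(size=(5, 100)))
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_probabilities_bounded_for_every_activation(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 3, (20, 7))
        for act in ("linear", "selu", "tanh", "softmax"):
            net = FeedForwardNet(7, [LayerSpec(6, act), LayerSpec(4, act)], seed=2)
            p = net.predict_proba(X)
            assert ((p >= 0) & (p <= 1)).all()

    def test_overfits_separable_toy_problem(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (80, 5))
        y = (X[:, 0] > 0).astype(float)
        net = FeedForwardNet(5, [LayerSpec(16, "tanh")], seed=0)
        net.fit(X, y, X, y, learning_rate=1e-2, optimizer="adam", max_epochs=300, min_delta=0.0, patience=50)
        assert np.mean((net.predict_proba(X) > 0.5) == (y > 0.5)) == 1.0

    def test_training_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X = rng.normal(0, 1, (50, 4))
        y = (X[:, 1] > 0).astype(float)
        outs = []
        for _ in range(2):
            net = FeedForwardNet(4, [LayerSpec(8, "selu")], seed=7)
            net.fit(X, y, X, y, max_epochs=30, seed=7)
            outs.append(net.predict_proba(X))
        assert np.array_equal(outs[0], outs[1])

    def test_early_stopping_restores_best_weights(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (60, 3))
        y = rng.integers(0, 2, 60).astype(float)
        net = FeedForwardNet(3, [LayerSpec(4, "tanh")], seed=1)
        result = net.fit(X, y, X, y, max_epochs=100, patience=5, min_delta=0.5)
        assert result.epochs_run <= 100
        val = net._bce(net.predict_proba(X), y)
        assert val == pytest.approx(result.best_val_loss, abs=1e-9)


class TestDatasetAssembly:
    def test_labels_and_counts(self):
        sets, peaks = _toy_window_sets(n_groups=2)
        ds = build_dataset(sets, peaks)
        assert len(ds) == 120
        assert ds.y.sum() == 2  # one positive per site-season
        assert ds.feature_names == sets[0].feature_names

    def test_no_peaks_means_all_negative(self):
        sets, _ = _toy_window_sets(n_groups=2)
        ds = build_dataset(sets, [])
        assert ds.y.sum() == 0

    def test_duplicate_anchor_windows_rejected(self):
        sets, peaks = _toy_window_sets(n_groups=1)
        ws = sets[0]
        dup = WindowSet(ws.site_id, ws.season, np.vstack([ws.X, ws.X[:1]]),
                        np.append(ws.anchor_doys, ws.anchor_doys[0]), ws.feature_names)
        with pytest.raises(ValueError, match="duplicate anchor"):
            build_dataset([dup], peaks)

    def test_balance_oversamples_to_ratio(self):
        sets, peaks = _toy_window_sets(n_groups=4, n_days=50)
        ds = build_dataset(sets, peaks)  # 4 pos / 196 neg
        out = balance_dataset(ds, ratio=3.0, seed=0)
        n_pos = int(out.y.sum())
        assert n_pos == int(np.ceil(196 / 3.0))
        assert (out.y <= 0.5).sum() == 196  # no negatives discarded

    def test_balance_identity_when_already_balanced(self):
        sets, peaks = _toy_window_sets(n_groups=2, n_days=4)
        ds = build_dataset(sets, peaks)
        out = balance_dataset(ds, ratio=3.0, seed=0)
        assert len(out) == len(ds)

    def test_balance_deterministic(self):
        sets, peaks = _toy_window_sets(n_groups=4)
        ds = build_dataset(sets, peaks)
        a = balance_dataset(ds, seed=5)
        b = balance_dataset(ds, seed=5)
        assert np.array_equal(a.X, b.X)

    def test_single_class_balance_rejected(self):
        sets, _ = _toy_window_sets(n_groups=2)
        ds = build_dataset(sets, [])
        with pytest.raises(ValueError, match="both classes"):
            balance_dataset(ds)


class TestSplit:
    def test_fraction_partition_10_groups(self):
        sets, peaks = _toy_window_sets(n_groups=10)
        ds = build_dataset(sets, peaks)
        split = split_by_group(ds, (0.8, 0.1, 0.1), seed=0)
        assert (len(split.train), len(split.validation), len(split.test)) == (8, 1, 1)

    def test_no_group_leakage(self):
        sets, peaks = _toy_window_sets(n_groups=12)
        ds = build_dataset(sets, peaks)
        split = split_by_group(ds, seed=3)
        parts = [set(split.train), set(split.validation), set(split.test)]
        for a, b in itertools.combinations(parts, 2):
            assert not (a & b)

    def test_split_invariant_to_row_order(self):
        sets, peaks = _toy_window_sets(n_groups=8)
        ds = build_dataset(sets, peaks)
        perm = np.random.default_rng(0).permutation(len(ds))
        shuffled = ds.subset(perm)
        assert split_by_group(ds, seed=9) == split_by_group(shuffled, seed=9)

    def test_too_few_groups_rejected(self):
        sets, peaks = _toy_window_sets(n_groups=2)
        ds = build_dataset(sets, peaks)
        with pytest.raises(ValueError, match="at least 3"):
            split_by_group(ds)


class TestPeakExtraction:
    def test_three_bumps_match_bruteforce_span_search(self):
        doys = np.arange(100, 220)
        probs = np.zeros(len(doys))
        for centre, height in ((115, 0.9), (160, 0.8), (205, 0.7)):
            probs += height * np.exp(-0.5 * ((doys - centre) / 4.0) ** 2)

        # oracle: best triple of days pairwise >= 28 days apart, by summed prob
        best, best_score = None, -1.0
        for triple in itertools.combinations(range(0, len(doys), 5), 3):
            days = [int(doys[i]) for i in triple]
            if all(abs(a - b) >= 28 for a, b in itertools.combinations(days, 2)):
                score = sum(probs[i] for i in triple)
                if score > best_score:
                    best, best_score = days, score
        assert peaks_from_probabilities(probs, doys) == sorted(best) == [115, 160, 205]

    def test_flat_probabilities_tie_break_earliest(self):
        doys = np.arange(100, 200)
        out = peaks_from_probabilities(np.full(100, 0.5), doys)
        assert out == [100, 128, 156]

    def test_fewer_days_than_spans(self):
        doys = np.arange(100, 120)
        out = peaks_from_probabilities(np.linspace(0, 1, 20), doys)
        assert out == [119]


class TestSearchAndRelevance:
    def _searched(self, seed=0, n_trials=3):
        sets, peaks = _toy_window_sets(n_groups=10, n_days=60, seed=1)
        ds = build_dataset(sets, peaks)
        split = split_by_group(ds, (0.6, 0.2, 0.2), seed=seed)
        space = SearchSpace(
            n_layers=(1, 2),
            intermediate_units=(8, 16),
            last_two_units=(8, 16),
            activations=("tanh", "selu"),
            learning_rates=(1e-2,),
            optimizers=("adam",),
            max_epochs=60,
        )
        return ds, split, search_and_train(ds, split, space, n_trials=n_trials, seed=seed)

    def test_search_reproducible_and_logged(self):
        _, _, a = self._searched(seed=4)
        _, _, b = self._searched(seed=4)
        assert a.best_trial == b.best_trial
        assert len(a.trials) == 3
        pd.testing.assert_frame_equal(a.trials, b.trials)

    def test_fixed_config_builds_requested_architecture(self):
        sets, peaks = _toy_window_sets(n_groups=10, n_days=40, seed=2)
        ds = build_dataset(sets, peaks)
        split = split_by_group(ds, (0.6, 0.2, 0.2), seed=0)
        space = SearchSpace(max_epochs=5)
        result = search_and_train(
            ds, split, space, n_trials=1, seed=0, fixed_config=PUBLISHED_BEST_CONFIG
        )
        assert [(l.units, l.activation) for l in result.best.config.layers] == [
            (96, "linear"),
            (336, "selu"),
            (64, "linear"),
            (144, "selu"),
        ]

    def test_feature_signature_enforced_at_predict_time(self):
        ds, split, result = self._searched()
        with pytest.raises(ValueError, match="signature"):
            result.best.predict_proba(ds.X, feature_names=["wrong"] * ds.X.shape[1])

    def test_model_round_trips_through_disk(self, tmp_path):
        ds, split, result = self._searched()
        result.best.save(tmp_path / "model")
        loaded = type(result.best).load(tmp_path / "model")
        assert np.allclose(loaded.predict_proba(ds.X), result.best.predict_proba(ds.X))
        assert loaded.feature_names == result.best.feature_names

    def test_relevance_ranks_signal_feature_first(self):
        ds, split, result = self._searched(n_trials=4)
        val = ds.subset(split.mask(ds, "validation"))
        ranking = rank_relevance(result.best, val, list(split.validation), seed=0, k=5)
        assert ranking["feature_group"].iloc[0] == "sig"
        statics = ranking.set_index("feature_group")["importance"]
        assert statics["noise"] <= ranking["importance"].iloc[0]

    def test_grouping_collapses_lags(self):
        groups = feature_groups(["TM_d1", "TM_d2", "rh_d1", "longitude"])
        assert groups == {"TM": [0, 1], "rh": [2], "longitude": [3]}
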