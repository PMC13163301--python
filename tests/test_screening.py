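"""Three-track screening: prevalence filter, the individual tracks with
uncontaminated planted outcomes, vote combination, redundancy pruning,
node freezing, and validation AUC."""

import numpy as np
import pandas as pd
import pytest

from distressnet.datatypes import ItemResponseMatrix
from distressnet.screening import (
    ScreeningConfig,
    combine_tracks,
    leave_one_out_totals,
    prevalence_filter,
    redundancy_prune,
    screen_nodes,
    track_cv_lasso,
    track_repeated_logistic,
    track_spearman,
    validate_nodes,
)
from distressnet.synthetic import make_screening_benchmark


def ordinal_items(values: np.ndarray, dims=None) -> ItemResponseMatrix:
    cols = [f"TA{k+1}" for k in range(values.shape[1])]
    labels = dims or {c: "TA" for c in cols}
    return ItemResponseMatrix(pd.DataFrame(values, columns=cols), labels)


class TestPrevalenceFilter:
    def test_boundary_rate_is_excluded(self):
        vals = np.zeros((10, 2))
        vals[:5, 0] = 2  # rate exactly 0.50 -> excluded (strict >)
        vals[:6, 1] = 2  # rate 0.60 -> retained
        items = ordinal_items(vals)
        assert prevalence_filter(items, threshold=2, min_rate=0.5) == ["TA2"]

    def test_all_saturated_items_retained(self):
        items = ordinal_items(np.full((8, 3), 4.0))
        assert len(prevalence_filter(items)) == 3

    def test_vigor_items_are_never_candidates(self):
        vals = np.full((8, 2), 4.0)
        items = ItemResponseMatrix(
            pd.DataFrame(vals, columns=["TA1", "V1"]), {"TA1": "TA", "V1": "V"}
        )
        assert prevalence_filter(items) == ["TA1"]

    def test_empty_candidates_raise_with_rates(self):
        items = ordinal_items(np.zeros((8, 2)))
        with pytest.raises(ValueError, match="rates"):
            prevalence_filter(items)

    def test_calibrated_cohort_retains_moderate_prevalence_item(self):
        # AH2-like item (positive rate ~0.66) must survive the 50% filter
        items, signal, _ = make_screening_benchmark(1000, seed=0)
        assert "AH2" in prevalence_filter(items)


class TestTrackSpearman:
    def test_thresholds_are_conjunctive(self, rng):
        n = 600
        core = rng.normal(size=n)
        strong = np.clip(np.round(2 + 1.2 * core + 0.9 * rng.normal(size=n)), 0, 4)
        weak_assoc = np.clip(np.round(2.5 + 0.1 * core + rng.normal(size=n)), 0, 4)
        df = pd.DataFrame({"strong": strong, "weak": weak_assoc})
        sel = track_spearman(df, pd.Series(core), rho_min=0.3, rate_min=0.5)
        assert sel == {"strong"}

    def test_independent_item_rarely_selected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            core = rng.normal(size=2000)
            item = np.clip(np.round(2 + rng.normal(size=2000)), 0, 4)
            sel = track_spearman(
                pd.DataFrame({"x": item}), pd.Series(core), 0.3, 0.5
            )
            hits += bool(sel)
        assert hits <= 1

    def test_constant_core_raises(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3, 4]})
        with pytest.raises(ValueError, match="constant core"):
            track_spearman(df, pd.Series(np.ones(5)), 0.3, 0.5)


class TestTrackCvLasso:
    def test_zero_outcome_selects_nothing(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (100, 5)).astype(float))
        assert track_cv_lasso(df, np.zeros(100), folds=5, seed=0) == set()

    def test_planted_signal_item_selected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                rng.integers(0, 5, (300, 6)).astype(float),
                columns=[f"x{k}" for k in range(6)],
            )
            y = df["x2"] + 0.05 * rng.normal(size=300)
            if "x2" in track_cv_lasso(df, y, folds=10, seed=seed):
                hits += 1
        assert hits >= 9

    def test_determinism(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (150, 5)).astype(float))
        y = df.sum(axis=1) + rng.normal(size=150)
        assert track_cv_lasso(df, y, seed=4) == track_cv_lasso(df, y, seed=4)

    def test_too_many_folds_raise(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (8, 3)).astype(float))
        with pytest.raises(ValueError, match="folds"):
            track_cv_lasso(df, np.ones(8), folds=10)


class TestTrackRepeatedLogistic:
    def test_pure_noise_item_falls_below_frequency_cut(self):
        failures = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 1000
            signal = np.clip(np.round(2 + rng.normal(size=(n, 3))), 0, 4)
            y = (signal.sum(axis=1) + rng.normal(size=n) > 6).astype(int)
            noise = np.clip(np.round(2 + rng.normal(size=n)), 0, 4)
            df = pd.DataFrame(
                np.column_stack([signal, noise]), columns=["a", "b", "c", "noise"]
            )
            _, freqs = track_repeated_logistic(
                df, y, reps=20, folds=5, select_frac=0.6, seed=seed
            )
            failures += freqs["noise"] >= 0.6
        assert failures <= 1

    def test_single_rep_frequency_is_binary(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (80, 4)).astype(float))
        y = (df.sum(axis=1) > df.sum(axis=1).median()).astype(int)
        _, freqs = track_repeated_logistic(df, y, reps=1, folds=5, seed=0)
        assert set(freqs.values()) <= {0.0, 1.0}

    def test_boundary_frequency_retained(self):
        # the >= comparison keeps an item at exactly the selection fraction
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.integers(0, 5, (120, 3)).astype(float))
        y = (df.iloc[:, 0] + 0.3 * rng.normal(size=120) > 2).astype(int)
        selected, freqs = track_repeated_logistic(
            df, y, reps=5, folds=5, select_frac=0.0, seed=1
        )
        assert {c for c, f in freqs.items() if f >= 0.0} == selected

    def test_single_class_outcome_raises(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (50, 3)).astype(float))
        with pytest.raises(ValueError, match="2 classes"):
            track_repeated_logistic(df, np.ones(50), reps=1)


class TestCombineTracks:
    def test_vote_arithmetic(self):
        retained, votes = combine_tracks({"a"}, {"b", "c"}, {"c"}, (1, 2, 2), 3)
        assert votes == {"a": 1, "b": 2, "c": 4}
        assert retained == {"c"}

    def test_b_and_c_suffice_but_a_alone_does_not(self):
        retained, _ = combine_tracks({"x"}, {"y"}, {"y"}, (1, 2, 2), 3)
        assert retained == {"y"}

    def test_all_three_tracks(self):
        retained, votes = combine_tracks({"z"}, {"z"}, {"z"}, (1, 2, 2), 3)
        assert votes["z"] == 5 and retained == {"z"}

    def test_raising_vote_min_never_enlarges(self):
        a, b, c = {"p", "q"}, {"q", "r"}, {"r", "s"}
        prev = None
        for vote_min in (1, 2, 3, 4, 5):
            retained, _ = combine_tracks(a, b, c, (1, 2, 2), vote_min)
            if prev is not None:
                assert retained <= prev
            prev = retained

    def test_nonpositive_weights_raise(self):
        with pytest.raises(ValueError):
            combine_tracks(set(), set(), set(), (0, 2, 2), 3)


class TestRedundancyPrune:
    def test_duplicate_column_keeps_exactly_one(self, rng):
        x = rng.integers(0, 5, 200).astype(float)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.integers(0, 5, 200).astype(float)})
        core = pd.Series(rng.normal(size=200))
        kept, pruned = redundancy_prune(df, {"a", "b", "c"}, core)
        assert len([k for k in kept if k in ("a", "b")]) == 1
        assert len(pruned) == 1

    def test_no_offending_pair_is_noop(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (300, 4)).astype(float))
        df.columns = list("abcd")
        core = pd.Series(rng.normal(size=300))
        kept, pruned = redundancy_prune(df, set("abcd"), core)
        assert set(kept) == set("abcd") and pruned == []

    def test_three_way_duplicates_leave_one_survivor(self, rng):
        x = rng.integers(0, 5, 150).astype(float)
        df = pd.DataFrame({"a": x, "b": x, "c": x})
        core = pd.Series(rng.normal(size=150))
        kept, pruned = redundancy_prune(df, {"a", "b", "c"}, core)
        assert len(kept) == 1 and len(pruned) == 2

    def test_empty_retained_raises(self, rng):
        df = pd.DataFrame(rng.integers(0, 5, (20, 2)).astype(float))
        with pytest.raises(ValueError):
            redundancy_prune(df, set(), pd.Series(np.zeros(20)))


class TestValidateNodes:
    def test_perfect_ranking_gives_auc_one(self):
        items, _, _ = make_screening_benchmark(200, seed=1)
        # score equals the outcome's own total -> perfect discrimination
        frozen = items.item_ids
        auc, table = validate_nodes(frozen, items)
        assert auc == 1.0
        assert len(table) == len(frozen)

    def test_independent_score_near_half(self):
        rng = np.random.default_rng(2)
        n = 2000
        vals = np.clip(np.round(2 + rng.normal(size=(n, 6))), 0, 4)
        cols = ["TA1", "TA2", "DD1", "DD2", "FI1", "V1"]
        items = ItemResponseMatrix(
            pd.DataFrame(vals, columns=cols), {c: c[:2] for c in cols}
        )
        # the vigor item is independent of the (negative-item) distress
        # outcome, so its sum score cannot discriminate
        auc, _ = validate_nodes(["V1"], items)
        assert abs(auc - 0.5) < 0.05

    def test_consistency_table_one_row_per_node(self):
        items, signal, _ = make_screening_benchmark(150, seed=3)
        _, table = validate_nodes(signal[:5], items)
        assert list(table.index) == signal[:5]
        assert {"mean", "positive_rate"} <= set(table.columns)


class TestScreenNodes:
    def test_planted_signal_recovery_single_seed(self):
        items, signal, _ = make_screening_benchmark(290, seed=42)
        result = screen_nodes(items, ScreeningConfig(reps=10, seed=42))
        retained_signal = [s for s in signal if s in result.frozen_nodes]
        assert len(retained_signal) >= 14
        assert set(result.frozen_nodes) <= set(result.candidates)
        assert set(result.votes) == set(result.candidates)

    def test_determinism(self):
        items, _, _ = make_screening_benchmark(200, seed=8)
        cfg = ScreeningConfig(reps=5, seed=8)
        a = screen_nodes(items, cfg)
        b = screen_nodes(items, cfg)
        assert a.frozen_nodes == b.frozen_nodes
        assert a.votes == b.votes
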