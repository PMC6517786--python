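import numpy as np
import pandas as pd
import pytest

from labelamp.aggregation import (
    RaterWeightModel,
    amplify_labels,
    build_design_matrix,
    equal_weight_scores,
    fit_weighted_aggregator,
    split_gold,
    training_size_sweep,
)
from labelamp.metrics import auc_mann_whitney

from conftest import simulate_gold_campaign

FAST_FIT = dict(n_estimators=60, depth_grid=(2,), lr_grid=(0.1,), cv_folds=3)


def events_from(rows):
    return pd.DataFrame(
        [
            {"rater_id": r, "slice_id": s, "rating": v, "timestamp": t}
            for t, (r, s, v) in enumerate(rows)
        ]
    )


class TestDesignMatrix:
    def test_repeat_ratings_average(self):
        ev = events_from([("a", "s1", 1), ("a", "s1", 1), ("a", "s1", 0)])
        d = build_design_matrix(ev)
        assert np.isclose(d.loc["s1", "a"], 2 / 3)

    def test_unrated_pair_is_missing_not_zero(self):
        ev = events_from([("a", "s1", 1), ("b", "s2", 0)])
        d = build_design_matrix(ev)
        assert np.isnan(d.loc["s1", "b"])
        assert d.loc["s2", "b"] == 0.0

    def test_matches_bruteforce_groupby(self, rng):
        rows = [
            (f"r{rng.integers(6)}", f"s{rng.integers(15)}", int(rng.integers(2)))
            for _ in range(400)
        ]
        ev = events_from(rows)
        d = build_design_matrix(ev)
        for (r, s, _) in rows[:50]:
            vals = [v for rr, ss, v in rows if rr == r and ss == s]
            assert np.isclose(d.loc[s, r], np.mean(vals))

    def test_restriction_to_retained_raters(self):
        ev = events_from([("a", "s1", 1), ("b", "s1", 0)])
        d = build_design_matrix(ev, raters={"a"})
        assert list(d.columns) == ["a"]


class TestEqualWeight:
    def test_simple_disagreement_averages_to_half(self):
        ev = events_from([("a", "s1", 1), ("b", "s1", 0)])
        assert equal_weight_scores(ev)["s1"] == 0.5

    def test_rater_first_convention(self):
        # a rates s1 twice pass, b once fail: rater-first = mean(1, 0) = 0.5
        ev = events_from([("a", "s1", 1), ("a", "s1", 1), ("b", "s1", 0)])
        assert equal_weight_scores(ev)["s1"] == 0.5
        assert np.isclose(equal_weight_scores(ev, rater_first=False)["s1"], 2 / 3)

    def test_unanimous_pass_scores_one(self):
        ev = events_from([("a", "s1", 1), ("b", "s1", 1), ("a", "s2", 1)])
        assert (equal_weight_scores(ev) == 1.0).all()


class TestWeightedAggregator:
    def test_single_perfect_rater_separates_training_set(self):
        labels = pd.Series([1, 0] * 10, index=[f"s{i}" for i in range(20)])
        ev = events_from(
            [("a", f"s{i}", int(labels[f"s{i}"])) for i in range(20)]
        )
        design = build_design_matrix(ev)
        fit = fit_weighted_aggregator(design, labels.loc[design.index], **FAST_FIT)
        auc = auc_mann_whitney(fit.predict_scores(design), labels.loc[design.index])
        assert auc == 1.0

    def test_single_class_gold_rejected(self):
        ev = events_from([("a", "s1", 1), ("a", "s2", 1)])
        design = build_design_matrix(ev)
        with pytest.raises(ValueError):
            RaterWeightModel(design, pd.Series([1, 1], index=design.index))

    def test_fold_reduction_warns(self):
        labels = pd.Series([1, 1, 1, 0, 0, 0], index=[f"s{i}" for i in range(6)])
        ev = events_from([("a", f"s{i}", int(labels.iloc[i])) for i in range(6)])
        design = build_design_matrix(ev)
        with pytest.warns(UserWarning, match="reducing CV folds"):
            fit_weighted_aggregator(
                design, labels.loc[design.index], n_estimators=20, cv_folds=10,
                depth_grid=(2,), lr_grid=(0.1,),
            )

    def test_importance_f_counts_splits(self):
        _, design, labels, _ = simulate_gold_campaign(7, n_slices=120, n_raters=10)
        fit = fit_weighted_aggregator(design, labels, **FAST_FIT)
        assert (fit.importance_f >= 0).all()
        assert fit.importance_f.sum() > 0
        booster_total = sum(
            fit.model.get_booster().get_score(importance_type="weight").values()
        )
        assert fit.importance_f.sum() == booster_total

    def test_missing_entry_distinct_from_zero_in_predictions(self):
        # pass slices: rater 'a' says 0; fail slices: 'a' never saw them.
        # A model fit on this design must route NaN differently from 0.
        idx = [f"s{i}" for i in range(40)]
        labels = pd.Series([1] * 20 + [0] * 20, index=idx)
        rows = [("a", f"s{i}", 0) for i in range(20)]
        rows += [("b", f"s{i}", 1) for i in range(0, 40, 2)]  # keep b uninformative
        ev = events_from(rows)
        design = build_design_matrix(ev).reindex(idx)
        fit = fit_weighted_aggregator(design, labels, **FAST_FIT)
        pred_nan = fit.predict_scores(design)
        pred_zero = fit.predict_scores(design.fillna(0.0))
        assert not np.allclose(pred_nan, pred_zero)

    def test_summary_mentions_chosen_hyperparameters(self):
        _, design, labels, _ = simulate_gold_campaign(8, n_slices=80, n_raters=8)
        fit = fit_weighted_aggregator(design, labels, **FAST_FIT)
        text = fit.summary()
        assert "max_depth" in text and "CV AUC" in text


class TestAmplify:
    def test_training_predictions_deterministic(self):
        _, design, labels, _ = simulate_gold_campaign(9, n_slices=100, n_raters=8)
        fit = fit_weighted_aggregator(design, labels, **FAST_FIT)
        a = amplify_labels(fit, design)
        b = amplify_labels(fit, design)
        pd.testing.assert_frame_equal(a, b)
        assert ((a["score"] >= 0) & (a["score"] <= 1)).all()

    def test_row_permutation_invariance(self):
        _, design, labels, _ = simulate_gold_campaign(10, n_slices=100, n_raters=8)
        fit = fit_weighted_aggregator(design, labels, **FAST_FIT)
        base = fit.predict_scores(design)
        shuffled = fit.predict_scores(design.sample(frac=1.0, random_state=4))
        pd.testing.assert_series_equal(base.sort_index(), shuffled.sort_index())

    def test_unseen_rater_column_dropped_with_warning(self):
        _, design, labels, _ = simulate_gold_campaign(11, n_slices=80, n_raters=6)
        fit = fit_weighted_aggregator(design, labels, **FAST_FIT)
        extended = design.copy()
        extended["stranger"] = 1.0
        with pytest.warns(UserWarning, match="unseen"):
            pred = fit.predict_scores(extended)
        pd.testing.assert_series_equal(pred, fit.predict_scores(design))

    def test_amplified_scores_bimodal_on_simulated_crowd(self):
        _, design, labels, _ = simulate_gold_campaign(12, n_slices=400, n_raters=30)
        fit = fit_weighted_aggregator(design, labels, n_estimators=150, cv_folds=3)
        scores = fit.predict_scores(design).to_numpy()
        counts, _ = np.histogram(scores, bins=20, range=(0, 1))
        interior = counts[4:16].max()
        assert counts[:4].max() > interior and counts[16:].max() > interior


class TestTrainingSizeSweep:
    def test_same_seed_reproduces_auc(self):
        _, design, labels, _ = simulate_gold_campaign(13, n_slices=150, n_raters=10)
        n_train = len(design) - int(np.ceil(len(design) / 3))
        a = training_size_sweep(design, labels, [n_train], seed=5, **FAST_FIT)
        b = training_size_sweep(design, labels, [n_train], seed=5, **FAST_FIT)
        assert a.loc[0, "auc"] == b.loc[0, "auc"]

    def test_learning_curve_improves_with_size(self):
        gains = []
        for seed in range(10):
            _, design, labels, _ = simulate_gold_campaign(
                200 + seed, n_slices=150, n_raters=20, ratings_per_slice=8
            )
            sweep = training_size_sweep(
                design, labels, [20, 90], seed=seed, **FAST_FIT
            )
            gains.append(sweep.loc[1, "auc"] - sweep.loc[0, "auc"])
        assert np.mean(gains) >= 0

    def test_perfect_raters_saturate_at_any_size(self):
        idx = [f"s{i}" for i in range(60)]
        labels = pd.Series([1, 0] * 30, index=idx)
        rows = [(r, s, int(labels[s])) for r in ("a", "b", "c") for s in idx]
        design = build_design_matrix(events_from(rows)).reindex(idx)
        sweep = training_size_sweep(design, labels, [10, 40], seed=0, **FAST_FIT)
        assert (sweep["auc"] == 1.0).all()

    def test_oversized_request_rejected(self):
        _, design, labels, _ = simulate_gold_campaign(14, n_slices=60, n_raters=6)
        with pytest.raises(ValueError):
            training_size_sweep(design, labels, [len(design)], seed=0, **FAST_FIT)


def test_split_gold_is_stratified_and_disjoint():
    _, design, labels, _ = simulate_gold_campaign(15, n_slices=120, n_raters=8)
    x_tr, y_tr, x_te, y_te = split_gold(design, labels, seed=3)
    assert set(x_tr.index).isdisjoint(x_te.index)
    assert len(x_tr) + len(x_te) == len(design)
    assert abs(y_tr.mean() - y_te.mean()) < 0.1
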