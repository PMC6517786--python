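import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from labelamp.crowdsim import (
    ActivityPrior,
    RaterProfile,
    ReliabilityPrior,
    filter_raters,
    sample_rater_pool,
    score_rating,
    serve_next_slice,
    simulate_ratings,
)


def perfect_rater(rid="r0", activity=1.0):
    return RaterProfile(rid, sensitivity=1.0, specificity=1.0, activity=activity)


class TestRaterPool:
    def test_single_perfect_rater_from_degenerate_priors(self):
        pool = sample_rater_pool(
            1,
            ReliabilityPrior(sens_a=1e6, sens_b=1e-3, spec_a=1e6, spec_b=1e-3, low_tail_weight=0),
            seed=0,
        )
        assert pool[0].sensitivity > 0.999 and pool[0].specificity > 0.999

    def test_pool_deterministic_for_fixed_seed(self):
        a = sample_rater_pool(100, seed=42)
        b = sample_rater_pool(100, seed=42)
        assert a == b

    def test_default_priors_encode_pass_bias(self):
        pool = sample_rater_pool(10000, seed=3)
        sens = np.mean([r.sensitivity for r in pool])
        spec = np.mean([r.specificity for r in pool])
        assert sens > spec

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            sample_rater_pool(5, ReliabilityPrior(sens_a=-1))
        with pytest.raises(ValueError):
            sample_rater_pool(0)
        with pytest.raises(ValueError):
            RaterProfile("r", sensitivity=1.2, specificity=0.5)


def slice_table(qs):
    return pd.DataFrame(
        {"slice_id": [f"s{i}" for i in range(len(qs))], "q": list(qs)}
    )


class TestSimulateRatings:
    def test_perfect_rater_always_passes_good_slice(self):
        ev = simulate_ratings([perfect_rater()], slice_table([1.0]), n_events=200, seed=0)
        assert (ev["rating"] == 1).all()

    def test_coin_flip_rater_rates_half_pass_any_quality(self):
        pool = [RaterProfile("r", 0.5, 0.5)]
        for q in (0.0, 0.5, 1.0):
            ev = simulate_ratings(pool, slice_table([q]), n_events=10000, seed=1)
            assert abs(ev["rating"].mean() - 0.5) < 0.02

    def test_bad_slice_pass_rate_is_one_minus_specificity(self):
        pool = [RaterProfile("r", 0.9, 0.8)]
        ev = simulate_ratings(pool, slice_table([0.0]), n_events=10000, seed=2)
        assert abs(ev["rating"].mean() - 0.2) < 0.02

    def test_event_conservation_and_timestamps(self):
        pool = sample_rater_pool(5, seed=0)
        ev = simulate_ratings(pool, slice_table([0.2, 0.9]), n_events=777, seed=3)
        assert len(ev) == 777
        assert (ev["timestamp"].to_numpy() == np.arange(777)).all()

    def test_rater_counts_proportional_to_activity(self):
        pool = [perfect_rater("a", activity=1.0), perfect_rater("b", activity=4.0)]
        ev = simulate_ratings(pool, slice_table([1.0]), n_events=20000, seed=4)
        share = (ev["rater_id"] == "b").mean()
        assert abs(share - 0.8) < 0.02

    def test_two_coin_reduction_at_extreme_quality(self):
        pool = [RaterProfile("r", 0.85, 0.7)]
        n = 20000
        good = simulate_ratings(pool, slice_table([1.0]), n_events=n, seed=5)
        bad = simulate_ratings(pool, slice_table([0.0]), n_events=n, seed=6)
        assert abs(good["rating"].mean() - 0.85) < 3 / np.sqrt(n)
        assert abs((1 - bad["rating"].mean()) - 0.7) < 3 / np.sqrt(n)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_ratings([], slice_table([0.5]), n_events=10)
        with pytest.raises(ValueError):
            simulate_ratings([perfect_rater()], slice_table([]), n_events=10)


class TestServing:
    def test_fewest_first_picks_least_rated(self, rng):
        assert serve_next_slice({"a": 0, "b": 5}, "fewest-first", rng) == "a"

    def test_single_slice_always_served(self, rng):
        assert serve_next_slice({"only": 3}, "random", rng) == "only"

    def test_uniform_when_counts_equal(self, rng):
        counts = {f"s{i}": 2 for i in range(5)}
        draws = [serve_next_slice(counts, "fewest-first", rng) for _ in range(10000)]
        observed = pd.Series(draws).value_counts().reindex(sorted(counts)).to_numpy()
        assert chisquare(observed).pvalue > 0.01

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError):
            serve_next_slice({"a": 0}, "newest-first")


def brute_force_points(rating, history):
    """Direct transcription of the scoring rule."""
    if len(history) > 5:
        avg = sum(history) / len(history)
        if avg > 0.7:
            majority = 1
        elif avg < 0.3:
            majority = 0
        else:
            majority = None
        if majority is not None and rating != majority:
            return 0
    return 1


class TestGamification:
    def test_rating_against_established_majority_scores_zero(self):
        history = [1, 1, 1, 1, 1, 0]  # 6 ratings, mean 5/6
        assert score_rating(0, history) == 0
        assert score_rating(1, history) == 1

    def test_majority_undefined_at_five_ratings(self):
        assert score_rating(0, [1, 1, 1, 1, 1]) == 1

    def test_matches_enumeration_up_to_length_8(self):
        from itertools import product

        for n in range(9):
            for history in product((0, 1), repeat=n):
                for rating in (0, 1):
                    assert score_rating(rating, list(history)) == brute_force_points(
                        rating, list(history)
                    ), (rating, history)


class TestFilterRaters:
    @staticmethod
    def events_with_gold_counts(counts):
        """One rater per count, rating that many distinct gold slices."""
        rows = []
        t = 0
        for i, c in enumerate(counts):
            for j in range(c):
                rows.append(
                    {"rater_id": f"r{i:03d}", "slice_id": f"g{j}", "rating": 1, "timestamp": t}
                )
                t += 1
        return pd.DataFrame(rows)

    def test_261_raters_retain_65(self):
        ev = self.events_with_gold_counts(range(1, 262))
        gold = {f"g{j}" for j in range(400)}
        assert len(filter_raters(ev, gold, quantile=0.25)) == 65

    def test_floor_keeps_exactly_one_of_four(self):
        ev = self.events_with_gold_counts([10, 9, 8, 7])
        kept = filter_raters(ev, {f"g{j}" for j in range(10)}, quantile=0.25)
        assert kept == ["r000"]  # the count-10 rater

    def test_matches_bruteforce_sort_and_cut(self, rng):
        rows = [
            {
                "rater_id": f"r{rng.integers(20):02d}",
                "slice_id": f"s{rng.integers(50)}",
                "rating": int(rng.integers(2)),
                "timestamp": t,
            }
            for t in range(2000)
        ]
        ev = pd.DataFrame(rows)
        gold = {f"s{j}" for j in range(25)}
        kept = filter_raters(ev, gold, quantile=0.4)

        counts = {}
        for r in ev["rater_id"].unique():
            sub = ev[(ev["rater_id"] == r) & (ev["slice_id"].isin(gold))]
            counts[r] = sub["slice_id"].nunique()
        expected = sorted(counts, key=lambda r: (-counts[r], r))[
            : int(np.floor(0.4 * len(counts)))
        ]
        assert kept == expected

    def test_repeat_views_counted_once_by_default(self):
        rows = [
            {"rater_id": "a", "slice_id": "g0", "rating": 1, "timestamp": t}
            for t in range(10)
        ] + [
            {"rater_id": "b", "slice_id": f"g{j}", "rating": 1, "timestamp": 10 + j}
            for j in range(2)
        ]
        ev = pd.DataFrame(rows)
        kept = filter_raters(ev, {"g0", "g1"}, quantile=0.5)
        assert kept == ["b"]
        kept_multi = filter_raters(ev, {"g0", "g1"}, quantile=0.5, distinct=False)
        assert kept_multi == ["a"]

    def test_empty_table_returns_empty(self):
        assert filter_raters(pd.DataFrame(columns=["rater_id", "slice_id"]), set()) == []
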