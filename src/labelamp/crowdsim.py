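"""Simulate citizen-scientist rating campaigns.

Each simulated rater follows a two-coin model: a truly passable slice is
passed with probability ``sensitivity`` and a truly bad one is failed with
probability ``specificity``. For a slice of intermediate latent quality q
the pass probability interpolates linearly between the two coins:

    P(pass) = q * sensitivity + (1 - q) * (1 - specificity)

Crowds in web-based rating games show a systematic tendency to pass bad
images and heavy-tailed per-user activity, so the default rater priors
skew sensitivity high, give specificity a low-reliability tail, and draw
activity from a log-normal. Serving starts random and switches to
fewest-first; a simple gamification rule awards a point per rating unless
the rating disagrees with an established majority.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RaterProfile",
    "ReliabilityPrior",
    "ActivityPrior",
    "sample_rater_pool",
    "simulate_ratings",
    "serve_next_slice",
    "score_rating",
    "filter_raters",
]


@dataclass(frozen=True)
class RaterProfile:
    rater_id: str
    sensitivity: float
    specificity: float
    activity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must be in [0, 1]")
        if self.activity <= 0:
            raise ValueError("activity must be positive")

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    def pass_probability(self, q: float) -> float:
        """Two-coin response interpolated linearly in latent quality q."""
        return q * self.sensitivity + (1.0 - q) * (1.0 - self.specificity)


@dataclass(frozen=True)
class ReliabilityPrior:
    """Beta priors for the two coins, plus a spammer mass.

    sensitivity ~ Beta(sens_a, sens_b), skewed high by default;
    specificity is a mixture of a competent mode Beta(spec_a, spec_b) and,
    with probability ``low_tail_weight``, a low-reliability tail
    Beta(tail_a, tail_b) — together these encode the pass bias.
    ``unreliable_fraction`` raters are outright random/adversarial
    (both coins ~ Uniform(0.2, 0.6)).
    """

    sens_a: float = 12.0
    sens_b: float = 2.0
    spec_a: float = 8.0
    spec_b: float = 3.0
    tail_a: float = 2.0
    tail_b: float = 5.0
    low_tail_weight: float = 0.15
    unreliable_fraction: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.sens_a, self.sens_b, self.spec_a, self.spec_b, self.tail_a, self.tail_b):
            if v <= 0:
                raise ValueError("Beta prior parameters must be positive")
        if not 0.0 <= self.low_tail_weight <= 1.0:
            raise ValueError("low_tail_weight must be in [0, 1]")
        if not 0.0 <= self.unreliable_fraction <= 1.0:
            raise ValueError("unreliable_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ActivityPrior:
    """Log-normal activity: heavy tail of a few very active raters."""

    mu: float = 0.0
    sigma: float = 1.0
    fixed: float | None = None  # set to force equal activity

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.fixed is not None and self.fixed <= 0:
            raise ValueError("fixed activity must be positive")


def sample_rater_pool(
    n_raters: int,
    reliability_prior: ReliabilityPrior | None = None,
    activity_prior: ActivityPrior | None = None,
    seed: int = 0,
) -> list[RaterProfile]:
    """Draw a pool of rater profiles i.i.d. from the priors."""
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    rel = reliability_prior or ReliabilityPrior()
    act = activity_prior or ActivityPrior()
    rng = np.random.default_rng(seed)

    sens = rng.beta(rel.sens_a, rel.sens_b, size=n_raters)
    spec = rng.beta(rel.spec_a, rel.spec_b, size=n_raters)
    tail = rng.random(n_raters) < rel.low_tail_weight
    spec[tail] = rng.beta(rel.tail_a, rel.tail_b, size=int(tail.sum()))
    bad = rng.random(n_raters) < rel.unreliable_fraction
    sens[bad] = rng.uniform(0.2, 0.6, size=int(bad.sum()))
    spec[bad] = rng.uniform(0.2, 0.6, size=int(bad.sum()))

    if act.fixed is not None:
        activity = np.full(n_raters, act.fixed)
    else:
        activity = rng.lognormal(act.mu, act.sigma, size=n_raters)

    width = max(3, len(str(n_raters)))
    return [
        RaterProfile(
            rater_id=f"rater{str(i).zfill(width)}",
            sensitivity=float(sens[i]),
            specificity=float(spec[i]),
            activity=float(activity[i]),
        )
        for i in range(n_raters)
    ]


def serve_next_slice(
    counts: dict[str, int],
    phase: str = "fewest-first",
    seed: int | np.random.Generator = 0,
) -> str:
    """Pick the next slice to serve.

    "random" draws uniformly over all slices; "fewest-first" draws
    uniformly among the slices with the minimal current rating count.
    """
    if not counts:
        raise ValueError("counts must contain at least one slice")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = sorted(counts)
    if phase == "random":
        return ids[rng.integers(len(ids))]
    if phase == "fewest-first":
        m = min(counts.values())
        pool = [s for s in ids if counts[s] == m]
        return pool[rng.integers(len(pool))]
    raise ValueError(f"unknown serving phase {phase!r}")


def score_rating(rating: int, slice_history: list[int] | np.ndarray) -> int:
    """Gamification points for one rating.

    A majority exists only when the slice already has more than 5 ratings
    and their mean is below 0.3 or above 0.7; rating against it earns 0
    points, anything else earns 1. The incoming rating is not part of the
    history.
    """
    if rating not in (0, 1):
        raise ValueError("rating must be 0 or 1")
    hist = np.asarray(slice_history, dtype=float)
    if hist.size > 5:
        m = hist.mean()
        if m > 0.7 and rating == 0:
            return 0
        if m < 0.3 and rating == 1:
            return 0
    return 1


def simulate_ratings(
    pool: list[RaterProfile],
    slices: pd.DataFrame,
    n_events: int,
    policy: str = "mixed",
    random_phase_events: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a rating campaign of ``n_events`` events.

    Parameters
    ----------
    pool
        Rater profiles; each event's rater is drawn with probability
        proportional to activity.
    slices
        DataFrame with columns ``slice_id`` and ``q`` (latent quality).
    policy
        "random", "fewest-first", or "mixed" (random for the first
        ``random_phase_events`` events — default one pass over the slice
        set — then fewest-first).
    Returns a DataFrame (rater_id, slice_id, rating, timestamp) with
    monotone integer timestamps.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not pool or len(slices) == 0:
        raise ValueError("pool and slices must be non-empty")
    if policy not in ("random", "fewest-first", "mixed"):
        raise ValueError(f"unknown policy {policy!r}")
    if "slice_id" not in slices.columns or "q" not in slices.columns:
        raise ValueError("slices must have columns slice_id and q")
    q = np.asarray(slices["q"], dtype=float)
    if ((q < 0) | (q > 1)).any():
        raise ValueError("latent quality q must be in [0, 1]")

    rng = np.random.default_rng(seed)
    slice_ids = slices["slice_id"].to_numpy()
    n_slices = slice_ids.size
    switch = random_phase_events if random_phase_events is not None else n_slices

    activity = np.array([r.activity for r in pool])
    p_rater = activity / activity.sum()
    rater_idx = rng.choice(len(pool), size=n_events, p=p_rater)

    counts = np.zeros(n_slices, dtype=int)
    served = np.empty(n_events, dtype=int)
    for t in range(n_events):
        if policy == "random" or (policy == "mixed" and t < switch):
            j = rng.integers(n_slices)
        else:  # fewest-first, uniform among minima
            m = counts.min()
            pool_idx = np.flatnonzero(counts == m)
            j = pool_idx[rng.integers(pool_idx.size)]
        served[t] = j
        counts[j] += 1

    sens = np.array([r.sensitivity for r in pool])[rater_idx]
    spec = np.array([r.specificity for r in pool])[rater_idx]
    qq = q[served]
    p_pass = qq * sens + (1.0 - qq) * (1.0 - spec)
    ratings = (rng.random(n_events) < p_pass).astype(int)

    return pd.DataFrame(
        {
            "rater_id": [pool[i].rater_id for i in rater_idx],
            "slice_id": slice_ids[served],
            "rating": ratings,
            "timestamp": np.arange(n_events),
        }
    )


def filter_raters(
    events: pd.DataFrame,
    gold_slice_ids,
    quantile: float = 0.25,
    distinct: bool = True,
) -> list[str]:
    """Keep the top fraction of raters by gold-standard coverage.

    Raters are ranked by how many gold-standard slices they rated
    (distinct slices by default; set ``distinct=False`` to count repeat
    views) and the top ``floor(quantile * n_raters)`` are retained. Ties
    at the cutoff break by rater_id so the result is deterministic.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    if len(events) == 0:
        return []
    gold = set(gold_slice_ids)
    on_gold = events[events["slice_id"].isin(gold)]
    counts = (
        on_gold.groupby("rater_id")["slice_id"].nunique()
        if distinct
        else on_gold.groupby("rater_id")["slice_id"].count()
    )
    all_raters = events["rater_id"].unique()
    counts = counts.reindex(all_raters, fill_value=0)
    n_keep = int(np.floor(quantile * len(all_raters)))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [r for r, _ in ranked[:n_keep]]
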