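import numpy as np
import pandas as pd
import pytest

from labelamp.phantom import generate_phantom_volume


@pytest.fixture(scope="session")
def phantom_volume():
    """One default phantom volume, shared across tests (read-only)."""
    return generate_phantom_volume(seed=1)


@pytest.fixture(scope="session")
def clean_slice(phantom_volume):
    """A mid-head axial slice of the phantom."""
    return phantom_volume.axial_slice(110)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def simulate_gold_campaign(
    seed,
    n_slices=300,
    n_raters=40,
    ratings_per_slice=15,
    unreliable_fraction=0.25,
    equal_activity=False,
):
    """Crowd campaign over a bimodal-quality slice set with known labels.

    Shared helper for aggregation/acceptance tests: returns (events,
    design, labels, pool).
    """
    from labelamp.aggregation import build_design_matrix
    from labelamp.crowdsim import (
        ActivityPrior,
        ReliabilityPrior,
        sample_rater_pool,
        simulate_ratings,
    )
    from labelamp.phantom import sample_severities

    sev = sample_severities(n_slices, fail_fraction=0.5, seed=seed)
    q = 1.0 - sev
    slices = pd.DataFrame(
        {"slice_id": [f"s{i:04d}" for i in range(n_slices)], "q": q}
    )
    pool = sample_rater_pool(
        n_raters,
        ReliabilityPrior(unreliable_fraction=unreliable_fraction),
        ActivityPrior(fixed=1.0) if equal_activity else ActivityPrior(),
        seed=seed + 1,
    )
    events = simulate_ratings(
        pool, slices, n_events=int(ratings_per_slice * n_slices), seed=seed + 2
    )
    design = build_design_matrix(events)
    labels = pd.Series((q >= 0.5).astype(int), index=slices["slice_id"]).loc[
        design.index
    ]
    return events, design, labels, pool
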