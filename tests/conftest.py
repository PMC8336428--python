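"""Shared fixtures: synthetic worlds, rater populations, cartoon faces."""

import numpy as np
import pytest

from percepspace.metric import FitConfig, fit_metric
from percepspace.ratings import DissimilarityTable
from percepspace.synthetic import (
    RaterModel,
    make_cartoon_faces,
    make_world,
    sample_pairs,
    simulate_ratings,
    true_dissimilarity,
)


def table_from_values(pairs, values):
    table = DissimilarityTable()
    for p, v in zip(pairs, values):
        key = DissimilarityTable._key(*p)
        table.entries[key] = float(v)
        table.n_ratings[key] = 1
    return table


@pytest.fixture(scope="session")
def small_world():
    """100 items in 10 dims with a planted rank-3 metric, b*=0.4."""
    return make_world(n_items=100, n_dims=10, rank=3, b=0.4, seed=1)


@pytest.fixture(scope="session")
def small_world_data(small_world):
    """Noiseless pairs/table for the small world plus a held-out split."""
    pairs = sample_pairs(small_world, 900, seed=2)
    f = true_dissimilarity(small_world, pairs)
    train = table_from_values(pairs[:700], f[:700])
    heldout = table_from_values(pairs[700:], f[700:])
    return {"pairs": pairs, "f": f, "train": train, "heldout": heldout}


@pytest.fixture(scope="session")
def small_fit(small_world, small_world_data):
    """Unregularized fit on the noiseless small world (exact recovery regime)."""
    return fit_metric(
        small_world.features, small_world_data["train"], FitConfig(regularizer="none", tol=1e-12)
    )


@pytest.fixture(scope="session")
def rated_population():
    """A simulated population: 30 attentive raters plus 3 random-clickers."""
    world = make_world(n_items=60, n_dims=8, rank=3, seed=5)
    raters = [RaterModel(sigma=0.05, pairs_per_rater=60) for _ in range(30)]
    raters += [RaterModel(attentive=False, pairs_per_rater=60) for _ in range(3)]
    df = simulate_ratings(world, raters, seed=7)
    return world, df


@pytest.fixture(scope="session")
def cartoon_set():
    images, landmarks, factors = make_cartoon_faces(n=50, image_size=64, seed=11)
    return images, landmarks, factors


@pytest.fixture(scope="session")
def aam_model(cartoon_set):
    from percepspace.aam import build_model

    images, landmarks, _ = cartoon_set
    return build_model(images, landmarks, variance_retained=0.98)
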