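import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import facebench as fb

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def stim_default() -> fb.StimulusSet:
    """The full 302-image stimulus set (25 per context + tokens)."""
    return fb.generate_stimulus_set(25, seed=11)


@pytest.fixture(scope="session")
def stim_small() -> fb.StimulusSet:
    """A 50-image set (4 per context + tokens) for fast simulations."""
    return fb.generate_stimulus_set(4, seed=13)


@pytest.fixture()
def uniform_observer(stim_small) -> fb.ObserverModel:
    """Lapse-free observer with per-image accuracy spread over (0.25, 0.95)."""
    rng = np.random.default_rng(7)
    ids = stim_small.image_ids
    return fb.ObserverModel("unif", pd.Series(rng.uniform(0.25, 0.95, len(ids)), index=ids))


def make_random_trials(n_trials: int, n_images: int, seed: int) -> pd.DataFrame:
    """Arbitrary (not model-based) trial table for counting oracles."""
    rng = np.random.default_rng(seed)
    img_idx = rng.integers(0, n_images, n_trials)
    cats = np.where(img_idx % 2 == 0, "A", "B")
    resp = np.where(rng.random(n_trials) < rng.uniform(0.2, 0.9, n_images)[img_idx],
                    cats, np.where(cats == "A", "B", "A"))
    return pd.DataFrame(
        {
            "subject_id": "s1",
            "pool_id": "p",
            "image_id": np.char.add("img", img_idx.astype(str)),
            "true_category": cats,
            "response_category": resp,
            "session": "x",
        }
    )
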