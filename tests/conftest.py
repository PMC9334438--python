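import warnings

import numpy as np
import pandas as pd
import pytest

from vocalid import default_profiles, sample_corpus
from vocalid.features import FEATURE_NAMES, extract_features_table
from vocalid.trials import DesignConfig, EffectConfig, generate_design, simulate_outcomes


@pytest.fixture(scope="session")
def small_corpus():
    """6 speakers x 6 sentences, short durations — shared across feature and
    speaker-space tests."""
    profiles = default_profiles(n_speakers=6, seed=11, duration_s=1.0)
    return sample_corpus(profiles, 6, seed=12)


@pytest.fixture(scope="session")
def small_features(small_corpus):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tab = extract_features_table(small_corpus)
    return tab.dropna(subset=FEATURE_NAMES)


@pytest.fixture(scope="session")
def marker_distances():
    """Synthetic z-scored per-control-speaker distances for the six markers."""
    rng = np.random.default_rng(77)
    dist = pd.DataFrame(
        {"control_speaker_id": [f"control_{i + 1:02d}" for i in range(14)]}
    )
    for m in ("f0_mean", "f0_sd", "dF", "HNR", "ent", "ppj"):
        v = np.abs(rng.normal(1.0, 0.6, 14))
        dist[f"dist_{m}_z"] = (v - v.mean()) / v.std(ddof=1)
    return dist


@pytest.fixture(scope="session")
def simulated_trials(marker_distances):
    """Paper-scale simulated experiment (28 dogs) under the default truth."""
    design = generate_design(DesignConfig(), seed=21)
    return simulate_outcomes(design, EffectConfig(), seed=22, distances=marker_distances)
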