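import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from crowdanx.embeddings import WordEmbedding
from crowdanx.lexicon import AnchorLexicon, FrequencyLexicon
from crowdanx.synth import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(n_communities=8, size_range=(20, 40), seed=3)


@pytest.fixture(scope="session")
def small_corpus(small_config):
    return generate_corpus(small_config)


@pytest.fixture(scope="session")
def toy_embedding():
    """Hand-built vectors: 'terrible' sits close to the anxiety anchors,
    'good' far from them; 'weekend'/'work' are off-axis fillers."""
    a = np.array([1.0, 0.0, 0.0, 0.0])
    return WordEmbedding({
        "nervous": a,
        "afraid": np.array([0.96, 0.28, 0.0, 0.0]),
        "terrible": np.array([0.9, 0.0, 0.435889894354, 0.0]),
        "good": np.array([-1.0, 0.0, 0.0, 0.0]),
        "weekend": np.array([0.0, 0.0, 0.0, 1.0]),
        "work": np.array([0.0, 1.0, 0.0, 0.0]),
        "life": np.array([0.0, 0.7, 0.7, 0.0]),
    })


@pytest.fixture(scope="session")
def toy_anchor_lexicon():
    return AnchorLexicon(("nervous", "afraid"))


@pytest.fixture(scope="session")
def toy_freq_lexicon():
    return FrequencyLexicon({"mele": 1000, "dora": 500, "kipu": 200, "i": 9000,
                             "you": 8000, "and": 7000})


def make_profiles(n, rng=None, **overrides):
    """Small personal-account profile table for unit tests."""
    rng = rng or np.random.default_rng(0)
    df = pd.DataFrame({
        "user_id": [f"u{i}" for i in range(n)],
        "gender": rng.choice(["female", "male"], n),
        "age": rng.integers(18, 70, n),
        "education_level": rng.integers(1, 6, n),
        "occupation": rng.choice(["student", "manual"], n),
        "income_band": rng.integers(1, 6, n),
        "location": rng.choice(["east", "west"], n),
        "is_influencer": np.zeros(n, dtype=bool),
        "is_verified": np.zeros(n, dtype=bool),
        "is_organizational": np.zeros(n, dtype=bool),
    })
    for col, val in overrides.items():
        df[col] = val
    return df
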