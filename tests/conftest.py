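import numpy as np
import pytest

from kinetraits import kineme, synthetic


@pytest.fixture(scope="session")
def small_corpus() -> synthetic.SynthCorpus:
    """10 videos, 3 prototypes, 10 fps, mild noise."""
    config = synthetic.SynthConfig(
        n_videos=10,
        duration_s=8.0,
        frame_rate=10.0,
        n_prototypes=3,
        noise_sd=synthetic.NoiseSpec(angle=0.01, au=0.3, lld=0.3, label=0.02),
        seed=11,
    )
    return synthetic.generate_corpus(config)


@pytest.fixture(scope="session")
def small_vocab(small_corpus) -> kineme.KinemeVocabulary:
    segments = kineme.build_segment_matrix(small_corpus.pose_series())
    return kineme.learn_vocabulary(segments, rank=6, k=3, seed=0)


@pytest.fixture(scope="session")
def small_encodings(small_corpus, small_vocab):
    return synthetic.encode_corpus(small_corpus, small_vocab)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
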