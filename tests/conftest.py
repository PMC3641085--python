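import numpy as np
import pytest

from parentese.detector import ParenteseDetector
from parentese.synth import StudyDesign, synth_corpus, synth_interaction_study

TRAIN_SEED = 20_001
TEST_SEED = 20_002
STUDY_SEED = 42


@pytest.fixture(scope="session")
def train_corpus():
    """100 parentese + 100 other-speech training utterances."""
    return synth_corpus(100, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def test_corpus():
    """Disjoint 50 + 50 held-out corpus."""
    return synth_corpus(50, seed=TEST_SEED)


@pytest.fixture(scope="session")
def trained_detector(train_corpus):
    return ParenteseDetector().fit(train_corpus, seed=0)


@pytest.fixture(scope="session")
def study():
    """One default synthetic interaction study plus its ground truth."""
    return synth_interaction_study(StudyDesign(random_seed=STUDY_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
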