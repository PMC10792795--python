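import numpy as np
import pytest

from perioloss.annotations import orient_molar
from perioloss.prior import fit_coordinate_distributions
from perioloss.synthgen import SynthParams, generate_dataset


@pytest.fixture(scope="session")
def synth_corpus():
    """300 oriented synthetic molar crops plus their ground-truth table."""
    molars, truth = generate_dataset(SynthParams(seed=7), 300)
    return [orient_molar(m) for m in molars], truth


@pytest.fixture(scope="session")
def synth_holdout():
    """100 oriented held-out crops from an independent stream."""
    molars, truth = generate_dataset(SynthParams(seed=8), 100)
    return [orient_molar(m) for m in molars], truth


@pytest.fixture(scope="session")
def corpus_prior(synth_corpus):
    """Keypoint prior fitted on the 300-crop corpus."""
    molars, _ = synth_corpus
    vectors = np.array([m.keypoint_vector()[0] for m in molars])
    return fit_coordinate_distributions(vectors)
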