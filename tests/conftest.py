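import numpy as np
import pytest

from redfas import builtin_word_sets, deviation_track, segment_chromosome
from redfas.synthetic import demo_chromosome


@pytest.fixture(scope="session")
def word_sets():
    return {ws.name: ws for ws in builtin_word_sets()}


@pytest.fixture(scope="session")
def demo_data():
    """Standard 2 Mb / 10 kb demo chromosome with two planted regions."""
    record, truth = demo_chromosome(seed=0)
    matrix = segment_chromosome(record, truth.segment_size, k=5)
    track = deviation_track(matrix, builtin_word_sets())
    return record, truth, matrix, track


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
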