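import numpy as np
import pytest

from oriforest import BiasWindow, GeneratorSpec, generate
from oriforest.sequence_io import SequenceRecord, write_fasta


@pytest.fixture(scope="session")
def tiny_biased_dataset():
    """A small, clearly separable benchmark for fast cross-validation tests."""
    spec = GeneratorSpec(
        n_pos=12,
        n_neg=12,
        length=40,
        bias_windows=(BiasWindow(start=5, end=25, code="AA", delta=0.8),),
        seed=7,
    )
    return generate(spec)


@pytest.fixture
def fasta_factory(tmp_path):
    """Write (id, seq) pairs to a FASTA file under tmp_path, return the path."""

    def _write(name, pairs):
        path = tmp_path / name
        write_fasta([SequenceRecord(id=i, seq=s) for i, s in pairs], path)
        return path

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(20160301)


def random_sequences(rng, n, length):
    """n random ACGT strings of the given length."""
    bases = np.array(list("ACGT"))
    return ["".join(bases[rng.integers(0, 4, size=length)]) for _ in range(n)]
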