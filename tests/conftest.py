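import numpy as np
import pytest

from codiv import PartialAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20201111)


@pytest.fixture
def write_fasta(tmp_path):
    """Write (label, sequence) pairs to a FASTA file and return its path."""

    def _write(pairs, name="aln.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{l}\n{s}\n" for l, s in pairs))
        return path

    return _write


def make_alignment(pairs) -> PartialAlignment:
    return PartialAlignment.from_sequences(pairs)
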