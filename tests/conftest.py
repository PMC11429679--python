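import numpy as np
import pytest

from twinc.genome import GenomeStore, onehot_from_string


@pytest.fixture
def tiny_fasta(tmp_path):
    """Two-chromosome FASTA with wrapped lines and mixed case."""
    path = tmp_path / "tiny.fa"
    path.write_text(
        ">c1\nACGTacgtNNNNACGT\nACGTACGTACGTACGT\n>c2\nGGGGCCCCAAAATTTT\n"
    )
    return path


def store_from_seqs(**seqs) -> GenomeStore:
    """In-memory GenomeStore from keyword chromosome sequences."""
    onehot = np.concatenate([onehot_from_string(s) for s in seqs.values()])
    return GenomeStore(list(seqs), {k: len(v) for k, v in seqs.items()}, onehot)


@pytest.fixture
def abc_store():
    return store_from_seqs(c1="ACGT" * 100, c2="GGCC" * 75)
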