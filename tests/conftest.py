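import numpy as np
import pytest

from mirtargraph.io_formats import SequenceRecord
from mirtargraph.kmer import KmerConfig, frequency_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_records(rng, n_mirna, n_target, mirna_len=21, target_len=60):
    """Random sequence records, miRNAs first then targets."""
    bases = np.array(list("ACGU"))
    recs = []
    for i in range(n_mirna):
        recs.append(
            SequenceRecord(
                id=f"m{i}", sequence="".join(rng.choice(bases, mirna_len)), role="miRNA"
            )
        )
    for j in range(n_target):
        recs.append(
            SequenceRecord(
                id=f"t{j}", sequence="".join(rng.choice(bases, target_len)), role="target"
            )
        )
    return recs


@pytest.fixture
def small_records(rng):
    return random_records(rng, n_mirna=3, n_target=5)


@pytest.fixture
def small_freqs(small_records):
    """3 miRNAs + 5 targets at k=3 (64 columns): cheap but non-trivial."""
    return frequency_matrix(small_records, KmerConfig(k=3))


@pytest.fixture
def fasta_file(tmp_path):
    def _write(content, name="seqs.fasta"):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
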