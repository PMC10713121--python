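import numpy as np
import pytest

from haplophase.fragments import ReadFragmentMatrix, encode_base


def matrix_from_strings(rows: list[str], positions=None) -> ReadFragmentMatrix:
    """Build a fragment matrix from allele strings ('-' = uncovered)."""
    entries = np.array([[encode_base(c) for c in row] for row in rows], dtype=np.int8)
    if positions is None:
        positions = np.arange(entries.shape[1])
    ids = [f"r{i}" for i in range(entries.shape[0])]
    return ReadFragmentMatrix(entries, ids, np.asarray(positions))


def haplotypes_from_strings(rows: list[str]) -> np.ndarray:
    return np.array([[encode_base(c) for c in row] for row in rows], dtype=np.int8)


@pytest.fixture
def simple_matrix():
    # two haplotype groups over 4 SNPs, fully bridged
    return matrix_from_strings([
        "ACGT",
        "ACG-",
        "-CGT",
        "TGCA",
        "TGC-",
        "-GCA",
    ])
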