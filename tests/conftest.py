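import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from stemward.matrix import CharacterMatrix, Partition

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_binary_matrix(rng, n_taxa, n_char, missing=0.1, n_states=2,
                         outgroup=None, hard=None):
    """Uniform random matrix (no tree structure) for engine tests."""
    codes = (1 << rng.integers(0, n_states, size=(n_taxa, n_char))).astype(np.int64)
    if missing:
        codes[rng.random((n_taxa, n_char)) < missing] = 0
    taxa = tuple(f"t{i}" for i in range(n_taxa))
    part = np.zeros(n_char, dtype=np.int8)
    if hard is not None:
        part[hard:] = int(Partition.SOFT)
    return CharacterMatrix(
        taxa=taxa, codes=codes, partition=part,
        outgroup=outgroup or taxa[0],
    )


@pytest.fixture
def matrix_factory():
    return random_binary_matrix


def build_matrix(rows, partition, outgroup, taxa=None):
    """Matrix from string rows like '01?{01}2'."""
    from stemward.matrix import _parse_row_tokens

    taxa = taxa or tuple(f"t{i}" for i in range(len(rows)))
    codes = np.array([_parse_row_tokens(r, "<test>", i) for i, r in enumerate(rows)],
                     dtype=np.int64)
    part = np.array(
        [int(Partition.HARD) if p.upper() == "H" else int(Partition.SOFT)
         for p in partition],
        dtype=np.int8,
    )
    return CharacterMatrix(taxa=tuple(taxa), codes=codes, partition=part,
                           outgroup=outgroup)


@pytest.fixture
def small_matrix():
    # 5 taxa x 4 characters, 2 hard + 2 soft, with missing and polymorphism
    return build_matrix(
        ["0101", "01?1", "1{01}10", "1010", "?110"],
        "HHSS",
        outgroup="t0",
    )
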