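import numpy as np
import pytest

from hybriddetect import MarkerMatrix, SpecimenMeta


@pytest.fixture
def toy_matrix():
    """Two parental specimens per species plus one query, five loci.

    L1 monomorphic; L2 diagnostic for A; L3 unique to A (polymorphic in A);
    L4 diagnostic for B; L5 present only in the query (novel).
    """
    values = np.array(
        [
            # L1 L2 L3 L4 L5
            [1, 1, 1, 0, 0],  # a1
            [1, 1, 0, 0, 0],  # a2
            [1, 0, 0, 1, 0],  # b1
            [1, 0, 0, 1, 0],  # b2
            [1, 1, 0, 1, 1],  # q1
        ],
        dtype=np.int8,
    )
    return MarkerMatrix(
        ["a1", "a2", "b1", "b2", "q1"],
        ["L1", "L2", "L3", "L4", "L5"],
        values,
    )


@pytest.fixture
def toy_meta():
    return {
        "a1": SpecimenMeta("a1", "parent_A"),
        "a2": SpecimenMeta("a2", "parent_A"),
        "b1": SpecimenMeta("b1", "parent_B"),
        "b2": SpecimenMeta("b2", "parent_B"),
        "q1": SpecimenMeta("q1", "query"),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
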