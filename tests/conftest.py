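import pytest

from molexpand.seq_io import Alignment


@pytest.fixture
def toy_alignment() -> Alignment:
    """4 sequences, 10 bp, 3 variable columns (positions 1, 4, 8).

    Pairwise differences, enumerated by hand over all 6 pairs:
      s1-s2: 1   s1-s3: 2   s1-s4: 3
      s2-s3: 1   s2-s4: 2   s3-s4: 1
    so S = 3, k̄ = 10/6 and π = (10/6)/10 = 1/6.
    """
    return Alignment(
        records=[
            ("s1", "AACGTACGTA"),
            ("s2", "ATCGTACGTA"),
            ("s3", "ATCGAACGTA"),
            ("s4", "ATCGAACGGA"),
        ]
    )


@pytest.fixture
def grouped_alignment() -> Alignment:
    recs = [
        ("a1", "AAAA"),
        ("a2", "AAAT"),
        ("b1", "CCCC"),
        ("b2", "CCCG"),
        ("b3", "CCCC"),
    ]
    return Alignment(
        records=recs,
        group_of={"a1": "A", "a2": "A", "b1": "B", "b2": "B", "b3": "B"},
    )
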