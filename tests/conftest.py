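from __future__ import annotations

import pytest

from nibls import AlignedRead, GenomeSpec


@pytest.fixture
def make_read():
    """Factory for reads with auto-generated ids."""
    counter = iter(range(10_000))

    def _make(chrom: str, start: int, end: int, strand: str = "+") -> AlignedRead:
        return AlignedRead(f"r{next(counter)}", chrom, start, end, strand)

    return _make


@pytest.fixture
def worked_example_reads(make_read):
    """Five reads whose proximity graph at M=1 is the worked five-vertex component.

    Edges: 1-2, 1-3, 2-3 (mutual overlaps), 3-4 (overlap), 4-5 (abutting, gap 0).
    No other pair comes within 1 nt.
    """
    return [
        make_read("chr1", 10, 20),
        make_read("chr1", 15, 25),
        make_read("chr1", 18, 30),
        make_read("chr1", 30, 40),
        make_read("chr1", 41, 50),
    ]


@pytest.fixture
def small_genome():
    return GenomeSpec({"chr1": 1000})
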