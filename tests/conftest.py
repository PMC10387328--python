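"""Shared builders for the test suite."""
from __future__ import annotations

import pytest

from ecdnatk.model import AlignedInterval, FragmentChain


def ai(
    read_start,
    read_end,
    chrom,
    ref_start,
    ref_end,
    strand="+",
    read_id="r1",
    cell_id="c1",
):
    return AlignedInterval(
        read_id=read_id,
        cell_id=cell_id,
        read_start=read_start,
        read_end=read_end,
        chrom=chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
    )


def chain(*intervals, read_id="r1", cell_id="c1"):
    ivs = [
        iv if isinstance(iv, AlignedInterval) else ai(*iv, read_id=read_id, cell_id=cell_id)
        for iv in intervals
    ]
    return FragmentChain(read_id=read_id, cell_id=cell_id, intervals=ivs)


@pytest.fixture
def make_chain():
    return chain


@pytest.fixture
def make_interval():
    return ai
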