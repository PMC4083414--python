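"""Shared fixtures: small hand-checkable stem-loops and read sets."""

import pytest

from miredit import StemLoop, Interval, make_stemloop


@pytest.fixture
def simple_hairpin() -> StemLoop:
    """4-bp stem, 3-nt loop; every coordinate checkable by eye.

        GCGA AUU UCGC   ->   (((( ... ))))
    """
    return StemLoop(
        id="hp1",
        sequence="GCGAATTTCGC",
        dotbracket="((((...))))",
        mature_intervals=(Interval("5P", 1, 4), Interval("3P", 8, 11)),
        genomic_segments=(Interval("exon", 1, 3), Interval("intron", 4, 8), Interval("exon", 9, 11)),
    )


@pytest.fixture
def bulged_hairpin() -> StemLoop:
    """Constructed hairpin with one 2-nt bulge on the 5P arm."""
    return make_stemloop(stem_len=12, loop_len=4, bulges=[("5p", 6, 2)], seed=11, id="hp-bulge")
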