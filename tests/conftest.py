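"""Shared fixtures: desk-scale references and small simulated samples.

The "mini" reference shrinks the default toy genome tenfold (5 chromosomes
x 200 kb) so unit tests simulate in milliseconds; CNA-scale tests use the
23-chromosome miniature genome at 30x.
"""

from __future__ import annotations

import pytest

from ball_subtyper.reference import build_toy_reference, human_like_reference

MINI_SPEC = {
    "chromosomes": [(c, 200_000) for c in ("chrA", "chrB", "chrC", "chrD", "chrE")],
    "loci": {
        "IGH": [("chrD", 80_000, 120_000)],
        "DUX4_arrays": [("chrA", 190_000, 195_000), ("chrE", 188_000, 196_000)],
        "ETV6": [("chrA", 20_000, 30_000)],
        "CDKN2A/B": [("chrA", 60_000, 70_000)],
        "RUNX1": [("chrB", 20_000, 30_000)],
        "KMT2A": [("chrB", 60_000, 70_000)],
        "PAX5": [("chrB", 100_000, 110_000)],
        "TCF3": [("chrC", 20_000, 30_000)],
        "PBX1": [("chrC", 60_000, 70_000)],
        "ABL1": [("chrC", 100_000, 110_000)],
        "RANBP2": [("chrC", 140_000, 150_000)],
        "BCR": [("chrD", 20_000, 30_000)],
        "ERG": [("chrD", 40_000, 50_000)],
        "P2RY8": [("chrE", 15_000, 25_000)],
        "CRLF2": [("chrE", 30_000, 40_000)],
        "PAR1": [("chrE", 15_000, 40_000)],
    },
    "overlap_allowed": ["PAR1", "P2RY8", "CRLF2"],
    "assembly_label": "toy-mini-200k",
}


@pytest.fixture(scope="session")
def mini_ref():
    return build_toy_reference(MINI_SPEC)


@pytest.fixture(scope="session")
def toy_ref():
    return build_toy_reference()


@pytest.fixture(scope="session")
def human_ref():
    return human_like_reference()
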