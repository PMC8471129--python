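"""Shared fixtures: synthetic genomes emulating the three study conditions."""

import pytest

from mitochar import GeneratorSpec, generate
from mitochar.synthetic import DEFAULT_OVERLAPS


@pytest.fixture(scope="session")
def genome_and_truth():
    """Default synthetic mitogenome (ancestral order, 32 bp x6 CR repeat)."""
    return generate(GeneratorSpec(seed=1))


@pytest.fixture(scope="session")
def genome(genome_and_truth):
    return genome_and_truth[0]


@pytest.fixture(scope="session")
def truth(genome_and_truth):
    return genome_and_truth[1]


def trio_specs():
    """Three specs mirroring the three sequenced stick-insect conditions:

    a long CR with a non-tandem 172 bp duplication, a short CR with a
    32 bp x6 tandem array (plus a GTG-started ND4L), and a long CR with a
    106 bp x7 tandem array.  One genome carries the C variant of the
    trnW/trnC overlap so the cross-genome consensus is degenerate (AAGYCTTA),
    and two of the three carry an extra private overlap.
    """
    extra = (("trnK", "trnD", 1, "A"),)
    variant_wc = tuple(
        ("trnW", "trnC", 8, "AAGCCTTA") if pair[0] == "trnW" else pair
        for pair in DEFAULT_OVERLAPS)
    return [
        GeneratorSpec(seed=101, genome_at_fraction=0.756, cr_length=2238,
                      cr_repeats=(), cr_dispersed=((172, 300),),
                      planted_overlaps=DEFAULT_OVERLAPS + extra,
                      accession="SYN000101", taxon_name="Synthetica prima"),
        GeneratorSpec(seed=102, genome_at_fraction=0.766, cr_length=1294,
                      cr_repeats=((32, 6.0, 1.0),),
                      gtg_start_genes=("ND4L",),
                      incomplete_stop_genes=("COX2", "ND3", "ND4L", "ND5"),
                      planted_overlaps=variant_wc + extra,
                      accession="SYN000102", taxon_name="Synthetica secunda"),
        GeneratorSpec(seed=103, genome_at_fraction=0.768, cr_length=2286,
                      cr_repeats=((106, 7.0, 1.0),),
                      accession="SYN000103", taxon_name="Synthetica tertia"),
    ]


@pytest.fixture(scope="session")
def trio():
    return [generate(s) for s in trio_specs()]


@pytest.fixture(scope="session")
def trio_genomes(trio):
    return [g for g, _t in trio]
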