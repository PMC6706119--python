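import pytest

from crisprkit import (
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    Transcript,
)
from crisprkit.fixtures import (
    FixtureSpec,
    GeneDef,
    PlantedGuide,
    PlantedOffTarget,
    generate_fixture,
)


@pytest.fixture
def toy_genome() -> GenomeSequence:
    # one candidate + site at 0 (AGG PAM); lowercase block marks a repeat
    return GenomeSequence(
        {
            "c1": "AAAAAAAAAAAAAAAAAAAAAGGA" + "acgtacgtacgt" + "CCCCTTTTGGGG",
            "c2": "ACGT" * 30,
        },
        "toy",
    )


@pytest.fixture
def simple_gene() -> GeneModel:
    exons_a = [GenomicInterval("c1", 0, 10, "+"), GenomicInterval("c1", 20, 30, "+")]
    exons_b = [GenomicInterval("c1", 5, 15, "+"), GenomicInterval("c1", 20, 30, "+")]
    return GeneModel(
        "GENEA",
        {"ENSG0001"},
        [Transcript("tx1", "c1", "+", exons_a), Transcript("tx2", "c1", "+", exons_b)],
    )


@pytest.fixture(scope="session")
def planted(tmp_path_factory):
    """A verified synthetic genome: one guide, four 4-mismatch off-targets,
    one 5-mismatch plant that must stay invisible at budget 4, plus a gene."""
    spec = FixtureSpec(
        contig_lengths={"chr1": 5000, "chr2": 3000},
        seed=11,
        guides=[
            PlantedGuide(
                "chr1",
                1000,
                "+",
                offtargets=[
                    PlantedOffTarget("chr1", 2000, "+", (3, 7, 12, 18)),
                    PlantedOffTarget("chr2", 500, "-", (1, 5, 9, 14)),
                    PlantedOffTarget("chr2", 1500, "+", (2, 6, 10, 16)),
                    PlantedOffTarget("chr1", 4000, "-", (4, 8, 13, 19)),
                    PlantedOffTarget("chr1", 3000, "+", (2, 5, 9, 13, 17)),
                ],
            )
        ],
        genes=[
            GeneDef(
                "GENEA",
                "chr1",
                "+",
                [("tx1", [(900, 1100), (1900, 2100)])],
            ),
            GeneDef("GENEB", "chr2", "-", [("tx2", [(400, 600), (1400, 1600)])]),
        ],
    )
    outdir = tmp_path_factory.mktemp("fixture")
    return generate_fixture(spec, outdir)
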