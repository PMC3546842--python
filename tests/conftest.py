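import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cisscan import ConsensusMotif, LocusModel


@pytest.fixture
def plus_locus() -> LocusModel:
    """6-exon '+' gene 1001..2000 with 100-bp exons, flank 500."""
    exons = tuple((1001 + i * 180, 1001 + i * 180 + 99) for i in range(6))
    return LocusModel(
        locus_id="gplus",
        chrom="chrT",
        span_start=1001,
        span_end=exons[-1][1],
        gene_strand="+",
        tss=1001,
        exons=exons,
        flank_bp=500,
    )


@pytest.fixture
def minus_locus() -> LocusModel:
    """6-exon '-' gene mirroring plus_locus (exon 1 is genomically rightmost)."""
    exons = tuple((1001 + i * 180, 1001 + i * 180 + 99) for i in range(6))
    return LocusModel(
        locus_id="gminus",
        chrom="chrT",
        span_start=1001,
        span_end=exons[-1][1],
        gene_strand="-",
        tss=exons[-1][1],
        exons=exons,
        flank_bp=500,
    )


@pytest.fixture
def e4bp4() -> ConsensusMotif:
    return ConsensusMotif("E4BP4", "GTTACGTAAC")


@pytest.fixture
def xfd1() -> ConsensusMotif:
    return ConsensusMotif("XFD1", "TGTTTATTT")
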