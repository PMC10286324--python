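import pytest

from fusionburden.io import Breakpoint, CohortConfig, FusionCall, GeneRecord
from fusionburden.summary import CohortCallSet


@pytest.fixture
def make_call():
    """Factory for fusion calls with sensible defaults."""

    def _make(
        sample_id="S1",
        gene1="A",
        gene2="B",
        confidence="high",
        split_reads1=1,
        split_reads2=1,
        discordant_mates=0,
        breakpoint1="1:100",
        breakpoint2="2:200",
        **kwargs,
    ):
        return FusionCall(
            sample_id=sample_id,
            gene1=gene1,
            gene2=gene2,
            breakpoint1=Breakpoint.parse(breakpoint1),
            breakpoint2=Breakpoint.parse(breakpoint2),
            confidence=confidence,
            split_reads1=split_reads1,
            split_reads2=split_reads2,
            discordant_mates=discordant_mates,
            **kwargs,
        )

    return _make


@pytest.fixture
def make_cohort():
    """Factory wrapping calls into a CohortCallSet."""

    def _make(calls, name="C", role="discovery", preservation="fresh_frozen", n_samples=None):
        n = n_samples if n_samples is not None else max(len({c.sample_id for c in calls}), 1)
        return CohortCallSet(CohortConfig(name, role, preservation, n), list(calls))

    return _make


@pytest.fixture
def gene_table():
    """Small annotation covering the partner classes the annotator handles."""

    def gene(symbol, chrom, start, end, gene_class="protein_coding", host_of=(), gene_sets=()):
        return GeneRecord(
            symbol=symbol,
            chrom=chrom,
            start=start,
            end=end,
            strand="+",
            gene_class=gene_class,
            host_of=tuple(host_of),
            gene_sets=frozenset(gene_sets),
        )

    return {
        "TMPRSS2": gene("TMPRSS2", "21", 41_464_300, 41_531_116, gene_sets=["androgen_response"]),
        "ERG": gene("ERG", "21", 38_380_027, 38_661_780, gene_sets=["ETS_family"]),
        "ELK4": gene("ELK4", "1", 205_588_395, 205_602_000, gene_sets=["ETS_family"]),
        "TTC6": gene("TTC6", "14", 37_549_702, 38_124_927, host_of=["SNORD127"]),
        "SNORD127": gene("SNORD127", "14", 37_600_000, 37_600_110, gene_class="snoRNA"),
        "MIPOL1": gene("MIPOL1", "14", 37_245_170, 37_593_479, gene_sets=["tumor_suppressor"]),
        "RNU4-2": gene("RNU4-2", "12", 120_291_825, 120_291_966, gene_class="snRNA"),
        "NEAR1": gene("NEAR1", "5", 1_000_000, 1_050_000),
        "NEAR2": gene("NEAR2", "5", 1_080_000, 1_120_000),  # 30 kb gap to NEAR1
        "FAR1": gene("FAR1", "5", 9_000_000, 9_050_000),
        "OTHER1": gene("OTHER1", "8", 2_000_000, 2_040_000),
    }
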