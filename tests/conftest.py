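import pandas as pd
import pytest

from riboq import Transcript, TranscriptomeFixture, generate_transcriptome


@pytest.fixture(scope="session")
def small_tx() -> TranscriptomeFixture:
    """Ten random genes, enough for alignment/occupancy unit tests."""
    return generate_transcriptome(10, (60, 90), seed=101)


@pytest.fixture(scope="session")
def utr_tx() -> TranscriptomeFixture:
    """Genes with a 30 nt 5' UTR so reads can sit upstream of the start codon."""
    return generate_transcriptome(6, (60, 90), seed=102, utr5_length=30)


@pytest.fixture()
def two_gene_tx() -> TranscriptomeFixture:
    """Two hand-built genes sharing no long substring."""
    cds_a = "ATG" + "GAC" * 10 + "AAA" * 10 + "TAA"
    cds_b = "ATG" + "CCT" * 10 + "GGT" * 10 + "TGA"
    return TranscriptomeFixture(
        [Transcript("geneA", cds_a), Transcript("geneB", cds_b)],
        {"geneA": 3.0, "geneB": 1.0},
    )


def make_asites(rows) -> pd.DataFrame:
    return pd.DataFrame(
        rows, columns=["read_id", "gene_id", "a_site_codon_index", "codon"]
    )
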