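import pytest

from henpop.core_data import GenotypeCall, GenotypeTable, LocusDef, SampleRecord
from henpop.datasets import counts_fixture_table


@pytest.fixture(scope="session")
def study_counts_table() -> GenotypeTable:
    """117-sample genotype table expanded from the published genotype counts."""
    return counts_fixture_table()


@pytest.fixture()
def tiny_table() -> GenotypeTable:
    """Three samples, two loci, one missing call, mixed breeds."""
    loci = [LocusDef("SNP1", 130, "A", "G"), LocusDef("SNP2", 301, "C", "T")]
    samples = [
        SampleRecord("h1", "PH", {"SNP1": GenotypeCall.from_string("GA"),
                                  "SNP2": GenotypeCall.from_string("CC")}),
        SampleRecord("h2", "PH", {"SNP1": GenotypeCall.from_string("AA"),
                                  "SNP2": GenotypeCall.from_string(".")}),
        SampleRecord("h3", "C", {"SNP1": GenotypeCall.from_string("GG"),
                                 "SNP2": GenotypeCall.from_string("TT")}),
    ]
    return GenotypeTable(loci, samples)
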