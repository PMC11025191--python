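import pytest
from hypothesis import HealthCheck, settings

import ndminer as nd

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(pmid, title, abstract="", year=2010, journal="J Test"):
    return nd.PublicationRecord(
        pmid=str(pmid), title=title, abstract=abstract, year=year, journal=journal
    )


@pytest.fixture(scope="session")
def vocabs():
    return nd.default_vocabulary_set()


@pytest.fixture(scope="session")
def registry():
    """Six well-known AD/ND genes; aliases chosen not to collide with any
    vocabulary token, so synthetic truth stays exact."""
    return [
        nd.GeneEntry("APOE", ("AD2", "LPG")),
        nd.GeneEntry("TREM2", ("TREM2a",)),
        nd.GeneEntry("APP",),
        nd.GeneEntry("PSEN1", ("PS1",)),
        nd.GeneEntry("MAPT", ("MTBT1",)),
        nd.GeneEntry("SNCA", ("NACP",)),
    ]


@pytest.fixture()
def registry_tsv(tmp_path):
    path = tmp_path / "gene_info.tsv"
    path.write_text(
        "#tax_id\tGeneID\tSymbol\tSynonyms\n"
        "9606\t348\tAPOE\tAD2|LPG\n"
        "9606\t54209\tTREM2\tTREM2a\n"
        "9606\t351\tAPP\t-\n"
        "9606\t5663\tPSEN1\tPS1\n"
        "9606\t4137\tMAPT\tMTBT1\n"
        "9606\t6622\tSNCA\tNACP\n",
        encoding="utf-8",
    )
    return path
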