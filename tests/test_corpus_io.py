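"""Corpus reading/writing and query construction."""

import json

import pytest
from hypothesis import given, strategies as st

import ndminer as nd
from ndminer.errors import CorpusParseError, DuplicatePmidError, SchemaError

from conftest import make_record

PUBMED_XML = """<?xml version="1.0" encoding="UTF-8"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID Version="1">101</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>2015</Year></PubDate></JournalIssue>
          <Title>Journal One</Title>
        </Journal>
        <ArticleTitle>First article about APOE.</ArticleTitle>
        <Abstract>
          <AbstractText Label="BACKGROUND">Part one.</AbstractText>
          <AbstractText Label="METHODS">Part two.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID Version="1">102</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><MedlineDate>2004 Jan-Feb</MedlineDate></PubDate></JournalIssue>
          <Title>Journal Two</Title>
        </Journal>
        <ArticleTitle>Second article, no abstract.</ArticleTitle>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID Version="1">103</PMID>
      <Article>
        <Journal>
          <JournalIssue><PubDate><Year>1999</Year></PubDate></JournalIssue>
          <Title>Journal Three</Title>
        </Journal>
        <ArticleTitle>Third article.</ArticleTitle>
        <Abstract><AbstractText>Single block.</AbstractText></Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


class TestReadPubmedXml:
    def test_fixture_articles(self, tmp_path):
        path = tmp_path / "set.xml"
        path.write_text(PUBMED_XML, encoding="utf-8")
        corpus = nd.read_pubmed_xml(path)
        assert len(corpus) == 3
        first = corpus.get("101")
        assert first.abstract == "Part one. Part two."  # blocks joined, labels dropped
        assert first.year == 2015
        assert first.journal == "Journal One"
        assert corpus.get("102").abstract == ""
        assert corpus.get("102").year == 2004  # MedlineDate fallback
        assert corpus.get("103").year == 1999

    def test_empty_article_set(self, tmp_path):
        path = tmp_path / "empty.xml"
        path.write_text("<PubmedArticleSet></PubmedArticleSet>", encoding="utf-8")
        assert len(nd.read_pubmed_xml(path)) == 0

    def test_malformed_xml_names_offset(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<PubmedArticleSet><Pubmed", encoding="utf-8")
        with pytest.raises(CorpusParseError, match="byte offset"):
            nd.read_pubmed_xml(path)

    def test_article_without_pmid_is_skipped(self, tmp_path, caplog):
        xml = (
            "<PubmedArticleSet><PubmedArticle><MedlineCitation>"
            "<Article><ArticleTitle>No pmid.</ArticleTitle></Article>"
            "</MedlineCitation></PubmedArticle></PubmedArticleSet>"
        )
        path = tmp_path / "nopmid.xml"
        path.write_text(xml, encoding="utf-8")
        with caplog.at_level("WARNING"):
            corpus = nd.read_pubmed_xml(path)
        assert len(corpus) == 0
        assert any("PMID" in m for m in caplog.messages)


class TestRecordsTable:
    def test_header_only_csv(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("pmid,year,title,abstract,journal\n", encoding="utf-8")
        assert len(nd.read_records_table(path)) == 0

    def test_duplicate_pmid_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "pmid,year,title,abstract,journal\n"
            "123,2010,T one,A,J\n123,2011,T two,B,J\n",
            encoding="utf-8",
        )
        with pytest.raises(DuplicatePmidError, match="123"):
            nd.read_records_table(path)

    def test_json_list(self, tmp_path):
        rows = [
            {"pmid": str(i), "title": f"T{i}", "abstract": "", "year": 2000 + i, "journal": "J"}
            for i in range(1, 6)
        ]
        path = tmp_path / "recs.json"
        path.write_text(json.dumps(rows), encoding="utf-8")
        corpus = nd.read_records_table(path)
        assert len(corpus) == 5
        assert corpus.get("3").year == 2003

    def test_missing_column_lists_names(self, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text("pmid,title\n1,T\n", encoding="utf-8")
        with pytest.raises(SchemaError) as err:
            nd.read_records_table(path)
        for name in ("abstract", "journal", "year"):
            assert name in str(err.value)


class TestGsppCsv:
    def test_empty_profile_writes_header_only(self, tmp_path):
        gene = nd.GeneEntry("APOE")
        profile = nd.GenePublicationProfile(gene=gene, records=())
        path = tmp_path / "empty.csv"
        nd.write_gspp_csv(profile, path)
        assert path.read_text(encoding="utf-8").strip() == "pmid,year,title,abstract,journal"

    def test_two_records_three_lines(self, tmp_path):
        recs = (make_record(1, "T1"), make_record(2, "T2"))
        profile = nd.GenePublicationProfile(gene=nd.GeneEntry("APOE"), records=recs)
        path = tmp_path / "two.csv"
        nd.write_gspp_csv(profile, path)
        assert len(path.read_text(encoding="utf-8").splitlines()) == 3

    def test_round_trip_identity(self, tmp_path):
        recs = [
            make_record(1, "Title, with comma", 'Abstract with "quotes"\nand a newline', 2001),
            make_record(2, "Plain", "", 0),
        ]
        path = tmp_path / "rt.csv"
        nd.write_records_csv(recs, path)
        back = nd.read_records_table(path)
        assert list(back) == recs


_field_text = st.text(
    alphabet=st.characters(blacklist_categories=("Cs",), blacklist_characters="\r"),
    max_size=40,
)


@given(
    rows=st.lists(
        st.tuples(
            st.integers(min_value=1, max_value=10**7),
            _field_text.filter(lambda s: s.strip()),
            _field_text,
            st.one_of(st.just(0), st.integers(min_value=1800, max_value=2026)),
            _field_text,
        ),
        max_size=8,
        unique_by=lambda r: r[0],
    )
)
def test_csv_round_trip_preserves_all_fields(tmp_path_factory, rows):
    """write -> read preserves (pmid, year, title, abstract, journal) exactly."""
    records = [
        nd.PublicationRecord(pmid=str(p), title=t, abstract=a, year=y, journal=j)
        for p, t, a, y, j in rows
    ]
    path = tmp_path_factory.mktemp("rt") / "corpus.csv"
    nd.write_records_csv(records, path)
    assert list(nd.read_records_table(path)) == records


class TestGeneQuery:
    def test_symbol_only(self):
        assert nd.build_gene_query(nd.GeneEntry("APOE")) == "APOE[Title/Abstract]"

    def test_symbol_and_aliases(self):
        q = nd.build_gene_query(nd.GeneEntry("APOE", ("AD2", "LPG")))
        assert q == "APOE[Title/Abstract] OR AD2[Title/Abstract] OR LPG[Title/Abstract]"

    def test_duplicate_surface_emitted_once(self):
        q = nd.build_gene_query(nd.GeneEntry("APOE", ("apoe", "LPG")))
        assert q == "APOE[Title/Abstract] OR LPG[Title/Abstract]"
        assert q.count("APOE") == 1
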