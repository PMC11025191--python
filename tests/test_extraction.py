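"""Category extraction, pruning, corpus summary and summary serialization."""

import pytest

import ndminer as nd

from conftest import make_record


def _filtered_profile(gene, records, vocabs):
    return nd.filter_nd(nd.build_gspp(gene, nd.Corpus(records)), vocabs.dementia)


@pytest.fixture()
def apoe_profile(vocabs):
    """Three APOE + alzheimer records with known planted content."""
    records = [
        make_record(
            11, "APOE in alzheimer disease",
            "Changes in the hippocampus and thalamus were found.", 2004
        ),
        make_record(
            12, "APOE cohort", "This alzheimer study used the 5xFAD strain. "
            "TREM2 modulates APOE signaling.", 2004
        ),
        make_record(
            13, "APOE and oxidative stress in alzheimers",
            "No other planted concepts.", 2010
        ),
    ]
    return _filtered_profile(nd.GeneEntry("APOE"), records, vocabs)


class TestYearTrend:
    def test_counts_partition_by_year(self, apoe_profile):
        trend = nd.extract_year_trend(apoe_profile)
        assert trend.counts() == {"2004": 2, "2010": 1}
        assert trend.entries["2004"].pmids == ("11", "12")

    def test_empty_profile(self, vocabs):
        profile = _filtered_profile(nd.GeneEntry("APOE"), [], vocabs)
        assert nd.extract_year_trend(profile).entries == {}

    def test_unknown_year_excluded_but_record_kept(self, vocabs):
        records = [make_record(21, "APOE in alzheimer cohorts", "", 0)]
        profile = _filtered_profile(nd.GeneEntry("APOE"), records, vocabs)
        assert len(profile) == 1
        assert nd.extract_year_trend(profile).entries == {}

    def test_sum_of_counts_equals_dated_records(self, apoe_profile):
        trend = nd.extract_year_trend(apoe_profile)
        dated = sum(1 for r in apoe_profile.records if r.year > 0)
        assert sum(trend.counts().values()) == dated

    def test_requires_filtered_profile(self, vocabs):
        profile = nd.build_gspp(nd.GeneEntry("APOE"), nd.Corpus([]))
        with pytest.raises(ValueError):
            nd.extract_year_trend(profile)


class TestTermCategory:
    def test_record_counts_once_per_subcategory(self, apoe_profile, vocabs):
        regions = nd.extract_term_category(apoe_profile, vocabs.brain_region)
        assert regions.counts() == {"Hippocampus": 1, "Thalamus": 1}
        assert regions.entries["Hippocampus"].pmids == ("11",)

    def test_unmatched_entries_absent(self, apoe_profile, vocabs):
        regions = nd.extract_term_category(apoe_profile, vocabs.brain_region)
        assert "Amygdala" not in regions.entries

    def test_dementia_prefix_stems(self, apoe_profile, vocabs):
        dem = nd.extract_term_category(
            apoe_profile, vocabs.dementia, mode="prefix", category_name="dementia_type"
        )
        assert dem.counts() == {"Alzheimer's Disease": 3}

    def test_mouse_model_and_keyword(self, apoe_profile, vocabs):
        strains = nd.extract_term_category(apoe_profile, vocabs.mouse_model)
        assert strains.counts() == {"5xFAD": 1}
        keywords = nd.extract_term_category(apoe_profile, vocabs.keyword)
        assert keywords.counts() == {"oxidative stress": 1}


class TestCooccurringGenes:
    def test_nominal_context_detected(self, apoe_profile, registry):
        cooc = nd.extract_cooccurring_genes(apoe_profile, registry)
        assert cooc.counts() == {"TREM2": 1}
        assert cooc.entries["TREM2"].pmids == ("12",)

    def test_focal_gene_never_its_own_subcategory(self, apoe_profile, registry):
        cooc = nd.extract_cooccurring_genes(apoe_profile, registry)
        assert "APOE" not in cooc.entries

    def test_no_other_gene_mentions(self, vocabs, registry):
        records = [make_record(31, "APOE alone in alzheimer work", "", 2012)]
        profile = _filtered_profile(nd.GeneEntry("APOE"), records, vocabs)
        assert nd.extract_cooccurring_genes(profile, registry).entries == {}

    def test_gated_counts_bounded_by_ungated(self, registry, vocabs):
        spec = nd.random_spec(registry, n_records=100, seed=21)
        corpus, _ = nd.generate_corpus(spec, registry, vocabs)
        for gene in registry[:2]:
            profile = nd.filter_nd(nd.build_gspp(gene, corpus), vocabs.dementia)
            gated = nd.extract_cooccurring_genes(profile, registry, pos_gating=True)
            ungated = nd.extract_cooccurring_genes(profile, registry, pos_gating=False)
            for symbol, entry in gated.entries.items():
                assert entry.count <= ungated.entries[symbol].count


class TestPruning:
    def _summary(self, symbol, region_hits):
        categories = {name: nd.CategoryProfile(name, {}) for name in nd.CATEGORY_NAMES}
        categories["year_trend"] = nd.CategoryProfile.from_pmid_map("year_trend", {"2010": ["1"]})
        if region_hits:
            categories["brain_region"] = nd.CategoryProfile.from_pmid_map(
                "brain_region", {"Hippocampus": region_hits}
            )
        return nd.GeneSummary(gene_symbol=symbol, categories=categories)

    def test_contentless_summary_dropped_despite_trend(self):
        summaries = [self._summary("GENEA", []), self._summary("GENEB", ["1"])]
        kept = nd.prune_profiles(summaries)
        assert [s.gene_symbol for s in kept] == ["GENEB"]

    def test_single_region_hit_survives(self):
        kept = nd.prune_profiles([self._summary("GENEB", ["1"])])
        assert len(kept) == 1

    def test_idempotent(self):
        summaries = [self._summary("GENEA", []), self._summary("GENEB", ["1"])]
        once = nd.prune_profiles(summaries)
        assert nd.prune_profiles(once) == once


class TestSummarizeCorpus:
    def test_year_subcategories_counted(self, apoe_profile, registry, vocabs):
        summary = nd.build_gene_summary(apoe_profile, registry, vocabs)
        table = nd.summarize_corpus([summary]).set_index("category")
        assert table.loc["year_trend", "n_subcategories"] == 2
        assert table.loc["year_trend", "n_publications"] == 3
        assert table.loc["brain_region", "n_subcategories"] == 2

    def test_no_summaries_all_zero(self):
        table = nd.summarize_corpus([])
        assert len(table) == 6
        assert (table[["n_subcategories", "n_publications", "n_attributions"]] == 0).all().all()

    def test_distinct_vs_attribution_totals(self, registry, vocabs):
        """A pmid attributed to several genes counts once in n_publications
        but once per attribution in n_attributions."""
        spec = nd.random_spec(registry, n_records=120, seed=31)
        corpus, _ = nd.generate_corpus(spec, registry, vocabs)
        summaries = [
            nd.build_gene_summary(
                nd.filter_nd(nd.build_gspp(g, corpus), vocabs.dementia), registry, vocabs
            )
            for g in registry
        ]
        table = nd.summarize_corpus(summaries).set_index("category")
        assert (table["n_attributions"] >= table["n_publications"]).all()

    def test_matches_generator_truth(self, registry, vocabs):
        spec = nd.random_spec(registry, n_records=100, seed=32)
        _corpus, truth = nd.generate_corpus(spec, registry, vocabs)
        report = nd.run_end_to_end(spec, registry, vocabs)
        assert report.all_match


class TestSummaryJson:
    def test_round_trip_object_identity(self, apoe_profile, registry, vocabs, tmp_path):
        summary = nd.build_gene_summary(apoe_profile, registry, vocabs)
        path = tmp_path / "apoe.json"
        nd.write_summary_json(summary, path)
        assert nd.read_summary_json(path) == summary

    def test_entry_invariants(self, apoe_profile, registry, vocabs):
        summary = nd.build_gene_summary(apoe_profile, registry, vocabs)
        profile_pmids = set(apoe_profile.pmids)
        for name in nd.CATEGORY_NAMES:
            for entry in summary.category(name).entries.values():
                assert entry.count == len(entry.pmids) > 0
                assert len(set(entry.pmids)) == len(entry.pmids)
                assert set(entry.pmids) <= profile_pmids
                assert list(entry.pmids) == sorted(entry.pmids, key=int)
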