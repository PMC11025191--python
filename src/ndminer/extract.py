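"""Per-gene information extraction: the six category profiles, profile
pruning and the corpus-level summary table.

For each disease-filtered GSPP the pipeline extracts six categories of
information: yearly publication trend, dementia-type occurrence, brain-region
occurrence, mouse-model occurrence, keyword occurrence and co-occurring
genes.  Each category profile maps a subcategory key (a year string, a
canonical vocabulary name or an official gene symbol) to a publication count
plus the sorted list of contributing PMIDs — mirroring the two-attribute
(count, PMIDs) storage layout of the downstream database.

Co-occurring gene detection is POS-gated: only nominal/adjectival tokens of
the title and abstract are candidates for symbol matching, which suppresses
spurious hits from verbs and function words.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .profiles import GenePublicationProfile
from .text import DEFAULT_POS_TAGS, match_term, pos_gate, tokenize
from .vocab import GeneEntry, TermVocabulary, VocabularySet

__all__ = [
    "CategoryEntry",
    "CategoryProfile",
    "GeneSummary",
    "CATEGORY_NAMES",
    "extract_year_trend",
    "extract_term_category",
    "extract_cooccurring_genes",
    "build_gene_summary",
    "prune_profiles",
    "summarize_corpus",
    "write_summary_json",
    "read_summary_json",
]

logger = logging.getLogger(__name__)

CATEGORY_NAMES = (
    "year_trend",
    "dementia_type",
    "brain_region",
    "mouse_model",
    "keyword",
    "cooccurring_gene",
)

#: The three content categories whose joint emptiness triggers pruning.
PRUNE_CATEGORIES = ("brain_region", "mouse_model", "keyword")


def _sort_pmids(pmids: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(set(pmids), key=int))


@dataclass(frozen=True)
class CategoryEntry:
    """Publication count plus the sorted PMIDs behind it."""

    count: int
    pmids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.count != len(self.pmids):
            raise ValueError("count must equal the number of pmids")


@dataclass(frozen=True)
class CategoryProfile:
    """One category's extraction result; zero-count entries are absent."""

    category: str
    entries: Mapping[str, CategoryEntry]

    @classmethod
    def from_pmid_map(cls, category: str, pmid_map: Mapping[str, Iterable[str]]) -> "CategoryProfile":
        entries = {}
        # subcategory keys sorted for deterministic serialization; year keys
        # sort chronologically, term keys alphabetically
        for key in sorted(pmid_map):
            pmids = _sort_pmids(pmid_map[key])
            if pmids:
                entries[key] = CategoryEntry(count=len(pmids), pmids=pmids)
        return cls(category=category, entries=entries)

    def counts(self) -> dict[str, int]:
        return {k: e.count for k, e in self.entries.items()}

    def all_pmids(self) -> set[str]:
        return {p for e in self.entries.values() for p in e.pmids}

    def is_empty(self) -> bool:
        return not self.entries


@dataclass(frozen=True)
class GeneSummary:
    """All six category profiles for one gene."""

    gene_symbol: str
    categories: Mapping[str, CategoryProfile]

    def __post_init__(self) -> None:
        missing = set(CATEGORY_NAMES) - set(self.categories)
        if missing:
            raise ValueError(f"summary for {self.gene_symbol} missing categories: {missing}")

    def category(self, name: str) -> CategoryProfile:
        return self.categories[name]


# ---------------------------------------------------------------------------
# Extractors
# ---------------------------------------------------------------------------


def _require_filtered(profile: GenePublicationProfile) -> None:
    if not profile.nd_filtered:
        raise ValueError(
            f"profile for {profile.gene.symbol}: extraction requires the disease filter"
        )


def extract_year_trend(profile: GenePublicationProfile) -> CategoryProfile:
    """Stratify the profile's publications by year.

    Records with unknown year (0) are excluded; the per-year counts
    partition the remaining records exactly.
    """
    _require_filtered(profile)
    by_year: dict[str, list[str]] = {}
    for rec in profile.records:
        if rec.year > 0:
            by_year.setdefault(f"{rec.year:04d}", []).append(rec.pmid)
    return CategoryProfile.from_pmid_map("year_trend", by_year)


def extract_term_category(
    profile: GenePublicationProfile,
    vocab: TermVocabulary,
    mode: str = "exact",
    category_name: str | None = None,
) -> CategoryProfile:
    """Collect, per canonical vocabulary entry, the PMIDs whose title or
    abstract contains one of its variants.

    A record counts at most once per subcategory regardless of mention
    count, but may appear under multiple subcategories.
    """
    _require_filtered(profile)
    hits: dict[str, list[str]] = {}
    for rec in profile.records:
        toks = tokenize(rec.text)
        tokset = set(toks)
        for name, variants in vocab.entries.items():
            if match_term(toks, variants, mode=mode, token_set=tokset):
                hits.setdefault(name, []).append(rec.pmid)
    return CategoryProfile.from_pmid_map(category_name or vocab.category, hits)


def extract_cooccurring_genes(
    profile: GenePublicationProfile,
    registry: Sequence[GeneEntry],
    *,
    pos_gating: bool = True,
    allowed_tags: frozenset[str] = DEFAULT_POS_TAGS,
) -> CategoryProfile:
    """Aggregate, per co-occurring official symbol, the profile PMIDs where
    that registry gene is mentioned.

    With ``pos_gating`` (default) symbol matching runs against the
    POS-gated token stream; disabling it matches the full token stream.
    The focal gene itself is always excluded.
    """
    _require_filtered(profile)
    focal = profile.gene.symbol
    others = [(g.symbol, g.variants()) for g in registry if g.symbol != focal]
    hits: dict[str, list[str]] = {}
    for rec in profile.records:
        toks = pos_gate(rec.text, allowed_tags) if pos_gating else tokenize(rec.text)
        tokset = set(toks)
        for symbol, variants in others:
            if match_term(toks, variants, mode="exact", token_set=tokset):
                hits.setdefault(symbol, []).append(rec.pmid)
    return CategoryProfile.from_pmid_map("cooccurring_gene", hits)


def build_gene_summary(
    profile: GenePublicationProfile,
    registry: Sequence[GeneEntry],
    vocabularies: VocabularySet,
    *,
    dementia_mode: str = "prefix",
    term_mode: str = "exact",
    pos_gating: bool = True,
    allowed_tags: frozenset[str] = DEFAULT_POS_TAGS,
) -> GeneSummary:
    """Run all six extractors on one disease-filtered profile.

    Dementia-type occurrence uses the same prefix stems as the disease
    filter; the other term categories match exact token n-grams.
    """
    return GeneSummary(
        gene_symbol=profile.gene.symbol,
        categories={
            "year_trend": extract_year_trend(profile),
            "dementia_type": extract_term_category(
                profile, vocabularies.dementia, mode=dementia_mode, category_name="dementia_type"
            ),
            "brain_region": extract_term_category(profile, vocabularies.brain_region, mode=term_mode),
            "mouse_model": extract_term_category(profile, vocabularies.mouse_model, mode=term_mode),
            "keyword": extract_term_category(profile, vocabularies.keyword, mode=term_mode),
            "cooccurring_gene": extract_cooccurring_genes(
                profile, registry, pos_gating=pos_gating, allowed_tags=allowed_tags
            ),
        },
    )


# ---------------------------------------------------------------------------
# Pruning and corpus summary
# ---------------------------------------------------------------------------


def prune_profiles(summaries: Sequence[GeneSummary]) -> list[GeneSummary]:
    """Drop summaries empty in all three content categories.

    A gene survives if any of brain_region, mouse_model or keyword has at
    least one hit; survivors are returned unchanged, in order.
    """
    kept = [
        s for s in summaries
        if not all(s.category(c).is_empty() for c in PRUNE_CATEGORIES)
    ]
    logger.info("pruned=%d kept=%d", len(summaries) - len(kept), len(kept))
    return kept


def summarize_corpus(summaries: Sequence[GeneSummary]) -> pd.DataFrame:
    """Corpus-level summary: per category, the number of distinct
    subcategories observed across all genes and the publication totals.

    ``n_publications`` counts distinct PMIDs per category across all gene
    summaries; ``n_attributions`` is the raw sum of per-gene subcategory
    counts (a PMID attributed to several genes or subcategories counts each
    time).  Both readings of "total publications" are exposed.
    """
    rows = []
    for name in CATEGORY_NAMES:
        subcats: set[str] = set()
        pmids: set[str] = set()
        attributions = 0
        for summary in summaries:
            prof = summary.category(name)
            subcats.update(prof.entries)
            pmids.update(prof.all_pmids())
            attributions += sum(e.count for e in prof.entries.values())
        rows.append(
            {
                "category": name,
                "n_subcategories": len(subcats),
                "n_publications": len(pmids),
                "n_attributions": attributions,
            }
        )
    return pd.DataFrame(rows, columns=["category", "n_subcategories", "n_publications", "n_attributions"])


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def _summary_to_dict(summary: GeneSummary) -> dict:
    return {
        "gene": summary.gene_symbol,
        "categories": {
            name: {
                key: {"count": entry.count, "pmids": list(entry.pmids)}
                for key, entry in summary.category(name).entries.items()
            }
            for name in CATEGORY_NAMES
        },
    }


def _summary_from_dict(doc: dict) -> GeneSummary:
    categories = {}
    for name in CATEGORY_NAMES:
        raw = doc["categories"].get(name, {})
        entries = {
            key: CategoryEntry(count=int(val["count"]), pmids=tuple(val["pmids"]))
            for key, val in raw.items()
        }
        categories[name] = CategoryProfile(category=name, entries=entries)
    return GeneSummary(gene_symbol=doc["gene"], categories=categories)


def write_summary_json(summary: GeneSummary, path: str | Path) -> None:
    """Write a gene summary as deterministic (sorted-key) JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_summary_to_dict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summary_json(path: str | Path) -> GeneSummary:
    with open(path, "r", encoding="utf-8") as fh:
        return _summary_from_dict(json.load(fh))
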