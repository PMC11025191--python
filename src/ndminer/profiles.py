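"""Gene-specific publication profiles (GSPPs) and the two cleaning filters.

A GSPP attributes publications to a gene because the gene's official symbol
or a non-stoplisted alias occurs as a token n-gram in the title or abstract.
The disease-of-focus filter then keeps only publications mentioning one of
the dementia types, via simplified-name stems matched in prefix mode
("alzheimer" hits "alzheimers").  Empty profiles are retained here; pruning
happens after information extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import ProfileStateError
from .records import Corpus, PublicationRecord
from .text import match_term, tokenize
from .vocab import GeneEntry, TermVocabulary

__all__ = ["GenePublicationProfile", "build_gspp", "filter_nd", "gene_matches", "nd_matches"]


@dataclass(frozen=True)
class GenePublicationProfile:
    gene: GeneEntry
    records: tuple[PublicationRecord, ...]
    nd_filtered: bool = False

    @property
    def pmids(self) -> tuple[str, ...]:
        return tuple(r.pmid for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


def gene_matches(gene: GeneEntry, record: PublicationRecord) -> bool:
    """True iff the gene's symbol or an alias occurs in title or abstract."""
    return match_term(tokenize(record.text), gene.variants(), mode="exact")


def nd_matches(record: PublicationRecord, dementia_vocab: TermVocabulary, mode: str = "prefix") -> bool:
    """True iff at least one dementia-type variant occurs in title or abstract."""
    return match_term(tokenize(record.text), dementia_vocab.all_variants(), mode=mode)


def build_gspp(gene: GeneEntry, corpus: Corpus) -> GenePublicationProfile:
    """Attribute corpus records to a gene by token-level symbol/alias match."""
    variants = gene.variants()
    kept = tuple(
        rec for rec in corpus if match_term(tokenize(rec.text), variants, mode="exact")
    )
    return GenePublicationProfile(gene=gene, records=kept, nd_filtered=False)


def filter_nd(
    profile: GenePublicationProfile,
    dementia_vocab: TermVocabulary,
    mode: str = "prefix",
) -> GenePublicationProfile:
    """Apply the disease-of-focus filter to a profile.

    Keeps records matching at least one dementia-type entry, preserving
    record order.  Filtering an already-filtered profile is a state error;
    idempotence holds on record sets, not on the operation.
    """
    if profile.nd_filtered:
        raise ProfileStateError(
            f"profile for {profile.gene.symbol} is already disease-filtered"
        )
    variants = dementia_vocab.all_variants()
    kept = tuple(
        rec for rec in profile.records if match_term(tokenize(rec.text), variants, mode=mode)
    )
    return replace(profile, records=kept, nd_filtered=True)
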