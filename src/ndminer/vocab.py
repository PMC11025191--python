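"""Controlled vocabularies: gene registry, dementia types, brain regions,
mouse-model strains and expert keywords.

A :class:`TermVocabulary` maps canonical concept names to lists of variant
token sequences; variants are tokenized with the same rules as publication
text (:func:`ndminer.text.tokenize`) so that dictionary matching is
self-consistent.  The gene registry is read from NCBI ``gene_info``-style
TSV (pipe-separated synonyms, ``-`` sentinel for none) and passed through an
ambiguous-symbol stoplist: alias surface forms that are common English words
or two characters or shorter would massively over-match in title/abstract
token streams (the classic example is the APOE alias "AD") and are excluded
from matching by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ConfigError, SchemaError
from .text import tokenize

__all__ = [
    "GeneEntry",
    "TermVocabulary",
    "VocabularySet",
    "VOCAB_CATEGORIES",
    "DEFAULT_ALIAS_STOPLIST",
    "load_gene_registry",
    "load_term_vocabulary",
    "default_dementia_vocabulary",
    "default_brain_region_vocabulary",
    "default_keyword_vocabulary",
    "default_mouse_model_vocabulary",
    "default_vocabulary_set",
]

VOCAB_CATEGORIES = ("dementia", "brain_region", "mouse_model", "keyword")

#: Alias surface forms excluded from token matching: known gene aliases that
#: collide with everyday English or with ubiquitous biomedical abbreviations.
#: The two-character rule below catches the bulk ("AD", "PD", "T2"...).
DEFAULT_ALIAS_STOPLIST: frozenset[str] = frozenset(
    {
        "ad", "act", "aim", "all", "and", "arc", "camp", "can", "cell",
        "cope", "fat", "for", "impact", "kit", "large", "map", "mass",
        "men", "met", "mice", "not", "rat", "ray", "rest", "set", "type",
        "via", "was", "with",
    }
)


@dataclass(frozen=True)
class GeneEntry:
    """A gene's official symbol plus its alias surface forms."""

    symbol: str
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ConfigError("gene symbol must be non-empty")
        if any(not a for a in self.aliases):
            raise ConfigError(f"gene {self.symbol}: empty alias string")

    def surface_forms(self) -> list[str]:
        """Symbol first, then aliases, case-insensitively de-duplicated."""
        seen: set[str] = set()
        forms: list[str] = []
        for surface in (self.symbol, *self.aliases):
            key = surface.lower()
            if key not in seen:
                seen.add(key)
                forms.append(surface)
        return forms

    def variants(self) -> list[tuple[str, ...]]:
        """Normalized token sequences used for title/abstract matching.

        Multi-token aliases (hyphenated forms before normalization) become
        n-gram variants.
        """
        out: list[tuple[str, ...]] = []
        seen: set[tuple[str, ...]] = set()
        for surface in self.surface_forms():
            toks = tuple(tokenize(surface))
            if toks and toks not in seen:
                seen.add(toks)
                out.append(toks)
        return out


@dataclass(frozen=True)
class TermVocabulary:
    """A named category mapping canonical concept names to token variants."""

    category: str
    entries: Mapping[str, tuple[tuple[str, ...], ...]]

    def __post_init__(self) -> None:
        if self.category not in VOCAB_CATEGORIES:
            raise ConfigError(f"unknown vocabulary category: {self.category!r}")
        for name, variants in self.entries.items():
            if not variants:
                raise ConfigError(f"{self.category}/{name!r}: no variants")
            for variant in variants:
                if not variant:
                    raise ConfigError(f"{self.category}/{name!r}: empty variant")
                for token in variant:
                    if tokenize(token) != [token]:
                        raise ConfigError(
                            f"{self.category}/{name!r}: token {token!r} is not normalized"
                        )

    def __len__(self) -> int:
        return len(self.entries)

    def canonical_names(self) -> list[str]:
        return list(self.entries)

    def all_variants(self) -> list[tuple[str, ...]]:
        return [v for variants in self.entries.values() for v in variants]

    @classmethod
    def from_mapping(
        cls, category: str, mapping: Mapping[str, Iterable[str]]
    ) -> "TermVocabulary":
        """Build a vocabulary from raw canonical -> variant-string mapping.

        Variant strings are tokenized and normalized; a variant that
        normalizes to nothing is a configuration error.
        """
        entries: dict[str, tuple[tuple[str, ...], ...]] = {}
        for name, raw_variants in mapping.items():
            variants: list[tuple[str, ...]] = []
            raw_list = list(raw_variants)
            if not raw_list:
                raise ConfigError(f"{category}/{name!r}: no variants configured")
            for raw in raw_list:
                toks = tuple(tokenize(str(raw)))
                if not toks:
                    raise ConfigError(
                        f"{category}/{name!r}: variant {raw!r} normalizes to nothing"
                    )
                if toks not in variants:
                    variants.append(toks)
            entries[str(name)] = tuple(variants)
        return cls(category=category, entries=entries)


@dataclass(frozen=True)
class VocabularySet:
    """The four term vocabularies the pipeline consumes."""

    dementia: TermVocabulary
    brain_region: TermVocabulary
    mouse_model: TermVocabulary
    keyword: TermVocabulary

    def by_category(self) -> dict[str, TermVocabulary]:
        return {
            "dementia": self.dementia,
            "brain_region": self.brain_region,
            "mouse_model": self.mouse_model,
            "keyword": self.keyword,
        }


# ---------------------------------------------------------------------------
# Loaders
# ---------------------------------------------------------------------------


def load_term_vocabulary(path: str | Path, category: str | None = None) -> TermVocabulary:
    """Load a vocabulary from a YAML/JSON config file.

    The config maps canonical names to lists of variant strings::

        category: brain_region
        entries:
          Hippocampus: [hippocampus]
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "entries" not in doc:
        raise ConfigError(f"{path}: expected a mapping with an 'entries' key")
    cat = category or doc.get("category")
    if cat is None:
        raise ConfigError(f"{path}: no category given in file or argument")
    return TermVocabulary.from_mapping(str(cat), doc["entries"])


def _load_packaged(name: str) -> TermVocabulary:
    ref = resources.files("ndminer").joinpath("data", name)
    with resources.as_file(ref) as path:
        return load_term_vocabulary(path)


def default_dementia_vocabulary() -> TermVocabulary:
    """The seven major dementia types with their simplified-name variants."""
    return _load_packaged("dementia.yaml")


def default_brain_region_vocabulary() -> TermVocabulary:
    """The thirteen brain regions commonly studied in neurodegeneration."""
    return _load_packaged("brain_regions.yaml")


def default_keyword_vocabulary() -> TermVocabulary:
    """The 32-entry expert keyword list (synthetic snapshot, see data file)."""
    return _load_packaged("keywords_synthetic.yaml")


def default_mouse_model_vocabulary() -> TermVocabulary:
    """AD mouse-model strain names (synthetic snapshot, see data file)."""
    return _load_packaged("mouse_models_synthetic.yaml")


def default_vocabulary_set() -> VocabularySet:
    return VocabularySet(
        dementia=default_dementia_vocabulary(),
        brain_region=default_brain_region_vocabulary(),
        mouse_model=default_mouse_model_vocabulary(),
        keyword=default_keyword_vocabulary(),
    )


def load_gene_registry(
    path: str | Path,
    *,
    stoplist: frozenset[str] | set[str] = DEFAULT_ALIAS_STOPLIST,
    min_alias_len: int = 3,
) -> list[GeneEntry]:
    """Read a gene registry from NCBI ``gene_info``-style TSV.

    The file must have a ``Symbol`` column and a ``Synonyms`` column
    (case-insensitive header match; ``Synonyms`` pipe-separated, ``-`` for
    none).  Aliases that are stoplisted, shorter than ``min_alias_len``
    characters, or duplicates of the symbol are dropped.  Row order is
    preserved.
    """
    import csv

    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty registry file") from None
        lower = [h.strip().lower() for h in header]
        missing = [c for c in ("symbol", "synonyms") if c not in lower]
        if missing:
            raise SchemaError(f"{path}: missing registry columns: {', '.join(missing)}")
        i_sym = lower.index("symbol")
        i_syn = lower.index("synonyms")
        registry: list[GeneEntry] = []
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            symbol = row[i_sym].strip()
            raw_syn = row[i_syn].strip() if i_syn < len(row) else "-"
            aliases: list[str] = []
            if raw_syn and raw_syn != "-":
                for alias in raw_syn.split("|"):
                    alias = alias.strip()
                    low = alias.lower()
                    if (
                        not alias
                        or low == symbol.lower()
                        or low in stoplist
                        or len(alias) < min_alias_len
                    ):
                        continue
                    if low not in (a.lower() for a in aliases):
                        aliases.append(alias)
            registry.append(GeneEntry(symbol=symbol, aliases=tuple(aliases)))
    return registry
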