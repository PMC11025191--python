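"""Synthetic publication corpora with planted, known concept mentions.

Every pipeline stage can be checked exactly against generated data: a
:class:`CorpusSpec` states, per concept (gene symbol, dementia type, brain
region, mouse strain, keyword), exactly which record indices must mention
it, and :func:`generate_corpus` embeds those surface forms in grammatical
carrier sentences ("The gene APOE was examined in this cohort.") so that
the POS gate sees gene symbols in nominal contexts.  The derived
:class:`CorpusTruth` is pure plan arithmetic; the generator independently
validates every record against the full active vocabularies and registry
and refuses to emit a corpus in which any concept matches where it was not
planted (or fails to match where it was).

Generation is deterministic: the same spec and seed produce a byte-identical
corpus.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError, PlantCollisionError
from .extract import (
    CATEGORY_NAMES,
    CategoryProfile,
    GeneSummary,
    build_gene_summary,
    prune_profiles,
)
from .profiles import build_gspp, filter_nd
from .records import Corpus, PublicationRecord
from .text import match_term, pos_gate, tokenize
from .vocab import GeneEntry, VocabularySet, default_vocabulary_set

__all__ = [
    "ConceptPlant",
    "CorpusSpec",
    "CorpusTruth",
    "EndToEndReport",
    "PLANT_KINDS",
    "generate_corpus",
    "run_end_to_end",
    "random_spec",
    "load_spec",
    "save_spec",
    "DEFAULT_FILLER",
]

PLANT_KINDS = ("gene", "dementia", "brain_region", "mouse_model", "keyword")

#: Neutral filler words; screened against the active vocabularies at
#: generation time, so accidental concept mentions are impossible.
DEFAULT_FILLER: tuple[str, ...] = (
    "analysis", "approach", "baseline", "comparison", "context", "criteria",
    "dataset", "design", "discussion", "distribution", "estimate",
    "evaluation", "findings", "framework", "longitudinal", "measurements",
    "methods", "outcomes", "overview", "participants", "procedure",
    "protocol", "questionnaire", "results", "review", "sample",
    "statistical", "summary", "survey", "variation", "workflow",
)

_CARRIERS: dict[str, str] = {
    "gene": "The gene {} was examined in this cohort.",
    "dementia": "Patients with {} pathology were enrolled.",
    "brain_region": "Structural changes in the {} were measured.",
    "mouse_model": "Experiments used the {} strain.",
    "keyword": "Evidence concerning {} was documented.",
}

_JOURNALS = (
    "Synthetic Neuroscience Reports",
    "Simulated Neurology Letters",
    "Archives of Generated Abstracts",
)


@dataclass(frozen=True)
class ConceptPlant:
    """One concept and the exact record indices that must mention it."""

    kind: str
    name: str  # gene symbol or canonical vocabulary name
    indices: frozenset[int]

    def __post_init__(self) -> None:
        if self.kind not in PLANT_KINDS:
            raise ConfigError(f"unknown plant kind: {self.kind!r}")


@dataclass(frozen=True)
class CorpusSpec:
    """Full description of a synthetic corpus."""

    n_records: int
    year_range: tuple[int, int] = (2000, 2023)
    plants: tuple[ConceptPlant, ...] = ()
    filler: tuple[str, ...] = DEFAULT_FILLER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ConfigError("n_records must be non-negative")
        lo, hi = self.year_range
        if not (1800 <= lo <= hi):
            raise ConfigError(f"invalid year_range: {self.year_range}")
        if not self.filler:
            raise ConfigError("filler vocabulary must be non-empty")
        for plant in self.plants:
            bad = [i for i in plant.indices if not (0 <= i < self.n_records)]
            if bad:
                raise ConfigError(
                    f"plant {plant.kind}/{plant.name}: indices out of range: {sorted(bad)}"
                )

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "year_range": list(self.year_range),
            "seed": self.seed,
            "filler": list(self.filler),
            "plants": [
                {"kind": p.kind, "name": p.name, "indices": sorted(p.indices)}
                for p in self.plants
            ],
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "CorpusSpec":
        return cls(
            n_records=int(doc["n_records"]),
            year_range=tuple(doc.get("year_range", (2000, 2023))),  # type: ignore[arg-type]
            plants=tuple(
                ConceptPlant(
                    kind=p["kind"], name=p["name"], indices=frozenset(int(i) for i in p["indices"])
                )
                for p in doc.get("plants", ())
            ),
            filler=tuple(doc.get("filler", DEFAULT_FILLER)),
            seed=int(doc.get("seed", 0)),
        )


def load_spec(path: str | Path) -> CorpusSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return CorpusSpec.from_dict(yaml.safe_load(fh))


def save_spec(spec: CorpusSpec, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Truth derivation (pure plan arithmetic)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorpusTruth:
    """Expected pipeline outputs, derived deterministically from the plan."""

    pmids: tuple[str, ...]  # index -> pmid
    years: Mapping[str, int]
    gene_pmids: Mapping[str, frozenset[str]]
    nd_pmids: frozenset[str]
    concept_pmids: Mapping[tuple[str, str], frozenset[str]]

    def profile_pmids(self, symbol: str, nd_filtered: bool = False) -> frozenset[str]:
        """Expected GSPP membership for one gene (optionally disease-filtered)."""
        base = self.gene_pmids.get(symbol, frozenset())
        return base & self.nd_pmids if nd_filtered else base

    def expected_summary(self, symbol: str, registry: Sequence[GeneEntry]) -> GeneSummary:
        base = self.profile_pmids(symbol, nd_filtered=True)
        categories: dict[str, CategoryProfile] = {}
        trend: dict[str, list[str]] = {}
        for pmid in base:
            year = self.years[pmid]
            if year > 0:
                trend.setdefault(f"{year:04d}", []).append(pmid)
        categories["year_trend"] = CategoryProfile.from_pmid_map("year_trend", trend)
        for kind, cat_name in (
            ("dementia", "dementia_type"),
            ("brain_region", "brain_region"),
            ("mouse_model", "mouse_model"),
            ("keyword", "keyword"),
        ):
            hits = {
                name: base & pmids
                for (k, name), pmids in self.concept_pmids.items()
                if k == kind
            }
            categories[cat_name] = CategoryProfile.from_pmid_map(cat_name, hits)
        cooc = {
            g.symbol: base & self.gene_pmids.get(g.symbol, frozenset())
            for g in registry
            if g.symbol != symbol
        }
        categories["cooccurring_gene"] = CategoryProfile.from_pmid_map("cooccurring_gene", cooc)
        return GeneSummary(gene_symbol=symbol, categories=categories)

    def surviving_symbols(self, registry: Sequence[GeneEntry]) -> frozenset[str]:
        """Gene symbols expected to survive post-extraction pruning."""
        content_kinds = ("brain_region", "mouse_model", "keyword")
        survivors = set()
        for gene in registry:
            base = self.profile_pmids(gene.symbol, nd_filtered=True)
            for (kind, _name), pmids in self.concept_pmids.items():
                if kind in content_kinds and base & pmids:
                    survivors.add(gene.symbol)
                    break
        return frozenset(survivors)


def _truth_from_spec(spec: CorpusSpec, years: Sequence[int]) -> CorpusTruth:
    pmids = tuple(str(1_000_001 + i) for i in range(spec.n_records))
    gene_pmids: dict[str, frozenset[str]] = {}
    concept_pmids: dict[tuple[str, str], frozenset[str]] = {}
    nd: set[str] = set()
    for plant in spec.plants:
        planted = frozenset(pmids[i] for i in plant.indices)
        if plant.kind == "gene":
            gene_pmids[plant.name] = gene_pmids.get(plant.name, frozenset()) | planted
        else:
            key = (plant.kind, plant.name)
            concept_pmids[key] = concept_pmids.get(key, frozenset()) | planted
            if plant.kind == "dementia":
                nd |= planted
    return CorpusTruth(
        pmids=pmids,
        years={pmids[i]: years[i] for i in range(spec.n_records)},
        gene_pmids=gene_pmids,
        nd_pmids=frozenset(nd),
        concept_pmids=concept_pmids,
    )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _screen_filler(filler: Sequence[str], vocabularies: VocabularySet, registry: Sequence[GeneEntry]) -> None:
    """Reject filler words that share a token with any active concept."""
    concept_tokens: set[str] = set()
    for vocab in vocabularies.by_category().values():
        for variant in vocab.all_variants():
            concept_tokens.update(variant)
    for gene in registry:
        for variant in gene.variants():
            concept_tokens.update(variant)
    for word in filler:
        toks = tokenize(word)
        if len(toks) != 1:
            raise ConfigError(f"filler word {word!r} is not a single token")
        if toks[0] in concept_tokens:
            raise PlantCollisionError(f"filler word {word!r} collides with a vocabulary token")


def _plants_by_record(spec: CorpusSpec) -> list[list[ConceptPlant]]:
    per_record: list[list[ConceptPlant]] = [[] for _ in range(spec.n_records)]
    order = {k: i for i, k in enumerate(PLANT_KINDS)}
    for plant in sorted(spec.plants, key=lambda p: (order[p.kind], p.name)):
        for i in plant.indices:
            per_record[i].append(plant)
    return per_record


_VOCAB_MODES = {
    "dementia": "prefix",
    "brain_region": "exact",
    "mouse_model": "exact",
    "keyword": "exact",
}


def _build_matchers(registry: Sequence[GeneEntry], vocabularies: VocabularySet):
    gene_matchers = [(g.symbol, g.variants()) for g in registry]
    vocab_matchers = [
        (kind, name, variants, _VOCAB_MODES[kind])
        for kind, vocab in vocabularies.by_category().items()
        for name, variants in vocab.entries.items()
    ]
    return gene_matchers, vocab_matchers


def _validate_record(
    index: int,
    record: PublicationRecord,
    planted: Sequence[ConceptPlant],
    gene_matchers,
    vocab_matchers,
) -> None:
    toks = tokenize(record.text)
    tokset = set(toks)
    planted_keys = {(p.kind, p.name) for p in planted}
    for symbol, variants in gene_matchers:
        expected = ("gene", symbol) in planted_keys
        if match_term(toks, variants, mode="exact", token_set=tokset) != expected:
            raise PlantCollisionError(
                f"record {index}: gene {symbol} match != planted ({expected})"
            )
        if expected and not match_term(pos_gate(record.text), variants, mode="exact"):
            raise PlantCollisionError(
                f"record {index}: gene {symbol} does not survive the POS gate"
            )
    for kind, name, variants, mode in vocab_matchers:
        expected = (kind, name) in planted_keys
        if match_term(toks, variants, mode=mode, token_set=tokset) != expected:
            raise PlantCollisionError(
                f"record {index}: {kind}/{name} match != planted ({expected})"
            )


def generate_corpus(
    spec: CorpusSpec,
    registry: Sequence[GeneEntry] | None = None,
    vocabularies: VocabularySet | None = None,
    validate: bool = True,
) -> tuple[Corpus, CorpusTruth]:
    """Generate a corpus and its exact truth object from a planting plan.

    When ``validate`` is set (default), every record is checked against the
    full registry and vocabularies: each concept must match exactly where it
    was planted and nowhere else, and planted gene symbols must survive POS
    gating.  A violation raises :class:`PlantCollisionError` rather than
    silently corrupting the truth.
    """
    if vocabularies is None:
        vocabularies = default_vocabulary_set()
    if registry is None:
        registry = [
            GeneEntry(symbol=p.name) for p in spec.plants if p.kind == "gene"
        ]
        seen: set[str] = set()
        registry = [g for g in registry if not (g.symbol in seen or seen.add(g.symbol))]
    _screen_filler(spec.filler, vocabularies, registry)

    rng = random.Random(spec.seed)
    years = [rng.randint(*spec.year_range) for _ in range(spec.n_records)]
    per_record = _plants_by_record(spec)
    gene_matchers, vocab_matchers = _build_matchers(registry, vocabularies)

    records: list[PublicationRecord] = []
    for i in range(spec.n_records):
        pmid = str(1_000_001 + i)
        w = [rng.choice(spec.filler) for _ in range(4)]
        title = f"A {w[0]} {w[1]} study of {w[2]} {w[3]}."
        sentences = [f"The {rng.choice(spec.filler)} of this {rng.choice(spec.filler)} is described."]
        for plant in per_record[i]:
            sentences.append(_CARRIERS[plant.kind].format(plant.name))
        sentences.append(f"Overall {rng.choice(spec.filler)} was considered.")
        record = PublicationRecord(
            pmid=pmid,
            title=title,
            abstract=" ".join(sentences),
            year=years[i],
            journal=_JOURNALS[i % len(_JOURNALS)],
        )
        if validate:
            _validate_record(i, record, per_record[i], gene_matchers, vocab_matchers)
        records.append(record)
    return Corpus(records), _truth_from_spec(spec, years)


# ---------------------------------------------------------------------------
# Randomized specs and end-to-end comparison
# ---------------------------------------------------------------------------


def _matcher(kind: str, name: str, registry_map: Mapping[str, GeneEntry], vocabularies: VocabularySet):
    if kind == "gene":
        return registry_map[name].variants(), "exact"
    vocab = vocabularies.by_category()[kind]
    mode = "prefix" if kind == "dementia" else "exact"
    return vocab.entries[name], mode


def random_spec(
    registry: Sequence[GeneEntry],
    vocabularies: VocabularySet | None = None,
    *,
    n_records: int = 100,
    seed: int = 0,
    densities: Mapping[str, float] | None = None,
    max_per_kind: int = 6,
) -> CorpusSpec:
    """Draw a random planting plan over the registry and vocabularies.

    Concepts whose carrier sentence would trigger another active concept's
    matcher (e.g. a strain name embedding a registry gene symbol) are
    dropped from the universe, so that plan-derived truth stays exact.
    Genes take precedence, then dementia types, then content concepts.
    """
    if vocabularies is None:
        vocabularies = default_vocabulary_set()
    dens = {"gene": 0.45, "dementia": 0.55, "brain_region": 0.25, "mouse_model": 0.2, "keyword": 0.3}
    if densities:
        dens.update(densities)
    rng = random.Random(seed)
    registry_map = {g.symbol: g for g in registry}

    candidates: list[tuple[str, str]] = [("gene", g.symbol) for g in registry]
    candidates += [("dementia", n) for n in vocabularies.dementia.canonical_names()]
    for kind in ("brain_region", "mouse_model", "keyword"):
        names = vocabularies.by_category()[kind].canonical_names()
        k = min(max_per_kind, len(names))
        candidates += [(kind, n) for n in rng.sample(names, k)]

    accepted: list[tuple[str, str]] = []
    carrier_tokens: dict[tuple[str, str], list[str]] = {}
    for kind, name in candidates:
        toks = tokenize(_CARRIERS[kind].format(name))
        variants, mode = _matcher(kind, name, registry_map, vocabularies)
        conflict = False
        for other in accepted:
            o_variants, o_mode = _matcher(other[0], other[1], registry_map, vocabularies)
            if match_term(toks, o_variants, mode=o_mode) or match_term(
                carrier_tokens[other], variants, mode=mode
            ):
                conflict = True
                break
        if not conflict:
            accepted.append((kind, name))
            carrier_tokens[(kind, name)] = toks

    plants = []
    for kind, name in accepted:
        indices = frozenset(i for i in range(n_records) if rng.random() < dens[kind])
        if indices:
            plants.append(ConceptPlant(kind=kind, name=name, indices=indices))
    return CorpusSpec(
        n_records=n_records,
        plants=tuple(plants),
        seed=rng.randrange(2**31),
    )


@dataclass(frozen=True)
class EndToEndReport:
    """Exact-match comparison of pipeline output against planted truth."""

    n_records: int
    n_genes: int
    n_profiles_nonempty: int
    n_pruned: int
    category_matches: Mapping[str, Mapping[str, bool]]  # symbol -> category -> bool
    prune_match: bool
    diffs: tuple[str, ...]

    @property
    def all_match(self) -> bool:
        return self.prune_match and all(
            ok for per_gene in self.category_matches.values() for ok in per_gene.values()
        )


def run_end_to_end(
    spec: CorpusSpec,
    registry: Sequence[GeneEntry],
    vocabularies: VocabularySet | None = None,
) -> EndToEndReport:
    """Generate a corpus, run the full pipeline, and compare every gene's
    category profiles (and the pruning outcome) against plan-derived truth.
    """
    if vocabularies is None:
        vocabularies = default_vocabulary_set()
    corpus, truth = generate_corpus(spec, registry, vocabularies)

    summaries: list[GeneSummary] = []
    category_matches: dict[str, dict[str, bool]] = {}
    diffs: list[str] = []
    n_nonempty = 0
    for gene in registry:
        profile = filter_nd(build_gspp(gene, corpus), vocabularies.dementia)
        if profile.records:
            n_nonempty += 1
        summary = build_gene_summary(profile, registry, vocabularies)
        expected = truth.expected_summary(gene.symbol, registry)
        per_gene: dict[str, bool] = {}
        for cat in CATEGORY_NAMES:
            ok = summary.category(cat).entries == expected.category(cat).entries
            per_gene[cat] = ok
            if not ok:
                diffs.append(
                    f"{gene.symbol}/{cat}: got {summary.category(cat).counts()}, "
                    f"expected {expected.category(cat).counts()}"
                )
        category_matches[gene.symbol] = per_gene
        summaries.append(summary)

    pruned = prune_profiles(summaries)
    got_survivors = frozenset(s.gene_symbol for s in pruned)
    want_survivors = truth.surviving_symbols(registry)
    prune_match = got_survivors == want_survivors
    if not prune_match:
        diffs.append(f"pruning: got {sorted(got_survivors)}, expected {sorted(want_survivors)}")
    return EndToEndReport(
        n_records=spec.n_records,
        n_genes=len(registry),
        n_profiles_nonempty=n_nonempty,
        n_pruned=len(summaries) - len(pruned),
        category_matches=category_matches,
        prune_match=prune_match,
        diffs=tuple(diffs),
    )
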