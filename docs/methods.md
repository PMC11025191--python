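# Methods

## Model of publication attribution

`ndminer` treats publication mining as dictionary matching over a
normalized token stream. A publication record carries five fields (PMID,
title, abstract, year, journal); all matching operates on the
concatenation of title and abstract — occurrence anywhere in that stream
attributes the publication, and full text is deliberately out of scope. The
operating assumption is that a gene symbol (or alias) appearing in the
title or abstract marks the gene as a substantive component of the study;
the same assumption underlies the disease, region, strain and keyword
extractors.

Tokenization segments sentences on terminal punctuation, extracts maximal
letter/digit runs, removes all punctuation and lowercases. Hyphens and
dashes split compounds (`blood-brain` → `blood`, `brain`), apostrophes
split clitics (`Alzheimer's` → `alzheimer`, `s`), and digits stay inside
tokens (`apoe4`, `5xfad`). Term matching is a contiguous n-gram scan with
two modes:

- **exact** — token-for-token equality; used for gene symbols/aliases,
  brain regions, mouse strains and keywords;
- **prefix** — each variant token matches any stream token it prefixes;
  used for dementia types, whose dictionary stores simplified stems
  (`alzheimer` matches `alzheimers`). Exact matching implies prefix
  matching, so prefix mode is strictly more permissive.

Whether disease matching should be exact or stem-based is genuinely open;
stem-prefix matching is the reading most faithful to a simplified-name
dictionary, and exact mode remains available via the `mode` arguments.

## Pipeline stages

1. **GSPP construction** (`build_gspp`): keep the records whose token
   stream contains the gene's symbol or a non-stoplisted alias (exact
   n-gram). Multi-token aliases become n-gram variants after the same
   normalization.
2. **Disease-of-focus filter** (`filter_nd`): keep records matching at
   least one of the seven dementia types in prefix mode. Profiles emptied
   by the filter are retained; pruning happens only after extraction, so
   the two funnel stages stay separately observable.
3. **Extraction** (`build_gene_summary`): six category profiles per gene.
   A record counts at most once per subcategory, regardless of mention
   count, and may appear under several subcategories. Year-trend entries
   partition the records with known year; records with year 0 (date
   undeterminable) stay in the profile but out of the trend — losing a
   record from every category over a missing date would be worse than
   excluding it from one. Dementia-type extraction aggregates all years;
   a per-year stratification can be layered on by composing the two
   extractors over year-sliced profiles.
4. **Pruning** (`prune_profiles`): drop gene summaries with zero hits
   across brain region, mouse model and keywords jointly.
5. **Summary** (`summarize_corpus`): per category, the number of distinct
   subcategories and two publication totals. "Total publications" is
   ambiguous when a PMID is attributed to several genes, so both readings
   are reported: `n_publications` (distinct PMIDs per category across all
   summaries) and `n_attributions` (raw sum of per-gene subcategory
   counts).
6. **Evaluation** (`compare_annotation_sets`): exact set intersection of
   PMID sets, fractions in both directions (reported to 4 decimals), and
   the reference-only PMID list for manual audit. The reference dialect is
   a generic `pmid / concept_type / concept_label` TSV so evaluation stays
   testable offline; adapters can convert richer formats.

## POS gating

Co-occurring-gene detection first restricts candidate tokens by part of
speech. The tagger is a compact rule-based Penn Treebank tagger designed
for title/abstract prose: a closed-class lexicon (determiners,
prepositions, pronouns, auxiliaries, modals), inflection rules over a stem
list of common scientific verbs, suffix heuristics for adverbs and
adjectives, and capitalization/digit cues that send gene symbols and
strain names to proper-noun tags. The default gate keeps
`{NN, NNS, NNP, NNPS, JJ}` — nominals plus adjectives, since symbols
occasionally tag adjectivally inside noun compounds; the set is
configurable. Gating only removes tokens, so gated co-occurrence counts
are bounded above by ungated counts, and with gating disabled the
co-occurrence relation is exactly symmetric (count of B in A's profile
equals count of A in B's when built from the same corpus and filters).

The tagger favors recall on nominals: an unknown capitalized word tags as
a proper noun, which keeps every gene-like token in the candidate stream
at the cost of admitting some sentence-initial ordinary words. For a
filter whose job is to drop verbs and function words before dictionary
matching, over-admission is the safe direction.

## Vocabularies and the alias stoplist

- **Dementia types (7)** — canonical names with simplified stems:
  `alzheimer`, `parkinson`, `huntington`, `frontotemporal dementia`,
  `lewy body`, `vascular dementia`, `mixed dementia`.
- **Brain regions (13)** — Amygdala, Basal ganglia, Brain stem,
  Cerebellum, Cingulate gyrus, Corpus callosum, Hippocampus,
  Hypothalamus, Neocortex, Pituitary gland, Prefrontal cortex, Spinal
  cord, Thalamus (plus the fused spelling `brainstem`).
- **Keywords (32)** — expert-style AD process/pathology terms. The shipped
  file is a synthetic snapshot (see `data/keywords_synthetic.yaml`): six
  entries are well-attested exemplars (tau deposition, innate immune
  response, mitochondria, lipid metabolism, oxidative stress, blood-brain
  barrier) and the remainder are representative terms from the AD
  literature. The code treats the list purely as configuration.
- **Mouse models (11)** — a synthetic snapshot of MODEL-AD-style strain
  names (5xFAD, 3xTg-AD, APP/PS1, …). Strain tables evolve; shipping a
  static snapshot keeps runs reproducible, and any strain list can be
  supplied as YAML.

Counted sub-categories in any given corpus can differ from the shipped
list sizes (e.g. 8 observed dementia subcategories against 7 configured
types, or 31 keyword subcategories against 32 entries) because extraction
emits only subcategories with at least one hit and downstream tables count
observed keys; the configured sizes above are the authoritative ones.

Alias matching applies an **ambiguous-symbol stoplist**: alias surface
forms that are common English words or shorter than three characters are
excluded by default (the APOE alias "AD" would otherwise match the
disease acronym everywhere). The official symbol itself is always
retained — dropping it would orphan the gene — and both the stoplist and
the length threshold are overridable at registry load. Because all
matching is lowercased, the stoplist is the main guard against
case-collapse ambiguity.

## Synthetic corpus generator

The generator emulates the one property of real PubMed records the
pipeline depends on: concept surface forms embedded in sentence context in
titles and abstracts. A `CorpusSpec` fixes the record count, year range
(default 2000–2023, drawn uniformly), a seed, and per concept the exact
set of record indices that mention it. Planted mentions are rendered as
grammatical carrier sentences ("The gene APOE was examined in this
cohort.") so the POS gate sees nominal contexts; remaining text is drawn
from a neutral filler vocabulary. Default densities in randomized specs
(genes 0.45, dementia 0.55, regions 0.25, strains 0.2, keywords 0.3 per
record) are chosen to exercise all categories, including empty and
near-empty profiles, in corpora of tens to thousands of records.

Two safeguards keep plan-derived truth exact. First, filler words are
screened against every token of every active vocabulary and registry
entry. Second, the generator validates each record against the full
registry and all four vocabularies: every concept must match exactly where
planted and nowhere else, and planted gene symbols must survive the POS
gate; any violation raises `PlantCollisionError` instead of silently
corrupting the truth. The randomized-spec sampler additionally drops
concepts whose carrier sentence would trigger another active concept's
matcher (a strain name such as `Trem2-R47H` embeds the TREM2 symbol), so
sampled plans are collision-free by construction. Generation is
deterministic: one seed, one byte-identical corpus.

What the generator does **not** emulate: real abstract language (sentence
variety, anaphora, abbreviation definitions), ambiguous gene mentions,
misspellings, OCR noise, or PubMed's growth curve. Passing the synthetic
end-to-end tests therefore demonstrates that the mechanics of filtering,
extraction and aggregation are exact — not that dictionary matching is
semantically sufficient on real literature, where short ambiguous aliases
and full-text-only mentions are known failure modes of any
title/abstract dictionary approach.

## Numerical and formatting choices

- PMIDs are digit strings, sorted numerically inside every entry; the
  subcategory keys of serialized summaries sort lexically (years
  chronologically, terms alphabetically), making JSON output
  byte-stable across write→read→write.
- GSPP CSV column order is fixed (`pmid,year,title,abstract,journal`),
  RFC 4180 quoting, embedded newlines preserved; CSV and JSON
  serialization round-trip exactly.
- Years outside [1800, next year] are rejected at record construction;
  year 0 is the explicit "unknown" sentinel.
- Applying the disease filter twice is a state error by design; the
  meaningful idempotence (re-running the predicate changes nothing) holds
  on record sets and is tested.
- Overlap fractions are reported to 4 decimal places; raw counts always
  accompany them.

## Problem sizes

The test suite and the acceptance script run randomized end-to-end
corpora of 20–1,000 records (50 specs in the suite, 25 in the script,
plus one 2,000-record funnel corpus) over a six-gene registry. These
sizes give every category multiple occupied and empty subcategories per
run while keeping a full suite execution under a minute on one core;
recovery is exact at these sizes by construction of the validator, and
nothing in the pipeline is size-dependent beyond linear scanning.

## Known limitations

- Dictionary matching cannot disambiguate polysemous symbols beyond the
  stoplist; no supervised NER or ontology expansion is attempted.
- Title/abstract scope undercounts relative to full-text annotation
  sources; the evaluation module reports the reference-only PMIDs so that
  such discrepancies can be audited rather than hidden.
- The rule-based tagger is not a trained statistical tagger; its tag
  assignments outside the nominal/function-word distinction are coarse.
- The Entrez fetch adapter is a thin optional convenience and performs no
  rate limiting beyond what the client library provides.
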