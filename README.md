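# ndminer

Gene-centric literature mining for neurodegenerative disease (ND).

Researchers in the Alzheimer's disease (AD) field face an ever-growing
publication record. `ndminer` implements a dictionary-based NLP pipeline
that organizes PubMed-style publication records around genes: for each gene
it builds a **gene-specific publication profile (GSPP)** — the set of
publications whose title or abstract contains the gene's official HUGO
symbol or one of its aliases as a token n-gram — then keeps only the
publications mentioning one of the seven major dementia types (AD,
Parkinson's disease, Huntington's disease, frontotemporal dementia, Lewy
body dementia, vascular dementia, mixed dementia) via simplified name stems
such as `alzheimer`. From each filtered profile it extracts six categories
of information, each stored as *subcategory → (publication count, PMID
list)*:

1. **Yearly publication trend** — records stratified by publication year;
2. **Dementia-type occurrence** — prefix-stem matches of the seven types;
3. **Brain-region occurrence** — exact n-gram matches against thirteen
   regions commonly studied in neurodegeneration (Amygdala … Thalamus);
4. **Mouse-model occurrence** — AD mouse-model strain names;
5. **Keyword occurrence** — a 32-entry expert keyword list (e.g. *tau
   deposition*, *oxidative stress*, *blood-brain barrier*);
6. **Co-occurring genes** — other registry genes mentioned in the same
   publication, with candidate tokens restricted by part-of-speech gating
   to nominal/adjectival tags (`NN`, `NNS`, `NNP`, `NNPS`, `JJ`) before
   symbol matching.

Profiles that end up empty in all three content categories (brain region,
mouse model, keywords) are pruned. The resulting per-gene summaries can be
aggregated into a per-category corpus table and evaluated against an
external reference annotation source by exact PMID set intersection.

A seeded synthetic-corpus generator plants known gene/disease/region/
strain/keyword mentions in grammatical carrier sentences and derives an
exact truth object from the planting plan, so every pipeline stage is
testable end to end with exact expectations.

## Worked example

```python
import ndminer as nd

spec = nd.CorpusSpec(
    n_records=10,
    plants=(
        nd.ConceptPlant("gene", "APOE", frozenset(range(10))),
        nd.ConceptPlant("gene", "TREM2", frozenset({2, 5, 8})),
        nd.ConceptPlant("dementia", "Alzheimer's Disease", frozenset(range(8))),
        nd.ConceptPlant("brain_region", "Hippocampus", frozenset({0, 3, 7})),
        nd.ConceptPlant("keyword", "oxidative stress", frozenset({1, 3})),
    ),
    seed=42,
)
registry = [nd.GeneEntry("APOE", ("AD2", "LPG")), nd.GeneEntry("TREM2")]
vocabs = nd.default_vocabulary_set()

corpus, truth = nd.generate_corpus(spec, registry, vocabs)
profile = nd.filter_nd(nd.build_gspp(registry[0], corpus), vocabs.dementia)
summary = nd.build_gene_summary(profile, registry, vocabs)
print("after disease filter:", len(profile))
for cat in ("dementia_type", "brain_region", "keyword", "cooccurring_gene"):
    print(cat, summary.category(cat).counts())
```

prints

```
after disease filter: 8
dementia_type {"Alzheimer's Disease": 8}
brain_region {'Hippocampus': 3}
keyword {'oxidative stress': 2}
cooccurring_gene {'TREM2': 2}
```

All ten records mention APOE, but only the eight with a planted dementia
mention survive the disease-of-focus filter; the three hippocampus plants
and two keyword plants all fall inside that surviving set, and TREM2
co-occurs in the two filtered records where it was planted (records 2 and
5; record 8 has no dementia mention). Exactly the planting plan, recovered
from raw text.

The same pipeline is available from the shell:

```sh
ndminer simulate --spec spec.yaml --out corpus.json
ndminer build-profiles --corpus corpus.json --registry gene_info.tsv --out-dir gspp/
ndminer extract --gspp gspp/APOE.csv --gene APOE --registry gene_info.tsv --out APOE.json
ndminer summarize --summaries APOE.json --out table.tsv
ndminer compare --summaries APOE.json --gene APOE \
    --dementia-type "Alzheimer's Disease" --reference ref.tsv --out overlap.json
```

Real PubMed XML (`PubmedArticleSet`) and flat CSV/JSON record tables are
read with `read_pubmed_xml` / `read_records_table`; GSPPs are written as
CSV with columns `pmid,year,title,abstract,journal`.

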