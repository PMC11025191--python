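"""Tokenization, normalization, multiword term matching and POS gating.

Every filter and extractor in the pipeline operates on the same normalized
token stream: sentences are segmented, words are tokenized, punctuation is
stripped (hyphens and dashes split compounds into separate tokens) and the
survivors are lowercased.  Term matching is a contiguous n-gram scan over
that stream, either exact per token or by token prefix; prefix matching is
what lets a simplified disease stem such as ``alzheimer`` hit inflected
surface forms like ``alzheimers``.

Gene-mention candidate detection is additionally gated by part of speech:
tokens are tagged with Penn Treebank tags by a compact rule-based tagger
(closed-class lexicon, inflection and suffix heuristics, capitalization
cues) and only nominal/adjectival tokens are retained before symbol
matching.  Gene symbols and strain names — uppercase or alphanumeric
surface forms — reliably receive proper-noun tags under these rules.
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Iterable, Sequence

__all__ = [
    "tokenize",
    "split_sentences",
    "match_term",
    "pos_tag",
    "pos_gate",
    "DEFAULT_POS_TAGS",
]

#: Default POS gate: nominals plus adjectives (gene symbols tag as proper or
#: common nouns, occasionally as adjectives inside noun compounds).
DEFAULT_POS_TAGS: frozenset[str] = frozenset({"NN", "NNS", "NNP", "NNPS", "JJ"})

# Word = maximal run of letters/digits (underscore excluded). Hyphens, dashes,
# apostrophes and all other punctuation act as token boundaries, so
# "blood-brain" -> ["blood", "brain"] and "Alzheimer's" -> ["alzheimer", "s"].
_WORD_RE = re.compile(r"[^\W_]+", re.UNICODE)
_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[str]:
    """Split free text into sentence chunks on terminal punctuation."""
    return [s for s in _SENT_BOUNDARY_RE.split(text) if s and not s.isspace()]


@lru_cache(maxsize=65536)
def _tokenize_cached(text: str) -> tuple[str, ...]:
    tokens: list[str] = []
    for sentence in split_sentences(text):
        tokens.extend(m.group(0).lower() for m in _WORD_RE.finditer(sentence))
    return tuple(tokens)


def tokenize(text: str) -> list[str]:
    """Normalize free text to a flat token stream.

    Sentence segmentation precedes word tokenization, but the result is the
    concatenated stream across sentences: occurrence checks are
    document-level, not per sentence.  Digits and Greek letters are retained
    inside tokens ("apoe4" stays a single token).
    """
    return list(_tokenize_cached(text))


def _match_exact(tokens: Sequence[str], token_set: frozenset[str] | set[str], variant: Sequence[str]) -> bool:
    n = len(variant)
    if n == 0 or n > len(tokens):
        return False
    for t in variant:
        if t not in token_set:
            return False
    if n == 1:
        return True
    first = variant[0]
    start = 0
    limit = len(tokens) - n + 1
    while start < limit:
        try:
            i = tokens.index(first, start, limit)
        except ValueError:
            return False
        ok = True
        for j in range(1, n):
            if tokens[i + j] != variant[j]:
                ok = False
                break
        if ok:
            return True
        start = i + 1
    return False


def _match_prefix(tokens: Sequence[str], variant: Sequence[str]) -> bool:
    n = len(variant)
    if n == 0 or n > len(tokens):
        return False
    first = variant[0]
    for i in range(len(tokens) - n + 1):
        if not tokens[i].startswith(first):
            continue
        ok = True
        for j in range(1, n):
            if not tokens[i + j].startswith(variant[j]):
                ok = False
                break
        if ok:
            return True
    return False


def match_term(
    tokens: Sequence[str],
    variants: Iterable[Sequence[str]],
    mode: str = "exact",
    token_set: frozenset[str] | set[str] | None = None,
) -> bool:
    """True iff some variant occurs as a contiguous n-gram in ``tokens``.

    Parameters
    ----------
    tokens
        Normalized token stream (as produced by :func:`tokenize`).
    variants
        Candidate token sequences; a match of any one suffices.
    mode
        ``"exact"`` compares tokens verbatim; ``"prefix"`` lets a variant
        token ``t`` match any stream token that starts with ``t``.
    token_set
        Optional precomputed ``set(tokens)``; callers scanning many
        variants against one stream can pass it to skip rebuilding it.
    """
    if mode == "exact":
        if token_set is None:
            token_set = set(tokens)
        return any(_match_exact(tokens, token_set, v) for v in variants)
    if mode == "prefix":
        return any(_match_prefix(tokens, v) for v in variants)
    raise ValueError(f"unknown match mode: {mode!r}")


# ---------------------------------------------------------------------------
# Rule-based Penn Treebank tagging
# ---------------------------------------------------------------------------

_CLOSED_CLASS: dict[str, str] = {
    # determiners / quantifiers
    "the": "DT", "a": "DT", "an": "DT", "this": "DT", "that": "DT",
    "these": "DT", "those": "DT", "each": "DT", "every": "DT", "some": "DT",
    "any": "DT", "no": "DT", "both": "DT", "all": "DT", "several": "DT",
    # prepositions and subordinating conjunctions
    "of": "IN", "in": "IN", "on": "IN", "at": "IN", "by": "IN", "for": "IN",
    "with": "IN", "from": "IN", "into": "IN", "during": "IN", "between": "IN",
    "among": "IN", "through": "IN", "after": "IN", "before": "IN",
    "under": "IN", "over": "IN", "within": "IN", "without": "IN", "via": "IN",
    "per": "IN", "upon": "IN", "against": "IN", "across": "IN",
    "toward": "IN", "towards": "IN", "as": "IN", "than": "IN",
    "whether": "IN", "while": "IN", "because": "IN", "although": "IN",
    "though": "IN", "since": "IN", "if": "IN",
    # coordination
    "and": "CC", "or": "CC", "but": "CC", "nor": "CC", "yet": "CC",
    "to": "TO",
    # adverbs / negation
    "not": "RB", "also": "RB", "only": "RB", "however": "RB", "thus": "RB",
    "therefore": "RB", "moreover": "RB", "furthermore": "RB", "here": "RB",
    "further": "RB", "respectively": "RB", "together": "RB", "well": "RB",
    # pronouns
    "we": "PRP", "it": "PRP", "they": "PRP", "he": "PRP", "she": "PRP",
    "i": "PRP", "them": "PRP", "us": "PRP",
    "our": "PRP$", "its": "PRP$", "their": "PRP$", "his": "PRP$", "her": "PRP$",
    # be / have / do
    "is": "VBZ", "are": "VBP", "was": "VBD", "were": "VBD", "be": "VB",
    "been": "VBN", "being": "VBG", "am": "VBP",
    "has": "VBZ", "have": "VBP", "had": "VBD", "having": "VBG",
    "does": "VBZ", "do": "VBP", "did": "VBD", "done": "VBN", "doing": "VBG",
    # modals
    "can": "MD", "could": "MD", "may": "MD", "might": "MD", "will": "MD",
    "would": "MD", "shall": "MD", "should": "MD", "must": "MD",
    # wh-words
    "which": "WDT", "what": "WDT", "who": "WP", "whom": "WP", "whose": "WP$",
    "when": "WRB", "where": "WRB", "how": "WRB", "why": "WRB",
    "there": "EX",
    # orphaned clitics left by punctuation splitting ("Alzheimer's" -> "s")
    "s": "POS", "t": "RB",
}

# Common verbs of scientific prose; inflections are derived below.
_VERB_STEMS: frozenset[str] = frozenset(
    """
    activate aggregate alter analyze assess associate cause characterize
    compare conduct confirm contribute correlate decrease demonstrate detect
    determine develop discuss elevate enhance enroll evaluate examine exhibit
    explore express find identify impair improve increase indicate induce
    influence inhibit investigate involve lead measure mediate modulate
    observe obtain perform play promote propose protect provide quantify
    reduce regulate remain report require result reveal show suggest
    suppress test treat trigger underlie use validate document consider
    """.split()
)

_ADJ_SUFFIXES = (
    "al", "ic", "ous", "ive", "ary", "able", "ible", "ful", "less", "ant",
)
_NUMBER_RE = re.compile(r"\d+(?:\.\d+)?")


def _is_verb_stem(stem: str) -> bool:
    return stem in _VERB_STEMS


def _tag_one(surface: str) -> str:
    low = surface.lower()
    closed = _CLOSED_CLASS.get(low)
    if closed is not None:
        return closed
    if _NUMBER_RE.fullmatch(surface):
        return "CD"
    if any(c.isupper() for c in surface):
        # Capitalized or mixed-case: proper noun. Gene symbols (APOE, TREM2)
        # and strain names (5xFAD) land here.
        if low.endswith("s") and not low.endswith("ss"):
            return "NNPS"
        return "NNP"
    if _is_verb_stem(low):
        return "VB"
    if low.endswith("ing") and (_is_verb_stem(low[:-3]) or _is_verb_stem(low[:-3] + "e")):
        return "VBG"
    if low.endswith("ied") and _is_verb_stem(low[:-3] + "y"):
        return "VBD"
    if low.endswith("ed") and (_is_verb_stem(low[:-2]) or _is_verb_stem(low[:-1])):
        return "VBD"
    if low.endswith("ies") and _is_verb_stem(low[:-3] + "y"):
        return "VBZ"
    if low.endswith("es") and _is_verb_stem(low[:-2]):
        return "VBZ"
    if low.endswith("s") and not low.endswith("ss") and _is_verb_stem(low[:-1]):
        return "VBZ"
    if low.endswith("ly"):
        return "RB"
    if low.endswith(_ADJ_SUFFIXES):
        return "JJ"
    if low.endswith("s") and not low.endswith(("ss", "us", "is")):
        return "NNS"
    return "NN"


def pos_tag(text: str) -> list[tuple[str, str]]:
    """Tag the un-normalized word-token stream with Penn Treebank tags.

    Returns ``(surface, tag)`` pairs, one per word token of the source
    tokenization (punctuation tokens are never emitted).
    """
    return [(m.group(0), _tag_one(m.group(0))) for m in _WORD_RE.finditer(text)]


@lru_cache(maxsize=65536)
def _pos_gate_cached(text: str, allowed_tags: frozenset[str]) -> tuple[str, ...]:
    return tuple(
        surface.lower() for surface, tag in pos_tag(text) if tag in allowed_tags
    )


def pos_gate(text: str, allowed_tags: frozenset[str] | set[str] = DEFAULT_POS_TAGS) -> list[str]:
    """Keep only tokens whose POS tag is allowed, then normalize survivors.

    The output is always a sub-multiset of ``tokenize(text)``.
    """
    if not allowed_tags:
        raise ValueError("allowed_tags must be non-empty")
    return list(_pos_gate_cached(text, frozenset(allowed_tags)))
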