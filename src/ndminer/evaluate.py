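"""Annotation-overlap evaluation.

Compares the pipeline's (gene, dementia-type) publication annotations
against an external reference annotation set by exact PMID set
intersection, reporting counts and coverage fractions in both directions
plus the reference-only PMIDs for manual audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import GeneNotFoundError, SchemaError
from .extract import GeneSummary

__all__ = [
    "AnnotationSet",
    "OverlapReport",
    "load_reference_annotations",
    "pipeline_annotation_set",
    "compare_annotation_sets",
]

_REFERENCE_COLUMNS = ("pmid", "concept_type", "concept_label")


@dataclass(frozen=True)
class AnnotationSet:
    """PMIDs annotated with a fixed concept pair, from one source."""

    label: str
    pmids: frozenset[str]

    def __len__(self) -> int:
        return len(self.pmids)


@dataclass(frozen=True)
class OverlapReport:
    n_ours: int
    n_reference: int
    n_overlap: int
    overlap_fraction_of_ours: float
    overlap_fraction_of_reference: float
    reference_only: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "n_ours": self.n_ours,
            "n_reference": self.n_reference,
            "n_overlap": self.n_overlap,
            "overlap_fraction_of_ours": round(self.overlap_fraction_of_ours, 4),
            "overlap_fraction_of_reference": round(self.overlap_fraction_of_reference, 4),
            "reference_only": list(self.reference_only),
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _concept_mask(frame: pd.DataFrame, concept) -> pd.Series:
    """Rows carrying one concept; a (type, label) tuple pins both columns."""
    if isinstance(concept, (tuple, list)):
        ctype, clabel = concept
        return (frame["concept_type"] == str(ctype)) & (frame["concept_label"] == str(clabel))
    return frame["concept_label"] == str(concept)


def load_reference_annotations(
    path: str | Path,
    concept_a,
    concept_b,
    label: str = "reference",
) -> AnnotationSet:
    """Load the PMIDs annotated with both concepts from a 3-column TSV.

    Columns: pmid, concept_type, concept_label.  Each concept argument is a
    label string or a ``(concept_type, concept_label)`` pair.  Duplicate
    rows collapse under set semantics.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_REFERENCE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(sorted(missing))}")
    with_a = set(frame.loc[_concept_mask(frame, concept_a), "pmid"])
    with_b = set(frame.loc[_concept_mask(frame, concept_b), "pmid"])
    return AnnotationSet(label=label, pmids=frozenset(with_a & with_b))


def pipeline_annotation_set(
    summaries: Sequence[GeneSummary],
    gene: str,
    dementia_type: str,
    label: str = "pipeline",
) -> AnnotationSet:
    """PMIDs in one gene's dementia-type entry (empty if the type is absent)."""
    for summary in summaries:
        if summary.gene_symbol == gene:
            entry = summary.category("dementia_type").entries.get(dementia_type)
            pmids = frozenset(entry.pmids) if entry is not None else frozenset()
            return AnnotationSet(label=label, pmids=pmids)
    raise GeneNotFoundError(gene)


def compare_annotation_sets(ours: AnnotationSet, reference: AnnotationSet) -> OverlapReport:
    """Exact set-intersection comparison of two annotation sets."""
    overlap = ours.pmids & reference.pmids
    n_ours, n_ref, n_overlap = len(ours.pmids), len(reference.pmids), len(overlap)
    return OverlapReport(
        n_ours=n_ours,
        n_reference=n_ref,
        n_overlap=n_overlap,
        overlap_fraction_of_ours=(n_overlap / n_ours) if n_ours else 0.0,
        overlap_fraction_of_reference=(n_overlap / n_ref) if n_ref else 0.0,
        reference_only=tuple(sorted(reference.pmids - ours.pmids, key=int)),
    )
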