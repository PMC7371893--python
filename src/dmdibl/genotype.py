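"""Dp140 isoform classification of DMD gene copy-number variants.

The Dp140 dystrophin isoform is transcribed from a promoter located around
exon 44 of the DMD gene (79 exons total). A deletion/duplication lying
entirely upstream of that promoter region (last affected exon <= 43) leaves
Dp140 intact (Dp140-positive); a CNV reaching exon 44 or beyond is
predicted to abolish it (Dp140-negative). Exon 44 itself is classified
negative - CNVs ending exactly there are flagged low-confidence because the
transcription start site is not confirmed at single-exon resolution - and
duplications are given the same upstream/downstream rule as deletions,
flagged in the rationale. Point mutations and CNV-free records cannot be
localized and yield "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .exceptions import AlignmentError, CoordinateError

N_EXONS = 79
DP140_PROMOTER_EXON = 44

MUTATION_KINDS = ("deletion", "duplication", "point", "none")

__all__ = [
    "N_EXONS",
    "DP140_PROMOTER_EXON",
    "MutationRecord",
    "IsoformCall",
    "classify_dp140",
    "cohort_summary",
    "REFERENCE_ID_CASES",
]


@dataclass(frozen=True)
class MutationRecord:
    """A DMD gene variant in exon-numbered coordinates (1-79, inclusive)."""

    kind: str
    exon_start: Optional[int] = None
    exon_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in MUTATION_KINDS:
            raise CoordinateError(f"unknown mutation kind {self.kind!r}")
        if self.kind in ("deletion", "duplication"):
            if self.exon_start is None or self.exon_end is None:
                raise CoordinateError(f"{self.kind} needs exon_start and exon_end")
            for exon in (self.exon_start, self.exon_end):
                if not (1 <= exon <= N_EXONS):
                    raise CoordinateError(
                        f"exon {exon} outside the DMD gene's 1-{N_EXONS} range")
            if self.exon_start > self.exon_end:
                raise CoordinateError("exon_start must be <= exon_end")


@dataclass(frozen=True)
class IsoformCall:
    dp140: str              # "positive", "negative" or "unknown"
    rationale: str
    low_confidence: bool = False


def classify_dp140(m: MutationRecord) -> IsoformCall:
    """Classify a mutation record as Dp140 positive / negative / unknown.

    Pure function of (kind, exon_end): CNVs ending at exon <= 43 are
    entirely upstream of the Dp140 promoter region (exon 44) and leave the
    isoform intact; CNVs reaching exon 44 or beyond are predicted to
    abolish it.
    """
    if m.kind in ("point", "none"):
        return IsoformCall(
            dp140="unknown",
            rationale=f"{m.kind} mutation cannot be localized relative to the "
                      f"Dp140 promoter by exon-level CNV screening")
    dup_note = ("; upstream/downstream rule extended to a duplication"
                if m.kind == "duplication" else "")
    span = f"{m.kind} of exons {m.exon_start}-{m.exon_end}"
    if m.exon_end < DP140_PROMOTER_EXON:
        return IsoformCall(
            dp140="positive",
            rationale=f"{span} lies entirely upstream of the Dp140 promoter "
                      f"region (exon {DP140_PROMOTER_EXON}){dup_note}")
    return IsoformCall(
        dp140="negative",
        rationale=f"{span} reaches the Dp140 promoter region "
                  f"(exon {DP140_PROMOTER_EXON}) or beyond{dup_note}",
        low_confidence=(m.exon_end == DP140_PROMOTER_EXON))


#: The five published DMD cases with intellectual disability:
#: (case id, full-scale IQ, mutation record). All classify Dp140-negative.
REFERENCE_ID_CASES = (
    ("case-1", 42, MutationRecord("deletion", 45, 52)),
    ("case-2", 55, MutationRecord("deletion", 45, 52)),
    ("case-3", 57, MutationRecord("deletion", 45, 49)),
    ("case-4", 65, MutationRecord("deletion", 45, 52)),
    ("case-5", 66, MutationRecord("deletion", 20, 44)),
)


def cohort_summary(calls: Sequence[IsoformCall],
                   iq_categories: Sequence[str]) -> pd.DataFrame:
    """Contingency table of isoform call x IQ category (counts conserved)."""
    if len(calls) != len(iq_categories):
        raise AlignmentError(
            f"{len(calls)} calls vs {len(iq_categories)} IQ categories")
    if not calls:
        return pd.DataFrame()
    frame = pd.DataFrame({
        "dp140": [c.dp140 for c in calls],
        "iq_category": list(iq_categories),
    })
    return pd.crosstab(frame["dp140"], frame["iq_category"])
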