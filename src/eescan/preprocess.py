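"""Assembly cleaning and host-bait preparation (pipeline step I).

Short contigs and scaffolds are removed before the similarity search: they
are frequently unintegrated symbiont contamination, and elements called on
them cannot be validated by flanking-sequence analysis. The host-bait
protein set can optionally be purged of uninformative annotations
("hypothetical"/"uncharacterized" products), which are often unannotated
endogenized elements themselves and would otherwise mask true detections
during reciprocal filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONTIG_LENGTH = 10_000
DEFAULT_BAIT_EXCLUDE_PATTERNS = ("hypothetical", "uncharacterized")


@dataclass(frozen=True)
class CleaningReport:
    """Summary of the short-contig filter."""

    n_input: int
    n_kept: int
    n_removed: int
    min_length: int
    removed_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.n_kept + self.n_removed != self.n_input:
            raise ValueError("inconsistent cleaning report totals")


def filter_short_contigs(
    assembly: Iterable[SequenceRecord], min_length: int = DEFAULT_MIN_CONTIG_LENGTH
) -> tuple[list[SequenceRecord], CleaningReport]:
    """Keep contigs/scaffolds of length >= ``min_length`` (input order preserved)."""
    if min_length < 0:
        raise ValueError("min_length must be >= 0")
    kept: list[SequenceRecord] = []
    removed_ids: list[str] = []
    n_input = 0
    for rec in assembly:
        n_input += 1
        if len(rec) >= min_length:
            kept.append(rec)
        else:
            removed_ids.append(rec.id)
    if n_input and not kept:
        logger.warning("all %d contigs are shorter than %d nt; nothing to search", n_input, min_length)
    report = CleaningReport(
        n_input=n_input,
        n_kept=len(kept),
        n_removed=len(removed_ids),
        min_length=min_length,
        removed_ids=tuple(removed_ids),
    )
    return kept, report


def filter_bait_proteins(
    baits: Iterable[SequenceRecord],
    exclude_patterns: Sequence[str] = DEFAULT_BAIT_EXCLUDE_PATTERNS,
    enabled: bool = True,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Split baits into (kept, removed) by case-insensitive substring match.

    Matching is on the record description only; when ``enabled`` is false the
    input passes through unchanged.
    """
    baits = list(baits)
    if not enabled:
        return baits, []
    patterns = [p.lower() for p in exclude_patterns]
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    for rec in baits:
        desc = rec.description.lower()
        if any(p in desc for p in patterns):
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed
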