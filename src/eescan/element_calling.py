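"""Candidate element calling, reciprocal host filtering and taxonomy transfer.

Raw translated-search hits are collapsed into candidate loci (steps III-IV):
hits on one contig whose nucleotide spans overlap are grouped transitively
into a single candidate annotated by its best-scoring hit. Because many
viral/bacterial proteins share deep ancestry with eukaryotic proteins, each
candidate is then re-searched against a host "bait" protein set and retained
only if its bitscore against the viral/bacterial database is strictly higher
than its best bitscore against the host baits — bitscores being
database-size independent, the two searches are directly comparable.
Finally the metadata table transfers taxonomy from the best-hit protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import NA, AlignmentHit, MetadataTable, SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateElement",
    "AnnotatedElement",
    "FilterDecision",
    "hits_to_candidates",
    "extract_candidate_sequences",
    "reciprocal_filter",
    "assign_taxonomy",
]


@dataclass(frozen=True)
class CandidateElement:
    """A putative element: the union span of transitively overlapping hits."""

    element_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    best_subject: str
    bit_score: float
    e_value: float
    percent_identity: float
    supporting_hits: tuple[AlignmentHit, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for candidate {self.element_id}")
        if self.supporting_hits:
            best = max(h.bit_score for h in self.supporting_hits)
            if abs(self.bit_score - best) > 1e-9:
                raise ValueError(f"bit_score is not the max supporting bitscore for {self.element_id}")


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the reciprocal bitscore comparison for one candidate."""

    element_id: str
    forward_bits: float
    host_bits: float | None
    retained: bool
    host_subject: str | None

    def __post_init__(self) -> None:
        expected = self.host_bits is None or self.forward_bits > self.host_bits
        if self.retained != expected:
            raise ValueError(f"inconsistent filter decision for {self.element_id}")


@dataclass(frozen=True)
class AnnotatedElement:
    """A retained candidate with taxonomy transferred from its best hit."""

    element_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    best_subject: str
    bit_score: float
    e_value: float
    percent_identity: float
    species: str = NA
    genus: str = NA
    family: str = NA
    molecule_type: str = NA
    protein_product: str = NA
    host: str = NA


def _element_id(contig_id: str, start: int, end: int, strand: str) -> str:
    return f"{contig_id}:{start}-{end}:{strand}"


def hits_to_candidates(hits: Iterable[AlignmentHit]) -> list[CandidateElement]:
    """Collapse hits into candidates by transitive span overlap (>= 1 nt).

    Grouping is strand-agnostic; abutting spans do not merge. The
    representative annotation comes from the maximal-bitscore hit, ties
    broken by lower e-value then lexicographic subject accession.
    """
    by_contig: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_contig.setdefault(h.query_id, []).append(h)

    candidates: list[CandidateElement] = []
    for contig_id in sorted(by_contig):
        group = sorted(by_contig[contig_id], key=lambda h: (h.q_start, h.q_end))
        cluster: list[AlignmentHit] = []
        cluster_end = -1
        for h in group:
            if cluster and h.q_start <= cluster_end:
                cluster.append(h)
                cluster_end = max(cluster_end, h.q_end)
            else:
                if cluster:
                    candidates.append(_make_candidate(contig_id, cluster))
                cluster = [h]
                cluster_end = h.q_end
        if cluster:
            candidates.append(_make_candidate(contig_id, cluster))
    return candidates


def _make_candidate(contig_id: str, cluster: Sequence[AlignmentHit]) -> CandidateElement:
    start = min(h.q_start for h in cluster)
    end = max(h.q_end for h in cluster)
    best = min(cluster, key=lambda h: (-h.bit_score, h.e_value, h.subject_id))
    return CandidateElement(
        element_id=_element_id(contig_id, start, end, best.strand),
        contig_id=contig_id,
        start=start,
        end=end,
        strand=best.strand,
        best_subject=best.subject_id,
        bit_score=best.bit_score,
        e_value=best.e_value,
        percent_identity=best.percent_identity,
        supporting_hits=tuple(sorted(cluster, key=lambda h: (h.q_start, h.q_end, h.subject_id, h.frame))),
    )


def extract_candidate_sequences(
    assembly: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    candidates: Iterable[CandidateElement],
) -> list[SequenceRecord]:
    """Forward-strand subsequence [start, end] of each candidate, id = element_id."""
    if not isinstance(assembly, Mapping):
        assembly = {rec.id: rec for rec in assembly}
    out: list[SequenceRecord] = []
    for cand in candidates:
        contig = assembly.get(cand.contig_id)
        if contig is None:
            raise ValueError(f"candidate {cand.element_id} references unknown contig {cand.contig_id}")
        if not (1 <= cand.start <= cand.end <= len(contig)):
            raise ValueError(
                f"candidate {cand.element_id} span ({cand.start},{cand.end}) outside "
                f"contig {cand.contig_id} of length {len(contig)}"
            )
        out.append(
            SequenceRecord(
                id=cand.element_id,
                residues=contig.residues[cand.start - 1 : cand.end],
                description=f"candidate {cand.contig_id}:{cand.start}-{cand.end}",
            )
        )
    return out


def reciprocal_filter(
    candidates: Sequence[CandidateElement], host_hits: Iterable[AlignmentHit]
) -> tuple[list[CandidateElement], list[CandidateElement], list[FilterDecision]]:
    """Retain candidates scoring strictly higher forward than against host baits.

    ``host_hits`` are hits of the extracted candidate sequences against the
    bait database (query ids are element ids). A candidate with no host hit
    is retained; a tie is removed (only strictly higher forward bitscores
    count as evidence of non-host origin).
    """
    known = {c.element_id for c in candidates}
    best_host: dict[str, AlignmentHit] = {}
    for h in host_hits:
        if h.query_id not in known:
            raise ValueError(f"host hit references unknown element id {h.query_id!r}")
        cur = best_host.get(h.query_id)
        if cur is None or (-h.bit_score, h.e_value, h.subject_id) < (-cur.bit_score, cur.e_value, cur.subject_id):
            best_host[h.query_id] = h

    retained: list[CandidateElement] = []
    removed: list[CandidateElement] = []
    decisions: list[FilterDecision] = []
    for cand in candidates:
        host = best_host.get(cand.element_id)
        host_bits = host.bit_score if host is not None else None
        keep = host_bits is None or cand.bit_score > host_bits
        decisions.append(
            FilterDecision(
                element_id=cand.element_id,
                forward_bits=cand.bit_score,
                host_bits=host_bits,
                retained=keep,
                host_subject=host.subject_id if host is not None else None,
            )
        )
        (retained if keep else removed).append(cand)
    return retained, removed, decisions


def assign_taxonomy(
    candidates: Iterable[CandidateElement], metadata: MetadataTable
) -> list[AnnotatedElement]:
    """Transfer the best-hit protein's metadata to each candidate.

    Candidates whose best subject is missing from the metadata table are
    annotated with the "NA" sentinel in every taxonomy field and kept (the
    mismatch is logged, never silently dropped).
    """
    out: list[AnnotatedElement] = []
    for cand in candidates:
        row = metadata.get(cand.best_subject)
        if row is None:
            logger.warning(
                "best subject %s of element %s missing from metadata; taxonomy set to NA",
                cand.best_subject,
                cand.element_id,
            )
            taxonomy = {}
        else:
            taxonomy = dict(
                species=row.species,
                genus=row.genus,
                family=row.family,
                molecule_type=row.molecule_type,
                protein_product=row.protein_product,
                host=row.host,
            )
        out.append(
            AnnotatedElement(
                element_id=cand.element_id,
                contig_id=cand.contig_id,
                start=cand.start,
                end=cand.end,
                strand=cand.strand,
                best_subject=cand.best_subject,
                bit_score=cand.bit_score,
                e_value=cand.e_value,
                percent_identity=cand.percent_identity,
                **taxonomy,
            )
        )
    return out
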