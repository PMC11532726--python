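"""Flanking-sequence extraction (pipeline step VI).

The genomic context on either side of an element carries the evidence used
downstream to validate an integration: host genes, transposable elements,
target-site signatures. Each final element yields two flank records (left
and right, forward-strand orientation), clamped at contig edges with an
explicit truncation flag. Element strand is metadata only — downstream users
reverse-complement if they need element-relative orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import SequenceRecord, write_fasta

__all__ = ["FlankRecord", "extract_flanks", "write_flank_outputs", "DEFAULT_FLANK_LENGTH"]

DEFAULT_FLANK_LENGTH = 10_000


@dataclass(frozen=True)
class FlankRecord:
    """One flank of one element; empty (start=end=0, residues="") if absent."""

    element_id: str
    side: str  # "left" or "right"
    start: int
    end: int
    requested_length: int
    actual_length: int
    truncated: bool
    residues: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"bad flank side {self.side!r}")
        if self.actual_length != len(self.residues):
            raise ValueError("actual_length does not match residues")
        if self.actual_length > self.requested_length:
            raise ValueError("flank longer than requested")
        if self.truncated != (self.actual_length < self.requested_length):
            raise ValueError("inconsistent truncated flag")


def extract_flanks(
    assembly: Sequence[SequenceRecord] | Mapping[str, SequenceRecord],
    elements: Iterable,
    flank_length: int = DEFAULT_FLANK_LENGTH,
) -> list[FlankRecord]:
    """Two flanks per element: [start-flank_length, start-1] and [end+1, end+flank_length].

    Both are clamped to the contig; ``elements`` may be any objects with
    ``element_id``, ``contig_id``, ``start`` and ``end`` attributes.
    """
    if flank_length < 0:
        raise ValueError("flank_length must be >= 0")
    if not isinstance(assembly, Mapping):
        assembly = {rec.id: rec for rec in assembly}
    out: list[FlankRecord] = []
    for el in elements:
        contig = assembly.get(el.contig_id)
        if contig is None:
            raise ValueError(f"element {el.element_id} references unknown contig {el.contig_id}")
        L = len(contig)
        if not (1 <= el.start <= el.end <= L):
            raise ValueError(
                f"element {el.element_id} span ({el.start},{el.end}) outside contig of length {L}"
            )
        left_start = max(1, el.start - flank_length)
        left_end = el.start - 1
        right_start = el.end + 1
        right_end = min(L, el.end + flank_length)
        for side, s, e in (("left", left_start, left_end), ("right", right_start, right_end)):
            if e >= s:
                residues = contig.residues[s - 1 : e]
            else:
                s = e = 0
                residues = ""
            out.append(
                FlankRecord(
                    element_id=el.element_id,
                    side=side,
                    start=s,
                    end=e,
                    requested_length=flank_length,
                    actual_length=len(residues),
                    truncated=len(residues) < flank_length,
                    residues=residues,
                )
            )
    return out


def write_flank_outputs(flanks: Sequence[FlankRecord], fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write non-empty flanks as FASTA (ids "element|side") and all as TSV."""
    records = [
        SequenceRecord(id=f"{f.element_id}|{f.side}", residues=f.residues)
        for f in flanks
        if f.residues
    ]
    write_fasta(records, fasta_path)
    with open(tsv_path, "w") as handle:
        handle.write("element_id\tside\tstart\tend\trequested_length\tactual_length\ttruncated\n")
        for f in flanks:
            handle.write(
                f"{f.element_id}\t{f.side}\t{f.start}\t{f.end}\t"
                f"{f.requested_length}\t{f.actual_length}\t{str(f.truncated).lower()}\n"
            )
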