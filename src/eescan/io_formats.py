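"""Readers, writers and core record types shared by every pipeline stage.

All genomic coordinates held in memory are 1-based inclusive on the forward
strand with an explicit strand flag. The reversed-coordinate dialect of raw
translated-search tabular output ("outfmt 6") exists only at the I/O
boundary: :func:`read_tabular_hits` normalizes it on the way in and
:func:`write_tabular_hits` restores it on the way out. BED output is 0-based
half-open, converted at write time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "FormatError",
    "SequenceRecord",
    "MetadataRow",
    "MetadataTable",
    "AlignmentHit",
    "ElementTableRow",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "read_tabular_hits",
    "write_tabular_hits",
    "write_element_table",
    "read_element_table",
    "write_bed",
]

NA = "NA"

# IUPAC nucleotide codes (incl. ambiguity) and the amino-acid alphabet of the
# BLOSUM matrices (incl. B/Z ambiguity, X unknown, * stop).
NUCLEOTIDE_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")

METADATA_FIELDS = (
    "accession",
    "species",
    "genus",
    "family",
    "molecule_type",
    "protein_product",
    "host",
)

ELEMENT_TABLE_COLUMNS = (
    "element_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "subject_accession",
    "bit_score",
    "e_value",
    "percent_identity",
    "species",
    "genus",
    "family",
    "molecule_type",
    "protein_product",
    "host",
    "n_fragments",
    "fragment_coords",
)


class FormatError(ValueError):
    """Malformed external input; message locates the offending record/line."""


@dataclass(frozen=True)
class SequenceRecord:
    """One named nucleotide or protein sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header;
    ``description`` is the remainder (possibly empty). ``residues`` is
    upper-case.
    """

    id: str
    residues: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class MetadataRow:
    """Taxonomic annotation for one database protein; blanks stored as "NA"."""

    accession: str
    species: str = NA
    genus: str = NA
    family: str = NA
    molecule_type: str = NA
    protein_product: str = NA
    host: str = NA


class MetadataTable:
    """Metadata rows keyed by protein accession."""

    def __init__(self, rows: Iterable[MetadataRow]):
        self._rows: dict[str, MetadataRow] = {}
        for row in rows:
            if not row.accession:
                raise FormatError("metadata row with empty accession")
            if row.accession in self._rows:
                raise FormatError(f"duplicate metadata accession: {row.accession!r}")
            self._rows[row.accession] = row

    def __len__(self) -> int:
        return len(self._rows)

    def __contains__(self, accession: str) -> bool:
        return accession in self._rows

    def __iter__(self) -> Iterator[MetadataRow]:
        return iter(self._rows.values())

    def get(self, accession: str) -> MetadataRow | None:
        return self._rows.get(accession)

    def __getitem__(self, accession: str) -> MetadataRow:
        return self._rows[accession]


@dataclass(frozen=True)
class AlignmentHit:
    """One translated-search local alignment in normalized coordinates.

    ``q_start``/``q_end`` are 1-based inclusive nucleotide positions on the
    forward strand of the contig with ``q_start <= q_end``; ``strand`` records
    the original orientation. ``s_start``/``s_end`` are 1-based inclusive
    amino-acid positions on the subject protein. ``frame`` is the blastx-style
    reading frame in {+1,+2,+3,-1,-2,-3} and its sign matches ``strand``.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_openings: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    frame: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"q_start > q_end in hit {self.query_id}/{self.subject_id}")
        if self.s_start > self.s_end:
            raise ValueError(f"s_start > s_end in hit {self.query_id}/{self.subject_id}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"bad frame {self.frame}")
        if (self.frame > 0) != (self.strand == "+"):
            raise ValueError(f"frame {self.frame} inconsistent with strand {self.strand}")
        if self.q_end - self.q_start + 1 > 3 * self.alignment_length:
            raise ValueError(
                f"nucleotide footprint {self.q_end - self.q_start + 1} exceeds "
                f"3 x alignment_length ({self.alignment_length}) in "
                f"{self.query_id}/{self.subject_id}"
            )


@dataclass(frozen=True)
class ElementTableRow:
    """One row of the final element table (the unified output schema)."""

    element_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    subject_accession: str
    bit_score: float
    e_value: float
    percent_identity: float
    species: str = NA
    genus: str = NA
    family: str = NA
    molecule_type: str = NA
    protein_product: str = NA
    host: str = NA
    n_fragments: int = 1
    fragment_coords: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for element {self.element_id}")
        coords = self.fragment_coords or ((self.start, self.end),)
        object.__setattr__(self, "fragment_coords", tuple(tuple(c) for c in coords))
        if self.n_fragments != len(self.fragment_coords):
            raise ValueError(
                f"n_fragments={self.n_fragments} but {len(self.fragment_coords)} "
                f"fragment_coords for element {self.element_id}"
            )
        for s, e in self.fragment_coords:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(
                    f"fragment ({s},{e}) outside span ({self.start},{self.end}) "
                    f"for element {self.element_id}"
                )


def _validate_residues(seq_id: str, residues: str, alphabet: str) -> None:
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    for pos, ch in enumerate(residues, start=1):
        if ch not in allowed:
            raise FormatError(
                f"illegal {alphabet} residue {ch!r} at position {pos} "
                f"of sequence {seq_id!r}"
            )


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated :class:`SequenceRecord`.

    ``alphabet`` is ``"nucleotide"`` or ``"protein"``. Residues are
    upper-cased; duplicate ids, empty sequences and residues outside the
    declared alphabet are hard errors.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"alphabet must be 'nucleotide' or 'protein', got {alphabet!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            parts = header.split(None, 1)
            if not parts:
                raise FormatError(f"{path}: FASTA record with empty header")
            seq_id = parts[0]
            description = parts[1] if len(parts) > 1 else ""
            if seq_id in seen:
                raise FormatError(f"{path}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            residues = seq.replace(" ", "").upper()
            if not residues:
                raise FormatError(f"{path}: empty sequence for id {seq_id!r}")
            _validate_residues(seq_id, residues, alphabet)
            records.append(SequenceRecord(id=seq_id, residues=residues, description=description))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``line_width``."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for i in range(0, len(rec.residues), line_width):
                handle.write(rec.residues[i : i + line_width] + "\n")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_metadata(path: str | Path) -> MetadataTable:
    """Read the protein metadata table (TSV, or CSV auto-detected).

    The header must name all seven fields (order-insensitive, case- and
    space-insensitive). Blank cells become the explicit sentinel "NA".
    """
    with open(path, newline="") as handle:
        first = handle.readline()
        if not first:
            raise FormatError(f"{path}: empty metadata file")
        delim = _sniff_delimiter(first)
        header = [h.strip().lower().replace(" ", "_") for h in first.rstrip("\r\n").split(delim)]
        missing = [f for f in METADATA_FIELDS if f not in header]
        if missing:
            raise FormatError(f"{path}: metadata header missing column(s): {', '.join(missing)}")
        reader = csv.reader(handle, delimiter=delim)
        idx = {f: header.index(f) for f in METADATA_FIELDS}
        rows = []
        for lineno, cells in enumerate(reader, start=2):
            if not cells or all(not c.strip() for c in cells):
                continue
            if len(cells) < len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} columns, got {len(cells)}")
            values = {f: (cells[idx[f]].strip() or NA) for f in METADATA_FIELDS}
            if values["accession"] == NA:
                raise FormatError(f"{path}:{lineno}: empty accession")
            rows.append(MetadataRow(**values))
    try:
        return MetadataTable(rows)
    except FormatError as err:
        raise FormatError(f"{path}: {err}") from None


def _infer_frame(raw_qstart: int, strand: str) -> int:
    # Without the contig length the minus-strand blast frame is not
    # recoverable from the 12-column format; this positional convention is
    # applied symmetrically by reader and writer.
    f = (raw_qstart - 1) % 3 + 1
    return f if strand == "+" else -f


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Read 12/13-column tab-separated translated-search output.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore [frame]. Raw ``qstart > qend`` denotes a minus-strand
    hit; coordinates are normalized to ``q_start <= q_end`` with the strand
    flag set. When the 13th (frame) column is absent the frame is inferred
    from the raw qstart position and strand.
    """
    hits: list[AlignmentHit] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) not in (12, 13):
                raise FormatError(
                    f"{path}:{lineno}: expected 12 or 13 tab-separated columns, got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length = int(cols[3])
                mismatch = int(cols[4])
                gapopen = int(cols[5])
                raw_qstart, raw_qend = int(cols[6]), int(cols[7])
                s_start, s_end = int(cols[8]), int(cols[9])
                e_value = float(cols[10])
                bit_score = float(cols[11])
                frame = int(cols[12]) if len(cols) == 13 else None
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric value in numeric column") from None
            if raw_qstart > raw_qend:
                strand = "-"
                q_start, q_end = raw_qend, raw_qstart
            else:
                strand = "+"
                q_start, q_end = raw_qstart, raw_qend
            if frame is None:
                frame = _infer_frame(raw_qstart, strand)
            hits.append(
                AlignmentHit(
                    query_id=cols[0],
                    subject_id=cols[1],
                    percent_identity=pident,
                    alignment_length=length,
                    mismatches=mismatch,
                    gap_openings=gapopen,
                    q_start=q_start,
                    q_end=q_end,
                    s_start=s_start,
                    s_end=s_end,
                    strand=strand,
                    frame=frame,
                    e_value=e_value,
                    bit_score=bit_score,
                )
            )
    return hits


def _fmt_float(x: float) -> str:
    return f"{x:g}"


def write_tabular_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits in the 13-column tabular dialect (raw orientation restored)."""
    with open(path, "w") as handle:
        for h in hits:
            if h.strand == "-":
                raw_qstart, raw_qend = h.q_end, h.q_start
            else:
                raw_qstart, raw_qend = h.q_start, h.q_end
            handle.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.3f}",
                        str(h.alignment_length),
                        str(h.mismatches),
                        str(h.gap_openings),
                        str(raw_qstart),
                        str(raw_qend),
                        str(h.s_start),
                        str(h.s_end),
                        _fmt_float(h.e_value),
                        f"{h.bit_score:.1f}",
                        str(h.frame),
                    ]
                )
                + "\n"
            )


def _coords_to_str(coords: Sequence[tuple[int, int]]) -> str:
    return ";".join(f"{s}-{e}" for s, e in coords)


def _coords_from_str(text: str) -> tuple[tuple[int, int], ...]:
    if not text:
        return ()
    out = []
    for part in text.split(";"):
        s, _, e = part.partition("-")
        out.append((int(s), int(e)))
    return tuple(out)


def write_element_table(rows: Iterable[ElementTableRow], path: str | Path) -> None:
    """Write the final element table as TSV with a fixed column order."""
    with open(path, "w") as handle:
        handle.write("\t".join(ELEMENT_TABLE_COLUMNS) + "\n")
        for r in rows:
            handle.write(
                "\t".join(
                    [
                        r.element_id,
                        r.contig_id,
                        str(r.start),
                        str(r.end),
                        r.strand,
                        r.subject_accession,
                        f"{r.bit_score:.1f}",
                        _fmt_float(r.e_value),
                        f"{r.percent_identity:.3f}",
                        r.species,
                        r.genus,
                        r.family,
                        r.molecule_type,
                        r.protein_product,
                        r.host,
                        str(r.n_fragments),
                        _coords_to_str(r.fragment_coords),
                    ]
                )
                + "\n"
            )


def read_element_table(path: str | Path) -> list[ElementTableRow]:
    """Read back an element table written by :func:`write_element_table`."""
    rows: list[ElementTableRow] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != list(ELEMENT_TABLE_COLUMNS):
            raise FormatError(f"{path}: unexpected element table header")
        for lineno, line in enumerate(handle, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != len(ELEMENT_TABLE_COLUMNS):
                raise FormatError(f"{path}:{lineno}: wrong column count")
            rows.append(
                ElementTableRow(
                    element_id=cols[0],
                    contig_id=cols[1],
                    start=int(cols[2]),
                    end=int(cols[3]),
                    strand=cols[4],
                    subject_accession=cols[5],
                    bit_score=float(cols[6]),
                    e_value=float(cols[7]),
                    percent_identity=float(cols[8]),
                    species=cols[9],
                    genus=cols[10],
                    family=cols[11],
                    molecule_type=cols[12],
                    protein_product=cols[13],
                    host=cols[14],
                    n_fragments=int(cols[15]),
                    fragment_coords=_coords_from_str(cols[16]),
                )
            )
    return rows


def write_bed(rows: Iterable[ElementTableRow], path: str | Path) -> None:
    """Write elements as BED6 (0-based half-open; score = min(1000, round(bits)))."""
    with open(path, "w") as handle:
        for r in rows:
            score = min(1000, round(r.bit_score))
            handle.write(
                f"{r.contig_id}\t{r.start - 1}\t{r.end}\t{r.element_id}\t{score}\t{r.strand}\n"
            )
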