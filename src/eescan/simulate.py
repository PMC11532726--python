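"""Synthetic fixture generation and the boundary-tolerance evaluation harness.

Real benchmarks of endogenous-element finders require multi-gigabyte genome
assemblies and dated database snapshots. This module replaces them at desk
scale: it generates a random host genome, synthetic "viral" proteins with
taxonomy, host-like bait proteins, and plants reverse-translated copies of
the proteins into the genome — either intact, or shattered into ordered
fragments separated by host-like spacers — recording every fragment in a
ground-truth table. Predictions are then scored against the truth with a
configurable boundary tolerance (default 100 nt at each end).

What the generator emulates: insertion, point-substitution decay,
fragmentation with frameshifting spacers, both strands. What it does not:
indels, transposable-element landscapes, or empirically calibrated decay.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    MetadataRow,
    MetadataTable,
    SequenceRecord,
)
from .translated_search import _CODON_TABLE, reverse_complement

__all__ = [
    "TruthRecord",
    "EvalResult",
    "FixtureSet",
    "generate_host_genome",
    "generate_proteins",
    "generate_bait_proteins",
    "reverse_translate",
    "mutate_nucleotides",
    "mutate_protein",
    "plant_insertions",
    "evaluate_predictions",
    "standard_fixture",
    "reciprocal_fixture",
    "write_truth",
    "read_truth",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"

# amino acid -> synonymous codons (standard genetic code)
_SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TABLE.items()):
    if _aa != "*":
        _SYNONYMS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted fragment (coordinates on the final assembly)."""

    contig_id: str
    start: int
    end: int
    source_protein: str
    event_id: str
    fragment_index: int
    mutated_fraction: float
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("truth record with start > end")
        if not (0.0 <= self.mutated_fraction <= 1.0):
            raise ValueError("mutated_fraction outside [0, 1]")


@dataclass(frozen=True)
class EvalResult:
    """Recall/precision of predictions against planted truth events."""

    n_truth_events: int
    n_predicted: int
    n_matched: int
    recall: float
    precision: float
    mean_boundary_error: float
    tolerance: int

    def __post_init__(self) -> None:
        if self.n_truth_events:
            if abs(self.recall - self.n_matched / self.n_truth_events) > 1e-9:
                raise ValueError("recall inconsistent with counts")
        if not (0.0 <= self.precision <= 1.0):
            raise ValueError("precision outside [0, 1]")


@dataclass
class FixtureSet:
    """One complete synthetic input set plus its ground truth."""

    genome: list[SequenceRecord]
    proteins: list[SequenceRecord]
    metadata: MetadataTable
    baits: list[SequenceRecord]
    truth: list[TruthRecord]


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(tag)])


def generate_host_genome(
    n_contigs: int,
    length_range: tuple[int, int],
    gc_fraction: float = 0.5,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Random i.i.d. host contigs with P(G)+P(C) == gc_fraction."""
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must be in (0, 1)")
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length_range")
    rng = _rng(seed, 1)
    p = np.array([(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2])
    out = []
    for i in range(n_contigs):
        length = int(rng.integers(lo, hi + 1))
        bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)
        out.append(
            SequenceRecord(id=f"contig{i + 1}", residues=bases.tobytes().decode(), description="synthetic host contig")
        )
    return out


def _random_sequence(rng: np.random.Generator, alphabet: str, length: int) -> str:
    idx = rng.integers(0, len(alphabet), size=length)
    return "".join(alphabet[i] for i in idx)


def generate_proteins(
    n: int,
    length_range: tuple[int, int] = (150, 250),
    seed: int = 0,
    prefix: str = "SYNV",
) -> tuple[list[SequenceRecord], MetadataTable]:
    """Synthetic database proteins, one taxon (family/genus/species) each."""
    rng = _rng(seed, 2)
    lo, hi = length_range
    records, rows = [], []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        acc = f"{prefix}{i + 1:03d}"
        records.append(
            SequenceRecord(
                id=acc,
                residues=_random_sequence(rng, _AA20, length),
                description=f"synthetic protein {i + 1}",
            )
        )
        rows.append(
            MetadataRow(
                accession=acc,
                species=f"Synthetic virus {i + 1}",
                genus=f"Syngenus{i + 1}",
                family=f"Synfam{i + 1}",
                molecule_type="ssRNA",
                protein_product=f"synthetic polyprotein {i + 1}",
                host="synthetic host",
            )
        )
    return records, MetadataTable(rows)


def generate_bait_proteins(
    n: int,
    length_range: tuple[int, int] = (150, 300),
    seed: int = 0,
    hypothetical_fraction: float = 0.3,
) -> list[SequenceRecord]:
    """Host-like decoy proteins; a fraction carry uninformative annotations."""
    rng = _rng(seed, 3)
    lo, hi = length_range
    n_hypo = int(round(n * hypothetical_fraction))
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        if i < n_hypo:
            desc = f"hypothetical protein LOC{i + 1}"
        else:
            desc = f"host enzyme {i + 1}"
        out.append(
            SequenceRecord(id=f"HOST{i + 1:03d}", residues=_random_sequence(rng, _AA20, length), description=desc)
        )
    return out


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Nucleotide sequence translating (frame +1) back to ``protein`` exactly.

    Codons are drawn uniformly from each residue's synonymous set; residues
    without codons (X and other ambiguity codes) become "NNN".
    """
    codons = []
    for aa in protein:
        options = _SYNONYMS.get(aa)
        if options is None:
            codons.append("NNN")
        else:
            codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def mutate_nucleotides(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, float]:
    """Point substitutions at ``rate`` per base; returns (sequence, observed fraction)."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    if rate == 0.0 or not seq:
        return seq, 0.0
    arr = list(seq)
    hit = rng.random(len(arr)) < rate
    n_sub = 0
    for i in np.flatnonzero(hit):
        old = arr[i]
        choices = [b for b in _NT if b != old]
        arr[i] = choices[int(rng.integers(0, 3))]
        n_sub += 1
    return "".join(arr), n_sub / len(arr)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Amino-acid substitutions at ``rate`` per residue (to a different residue)."""
    arr = list(seq)
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [a for a in _AA20 if a != arr[i]]
        arr[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(arr)


def _gc_of(records: Sequence[SequenceRecord]) -> float:
    gc = total = 0
    for rec in records:
        gc += rec.residues.count("G") + rec.residues.count("C")
        total += len(rec)
    return gc / total if total else 0.5


def _split_even(n: int, k: int) -> list[int]:
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def plant_insertions(
    assembly: Sequence[SequenceRecord],
    proteins: Sequence[SequenceRecord],
    n_intact: int = 10,
    n_fragmented: int = 10,
    fragments_per_event: int = 3,
    intra_event_gap_range: tuple[int, int] = (40, 95),
    mutation_rate: float = 0.0,
    strand_mix: float = 0.5,
    seed: int = 0,
    min_event_spacing: int = 15_000,
    edge_margin: int = 2_000,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Insert reverse-translated protein copies into the assembly.

    Intact events insert one contiguous copy; fragmented events insert
    ``fragments_per_event`` ordered pieces of one copy separated by
    host-like spacers whose lengths are drawn from ``intra_event_gap_range``
    and forced off multiples of three (a frameshift, the typical signature
    of a degraded insertion). Events are assigned source proteins
    round-robin and placed with at least ``min_event_spacing`` nt between
    insertion points on a contig. Point substitutions are applied at
    ``mutation_rate`` per base; ``strand_mix`` is the probability an event
    integrates on the minus strand. Truth coordinates refer to the modified
    assembly. Raises if the genome cannot host the requested events.
    """
    if not proteins:
        raise ValueError("no source proteins supplied")
    rng = _rng(seed, 4)
    gc = _gc_of(assembly)
    n_events = n_intact + n_fragmented
    if n_events == 0:
        return list(assembly), []

    # distribute events across contigs round-robin, check capacity per contig
    per_contig: dict[int, list[int]] = {}
    usable = [i for i, rec in enumerate(assembly) if len(rec) > 2 * edge_margin + min_event_spacing]
    if not usable:
        raise ValueError("genome too small to host requested events")
    for ev in range(n_events):
        cidx = usable[ev % len(usable)]
        per_contig.setdefault(cidx, []).append(ev)

    event_kind = ["intact"] * n_intact + ["fragmented"] * n_fragmented
    event_protein = [proteins[ev % len(proteins)] for ev in range(n_events)]
    event_strand = ["-" if rng.random() < strand_mix else "+" for _ in range(n_events)]

    new_assembly = list(assembly)
    truth: list[TruthRecord] = []
    for cidx, events in sorted(per_contig.items()):
        contig = assembly[cidx]
        L = len(contig)
        k = len(events)
        span = L - 2 * edge_margin - (k - 1) * min_event_spacing
        if span < k:
            raise ValueError(
                f"contig {contig.id} (length {L}) too small to host {k} events "
                f"with spacing {min_event_spacing}"
            )
        raw = np.sort(rng.integers(0, span, size=k))
        sites = [int(edge_margin + raw[i] + i * min_event_spacing) for i in range(k)]

        parts: list[str] = []
        cursor = 0
        offset = 0
        for site, ev in zip(sites, events):
            parts.append(contig.residues[cursor:site])
            cursor = site
            block, fragments = _build_event_block(
                event_protein[ev],
                event_kind[ev],
                fragments_per_event,
                intra_event_gap_range,
                mutation_rate,
                event_strand[ev],
                gc,
                rng,
            )
            for frag_idx, (fs, fe, frac) in enumerate(fragments):
                truth.append(
                    TruthRecord(
                        contig_id=contig.id,
                        start=site + offset + fs,
                        end=site + offset + fe,
                        source_protein=event_protein[ev].id,
                        event_id=f"ev{ev + 1}",
                        fragment_index=frag_idx,
                        mutated_fraction=frac,
                        strand=event_strand[ev],
                    )
                )
            parts.append(block)
            offset += len(block)
        parts.append(contig.residues[cursor:])
        new_assembly[cidx] = SequenceRecord(
            id=contig.id, residues="".join(parts), description=contig.description
        )
    return new_assembly, truth


def _build_event_block(
    protein: SequenceRecord,
    kind: str,
    fragments_per_event: int,
    gap_range: tuple[int, int],
    mutation_rate: float,
    strand: str,
    gc: float,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int, float]]]:
    """Build the inserted block; fragment coords are 1-based within the block."""
    coding = reverse_translate(protein.residues, rng)
    if kind == "intact":
        pieces = [coding]
    else:
        sizes = _split_even(len(protein.residues), fragments_per_event)
        pieces, pos = [], 0
        for s in sizes:
            pieces.append(coding[3 * pos : 3 * (pos + s)])
            pos += s

    block_parts: list[str] = []
    fragments: list[tuple[int, int, float]] = []  # (start, end, mutated_fraction) in block
    cursor = 0
    for i, piece in enumerate(pieces):
        if i > 0:
            lo, hi = gap_range
            gap = int(rng.integers(lo, hi + 1))
            # shift every spacer to length ≡ 1 (mod 3): successive fragments
            # then occupy pairwise distinct reading frames, so each planted
            # fragment corresponds to exactly one alignment and the ground
            # truth is unambiguous
            gap += (1 - gap) % 3
            spacer = _host_like(rng, gap, gc)
            block_parts.append(spacer)
            cursor += gap
        mutated, frac = mutate_nucleotides(piece, mutation_rate, rng)
        block_parts.append(mutated)
        fragments.append((cursor + 1, cursor + len(mutated), frac))
        cursor += len(mutated)
    block = "".join(block_parts)
    if strand == "-":
        n = len(block)
        block = reverse_complement(block)
        fragments = [(n - fe + 1, n - fs + 1, frac) for fs, fe, frac in reversed(fragments)]
    return block, fragments


def _host_like(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(_NT[i] for i in idx)


# ---------------------------------------------------------------------------
# Evaluation harness
# ---------------------------------------------------------------------------


def evaluate_predictions(
    predictions: Sequence,
    truth: Sequence[TruthRecord],
    tolerance: int = 100,
    match_fragments: bool = False,
) -> EvalResult:
    """Match predictions to truth events within a boundary tolerance.

    A truth event is matched when a predicted element's start and end are
    each within ``tolerance`` nt of the event's overall span (minimum
    fragment start to maximum fragment end); with ``match_fragments=True``
    (unmerged evaluation) matching any single fragment's boundaries
    suffices. Each prediction matches at most one event, assigned greedily
    by nucleotide overlap with deterministic tie-breaking.
    """
    events: dict[str, list[TruthRecord]] = {}
    for t in truth:
        events.setdefault(t.event_id, []).append(t)
    spans = {
        ev: (frags[0].contig_id, min(f.start for f in frags), max(f.end for f in frags))
        for ev, frags in events.items()
    }

    pairs = []  # (overlap, pred_idx, event_id, boundary_error)
    for pidx, pred in enumerate(predictions):
        for ev, (contig, es, ee) in spans.items():
            if pred.contig_id != contig:
                continue
            overlap = min(pred.end, ee) - max(pred.start, es) + 1
            if overlap <= 0:
                continue
            if match_fragments:
                errs = [
                    (abs(pred.start - f.start) + abs(pred.end - f.end)) / 2
                    for f in events[ev]
                    if abs(pred.start - f.start) <= tolerance and abs(pred.end - f.end) <= tolerance
                ]
                if not errs:
                    continue
                err = min(errs)
            else:
                if abs(pred.start - es) > tolerance or abs(pred.end - ee) > tolerance:
                    continue
                err = (abs(pred.start - es) + abs(pred.end - ee)) / 2
            pairs.append((overlap, pidx, ev, err))

    pairs.sort(key=lambda p: (-p[0], predictions[p[1]].start, p[1], p[2]))
    matched_preds: set[int] = set()
    matched_events: set[str] = set()
    errors: list[float] = []
    for overlap, pidx, ev, err in pairs:
        if pidx in matched_preds or ev in matched_events:
            continue
        matched_preds.add(pidx)
        matched_events.add(ev)
        errors.append(err)

    n_truth_events = len(events)
    n_predicted = len(predictions)
    n_matched = len(matched_events)
    return EvalResult(
        n_truth_events=n_truth_events,
        n_predicted=n_predicted,
        n_matched=n_matched,
        recall=(n_matched / n_truth_events) if n_truth_events else 0.0,
        precision=(len(matched_preds) / n_predicted) if n_predicted else 0.0,
        mean_boundary_error=(sum(errors) / len(errors)) if errors else 0.0,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# Canned fixtures
# ---------------------------------------------------------------------------


def standard_fixture(seed: int = 0, mutation_rate: float = 0.0) -> FixtureSet:
    """The standard planted-element recovery fixture.

    5 contigs of 100 kb, 8 synthetic database proteins, 10 intact and 10
    fragmented-into-3 insertions (round-robin over proteins, mixed strands),
    20 host-like bait proteins unrelated to the database.
    """
    genome = generate_host_genome(5, (100_000, 100_000), gc_fraction=0.5, seed=seed)
    proteins, metadata = generate_proteins(8, (150, 250), seed=seed)
    baits = generate_bait_proteins(20, (150, 300), seed=seed)
    planted, truth = plant_insertions(
        genome,
        proteins,
        n_intact=10,
        n_fragmented=10,
        fragments_per_event=3,
        intra_event_gap_range=(40, 95),
        mutation_rate=mutation_rate,
        strand_mix=0.5,
        seed=seed,
    )
    return FixtureSet(genome=planted, proteins=proteins, metadata=metadata, baits=baits, truth=truth)


def reciprocal_fixture(seed: int = 0) -> FixtureSet:
    """Fixture exercising the reciprocal host filter.

    Three planted "elements" are exact copies of bait (host) proteins while
    the database carries only diverged homologs of them (10% amino-acid
    substitutions), so their reverse bitscore beats the forward one and all
    three must be removed. Three genuine database-protein insertions must
    survive the filter.
    """
    rng = _rng(seed, 5)
    genome = generate_host_genome(2, (60_000, 60_000), gc_fraction=0.5, seed=seed + 10)
    viral, metadata_viral = generate_proteins(3, (150, 220), seed=seed + 11, prefix="SYNV")
    host_sources = generate_bait_proteins(3, (150, 220), seed=seed + 12, hypothetical_fraction=0.34)
    # database: real synthetic virals + diverged copies of the host proteins
    diverged = [
        SequenceRecord(
            id=f"DIVG{i + 1:03d}",
            residues=mutate_protein(h.residues, 0.10, rng),
            description=f"diverged homolog of {h.id}",
        )
        for i, h in enumerate(host_sources)
    ]
    rows = list(metadata_viral) + [
        MetadataRow(
            accession=d.id,
            species=f"Synthetic ancient virus {i + 1}",
            genus=f"Divgenus{i + 1}",
            family=f"Divfam{i + 1}",
            molecule_type="dsDNA",
            protein_product="host-homologous protein",
            host="synthetic host",
        )
        for i, d in enumerate(diverged)
    ]
    db = viral + diverged
    other_baits = generate_bait_proteins(10, (150, 300), seed=seed + 13)
    baits = host_sources + other_baits
    planted, truth = plant_insertions(
        genome,
        viral + host_sources,  # round-robin: 3 viral then 3 host-copy events
        n_intact=6,
        n_fragmented=0,
        mutation_rate=0.0,
        strand_mix=0.5,
        seed=seed + 14,
        min_event_spacing=12_000,
    )
    return FixtureSet(
        genome=planted, proteins=db, metadata=MetadataTable(rows), baits=baits, truth=truth
    )


# ---------------------------------------------------------------------------
# Truth table I/O
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = (
    "event_id",
    "fragment_index",
    "contig_id",
    "start",
    "end",
    "strand",
    "source_protein",
    "mutated_fraction",
)


def write_truth(truth: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_TRUTH_COLUMNS)
        for t in truth:
            writer.writerow(
                [
                    t.event_id,
                    t.fragment_index,
                    t.contig_id,
                    t.start,
                    t.end,
                    t.strand,
                    t.source_protein,
                    f"{t.mutated_fraction:.6f}",
                ]
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for row in reader:
            out.append(
                TruthRecord(
                    contig_id=row["contig_id"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    source_protein=row["source_protein"],
                    event_id=row["event_id"],
                    fragment_index=int(row["fragment_index"]),
                    mutated_fraction=float(row["mutated_fraction"]),
                    strand=row["strand"],
                )
            )
    return out
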