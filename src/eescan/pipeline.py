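"""End-to-end orchestration of the six pipeline stages.

Order: clean assembly -> translated search -> candidate collapse ->
reciprocal host filter -> taxonomy transfer -> merging -> flank extraction.
Outputs in the run directory: the final element table (TSV + BED + FASTA),
flanks (FASTA + TSV), the per-candidate filter decision table, the cleaning
report, and a JSON run manifest with per-stage counts. Intermediate hit
tables live in a temporary subdirectory that is deleted on success unless
``keep_temporary`` is set.
"""

from __future__ import annotations

import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .io_formats import (
    ElementTableRow,
    FormatError,
    SequenceRecord,
    read_fasta,
    read_metadata,
    read_tabular_hits,
    write_bed,
    write_element_table,
    write_fasta,
    write_tabular_hits,
)
from .preprocess import (
    DEFAULT_BAIT_EXCLUDE_PATTERNS,
    DEFAULT_MIN_CONTIG_LENGTH,
    filter_bait_proteins,
    filter_short_contigs,
)
from .translated_search import SearchParams, run_builtin_search, run_external_search
from .element_calling import (
    assign_taxonomy,
    extract_candidate_sequences,
    hits_to_candidates,
    reciprocal_filter,
)
from .merging import MergeParams, merge_elements
from .flanks import DEFAULT_FLANK_LENGTH, extract_flanks, write_flank_outputs

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    """Everything a full run needs: the four inputs plus stage parameters."""

    genome: str | Path
    database: str | Path
    metadata: str | Path
    baits: str | Path
    output_dir: str | Path
    search: SearchParams = field(default_factory=SearchParams)
    merge: MergeParams = field(default_factory=MergeParams)
    min_contig_length: int = DEFAULT_MIN_CONTIG_LENGTH
    flank_length: int = DEFAULT_FLANK_LENGTH
    filter_baits: bool = False
    bait_exclude_patterns: tuple[str, ...] = DEFAULT_BAIT_EXCLUDE_PATTERNS
    keep_temporary: bool = False
    precomputed_hits: str | Path | None = None


@dataclass
class RunManifest:
    """Structured record of one run: version, config and per-stage counts."""

    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)

    def check_consistency(self) -> None:
        c = self.counts
        if c.get("candidates") != c.get("retained", 0) + c.get("removed", 0):
            raise ValueError("manifest inconsistency: candidates != retained + removed")
        if c.get("merged_fragments_total") != c.get("retained"):
            raise ValueError("manifest inconsistency: sum of n_fragments != retained elements")
        if c.get("flank_records") != 2 * c.get("merged_elements", 0):
            raise ValueError("manifest inconsistency: flank records != 2 x merged elements")

    def write(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, default=str)
            handle.write("\n")


@dataclass
class PipelineResult:
    elements: list[ElementTableRow]
    manifest: RunManifest
    output_dir: Path


def _config_snapshot(config: PipelineConfig) -> dict:
    snap = asdict(config)
    for key in ("genome", "database", "metadata", "baits", "output_dir", "precomputed_hits"):
        if snap[key] is not None:
            snap[key] = str(snap[key])
    return snap


def validate_inputs(config: PipelineConfig) -> list[str]:
    """Parse-check the four inputs; returns warnings (hard failures raise).

    Errors name which of the four inputs is at fault; incomplete metadata
    coverage of the database is a warning, not an error.
    """
    warnings: list[str] = []
    try:
        read_fasta(config.genome, "nucleotide")
    except (OSError, FormatError) as err:
        raise FormatError(f"genome input invalid: {err}") from None
    try:
        db = read_fasta(config.database, "protein")
    except (OSError, FormatError) as err:
        raise FormatError(f"protein database input invalid: {err}") from None
    try:
        metadata = read_metadata(config.metadata)
    except (OSError, FormatError) as err:
        raise FormatError(f"metadata input invalid: {err}") from None
    try:
        read_fasta(config.baits, "protein")
    except (OSError, FormatError) as err:
        raise FormatError(f"baits input invalid: {err}") from None
    covered = sum(1 for rec in db if rec.id in metadata)
    if not covered:
        raise FormatError("metadata input invalid: covers no database accession")
    if covered < len(db):
        warnings.append(f"metadata covers {covered}/{len(db)} database proteins ({100.0 * covered / len(db):.1f}%)")
    return warnings


def _search(assembly, db, params: SearchParams, workdir: Path):
    if params.backend == "builtin":
        return run_builtin_search(assembly, db, params)
    return run_external_search(assembly, db, params, workdir)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages and write the output file set.

    An empty result at any stage completes the run with empty outputs and a
    warning; malformed inputs or internal inconsistencies raise.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tmp_dir = out_dir / "tmp"
    tmp_dir.mkdir(exist_ok=True)

    manifest = RunManifest(version=__version__, config=_config_snapshot(config))
    counts = manifest.counts
    t0 = time.monotonic()

    warnings = validate_inputs(config)
    manifest.warnings.extend(warnings)
    for w in warnings:
        logger.warning("%s", w)

    genome = read_fasta(config.genome, "nucleotide")
    db = read_fasta(config.database, "protein")
    metadata = read_metadata(config.metadata)
    baits = read_fasta(config.baits, "protein")
    counts["contigs_input"] = len(genome)
    counts["database_proteins"] = len(db)
    counts["baits_input"] = len(baits)

    # stage I: cleaning
    kept, report = filter_short_contigs(genome, config.min_contig_length)
    counts["contigs_kept"] = report.n_kept
    counts["contigs_removed"] = report.n_removed
    with open(out_dir / "cleaning_report.tsv", "w") as handle:
        handle.write("contig_id\treason\n")
        for cid in report.removed_ids:
            handle.write(f"{cid}\tshorter_than_{report.min_length}\n")
    baits_kept, baits_removed = filter_bait_proteins(
        baits, config.bait_exclude_patterns, enabled=config.filter_baits
    )
    counts["baits_kept"] = len(baits_kept)
    counts["baits_excluded"] = len(baits_removed)
    manifest.timings_s["clean"] = round(time.monotonic() - t0, 3)

    # stage II: translated search
    t1 = time.monotonic()
    if config.precomputed_hits is not None:
        hits = read_tabular_hits(config.precomputed_hits)
    elif not kept:
        manifest.warnings.append("no contigs pass the length filter; empty result")
        hits = []
    else:
        hits = _search(kept, db, config.search, tmp_dir)
    write_tabular_hits(hits, tmp_dir / "forward_hits.tsv")
    counts["forward_hits"] = len(hits)
    manifest.timings_s["search"] = round(time.monotonic() - t1, 3)

    # stages III-IV: candidates, reciprocal filter, taxonomy
    t2 = time.monotonic()
    candidates = hits_to_candidates(hits)
    counts["candidates"] = len(candidates)
    if candidates:
        genome_by_id = {rec.id: rec for rec in kept}
        cand_seqs = extract_candidate_sequences(genome_by_id, candidates)
        write_fasta(cand_seqs, tmp_dir / "candidates.fna")
        if baits_kept:
            host_hits = _search(cand_seqs, baits_kept, config.search, tmp_dir / "reverse")
        else:
            host_hits = []
        write_tabular_hits(host_hits, tmp_dir / "reverse_hits.tsv")
        retained, removed, decisions = reciprocal_filter(candidates, host_hits)
    else:
        manifest.warnings.append("no candidate elements; empty result")
        retained, removed, decisions = [], [], []
    counts["retained"] = len(retained)
    counts["removed"] = len(removed)
    with open(out_dir / "filter_decisions.tsv", "w") as handle:
        handle.write("element_id\tforward_bits\thost_bits\thost_subject\tretained\n")
        for d in decisions:
            host_bits = f"{d.host_bits:.1f}" if d.host_bits is not None else "NA"
            handle.write(
                f"{d.element_id}\t{d.forward_bits:.1f}\t{host_bits}\t"
                f"{d.host_subject or 'NA'}\t{str(d.retained).lower()}\n"
            )
    annotated = assign_taxonomy(retained, metadata)
    manifest.timings_s["filter"] = round(time.monotonic() - t2, 3)

    # stage V: merging
    t3 = time.monotonic()
    merged = merge_elements(annotated, config.merge)
    counts["merged_elements"] = len(merged)
    counts["merged_fragments_total"] = sum(m.n_fragments for m in merged)
    rows = [
        ElementTableRow(
            element_id=m.element_id,
            contig_id=m.contig_id,
            start=m.start,
            end=m.end,
            strand=m.strand,
            subject_accession=m.best_subject,
            bit_score=m.bit_score,
            e_value=m.e_value,
            percent_identity=m.percent_identity,
            species=m.species,
            genus=m.genus,
            family=m.family,
            molecule_type=m.molecule_type,
            protein_product=m.protein_product,
            host=m.host,
            n_fragments=m.n_fragments,
            fragment_coords=m.fragment_coords,
        )
        for m in merged
    ]
    write_element_table(rows, out_dir / "elements.tsv")
    write_bed(rows, out_dir / "elements.bed")
    genome_by_id = {rec.id: rec for rec in kept}
    element_records = [
        # forward-strand span including internal gaps of merged fragments
        SequenceRecord(
            id=m.element_id,
            residues=genome_by_id[m.contig_id].residues[m.start - 1 : m.end],
        )
        for m in merged
    ]
    write_fasta(element_records, out_dir / "elements.fna")
    manifest.timings_s["merge"] = round(time.monotonic() - t3, 3)

    # stage VI: flanks
    t4 = time.monotonic()
    flank_records = extract_flanks(genome_by_id, merged, config.flank_length) if merged else []
    counts["flank_records"] = len(flank_records)
    write_flank_outputs(flank_records, out_dir / "flanks.fna", out_dir / "flanks.tsv")
    manifest.timings_s["flanks"] = round(time.monotonic() - t4, 3)

    manifest.check_consistency()
    manifest.timings_s["total"] = round(time.monotonic() - t0, 3)
    manifest.write(out_dir / "manifest.json")

    if not config.keep_temporary:
        shutil.rmtree(tmp_dir, ignore_errors=True)

    return PipelineResult(elements=rows, manifest=manifest, output_dir=out_dir)
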