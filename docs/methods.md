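# Methods

`eescan` screens eukaryotic genome assemblies for endogenous viral and
bacterial elements (EVEs/EBEs): fragments of symbiont genomes that
integrated into the host germ line and have been inherited vertically ever
since. The pipeline follows the six steps that EVE/EBE studies converge on —
clean the assembly, search it by translated homology against a
viral/bacterial protein database, discard candidates better explained by
host genes, transfer taxonomy from the best database hit, merge fragmented
loci, and extract flanking context for downstream validation.

## Detection model

### Translated homology search

Endogenized elements are often tens of percent diverged from their closest
extant relative, so detection works in protein space: each contig is
translated in all six reading frames and the frame peptides are compared to
the protein database with Smith–Waterman local alignment under an affine
gap model (a gap of length *k* costs `gap_open + k·gap_extend`). The
default scoring is deliberately shallow — BLOSUM45, gap open 14 / extend 2,
word size 3 — because distant homology is the expected regime.

Raw scores *S* are converted to bitscores and e-values with Karlin–Altschul
statistics:

    bits = (λS − ln K) / ln 2        E = m·n·2^(−bits)

where *m* is the total translated query length (all frames, all contigs, in
amino acids) and *n* the total database residues. The bundled (λ, K) table
covers the common BLOSUM45/BLOSUM62 gap pairings; each entry was fitted
against full-precision NCBI BLAST+ 2.17 gapped statistics and agrees to
better than 0.001 bits. An unlisted (matrix, gap) triple is a hard error
rather than a silent approximation.

The builtin backend is seed-and-extend: exact `word_size`-mer matches seed
ungapped extensions, and only seeds whose ungapped score reaches a trigger
(default raw 30) open a gapped alignment window. The trigger exists purely
for tractability: on a 100 kb contig a 3-mer seed against a ~2,500-residue
database fires ~10⁴ times per frame by chance alone, while any hit able to
clear the default 10⁻⁵ e-value cutoff has raw score well above 180, so the
trigger cannot remove a reportable hit. Within each window, successive
locally optimal alignments are found by iterative masking (align, report,
mask the aligned query span with X, realign; bounded at 8 rounds), and each
Smith–Waterman optimum is decomposed at deep score valleys — cumulative
drop beyond an X-drop of 38 bits, the blastx default — into separate
segments, mirroring how blastx reports distinct HSPs rather than bridging
long internal deserts. Hit tables are deterministically sorted (contig,
start, descending bitscore, then fixed tie-breaks), so identical inputs
give byte-identical outputs.

External backends (`blastx`, `diamond blastx` with a verbatim sensitivity
mode) are invoked with the same matrix/gap/word-size/e-value parameters,
requesting the 13-column tabular format; blastx additionally runs with
composition-based statistics and SEG masking disabled so its scores are
comparable with the builtin backend, which applies no masking.

### Candidate calling and the reciprocal host filter

Hits on one contig whose nucleotide spans overlap by at least one base are
grouped transitively (strand-agnostic) into one candidate locus annotated
by its maximal-bitscore hit (ties: lower e-value, then lexicographic
accession). Abutting spans stay separate.

Many viral and bacterial proteins share deep ancestry with eukaryotic
genes, so every candidate sequence is re-searched against a host "bait"
protein set with the same scoring parameters. A candidate is retained only
if its forward bitscore strictly exceeds its best bitscore against the
baits; a tie is removed, which is conservative toward false positives.
Bitscores are database-size independent, which is what makes the two
searches comparable. Optionally, baits whose descriptions contain
"hypothetical" or "uncharacterized" (case-insensitive substrings,
configurable) are excluded first — such entries are frequently unannotated
endogenized elements themselves, and removing them can only grow the
retained set.

Taxonomy (species, genus, family, molecule type, product, host) is copied
from the metadata row of the best-hit accession. A best hit missing from
the metadata yields "NA" fields and a logged warning; the element is never
silently dropped.

### Merging fragmented loci

Integrations shatter over time through substitutions, indels and
transposable-element insertions. Merging is two-pass, with gaps counted as
bases strictly between spans (overlap/abutment = 0) and thresholds tested
with ≤:

1. **Range junction** (`-rj`, default 100 nt): same-contig neighbors
   hitting the *same subject protein* chain-merge when their gap is within
   the threshold — one shattered insertion.
2. **Limit merge** (`-lm`, default 10,000 nt): neighbors sharing the taxon
   at the configured merge level (`family`, `genus`, or `none`) chain-merge
   across larger gaps — large-scale shattering such as a fragmented
   whole-genome bacterial integration.

Chaining keeps a running maximum end, making each pass equal to the
transitive closure of its pairwise relation (verified against an exhaustive
union-find oracle). Elements whose merge-level taxon is "NA" never merge
with each other: an unknown taxon is no evidence of common origin.
Intervening foreign-taxon elements do not block a within-taxon chain.
Merging is strand-agnostic (fragments of one insertion may decay onto
either apparent strand); the merged record takes its annotation from the
best-bitscore member, spans the gaps, and preserves the original pieces in
`fragment_coords`. The composition of the two passes is idempotent in the
pipeline's regime (taxonomy is a function of the subject accession and
`rj ≤ lm`); with `rj > lm` a second application could merge further,
because taxon-pass span growth can bring same-subject spans into junction
range.

### Flanks

Each final element yields a left and a right flank of up to `flank_length`
nt (default 10,000), clamped at contig edges with an explicit truncation
flag, reported in forward-strand orientation regardless of element strand.
Flanks of neighboring elements may overlap; each element's context is
independent.

## Synthetic fixtures and evaluation

Real benchmarks require multi-gigabyte assemblies and dated database
snapshots, so verification runs on generated data. The generator produces
i.i.d. host contigs at a chosen GC fraction, synthetic database proteins
(one synthetic family/genus each), host-like bait decoys, and plants
reverse-translated protein copies into the genome — intact, or shattered
into ordered fragments separated by host-like spacers — on either strand,
with point substitutions at a configurable per-base rate. Ground truth
records every fragment with its event id on the *modified* assembly.

Two generator choices matter for interpretation:

* Spacer lengths inside fragmented events are drawn from the configured
  range and then shifted to length ≡ 1 (mod 3). Consecutive fragments
  therefore occupy pairwise distinct reading frames. When two fragments
  share a frame, Smith–Waterman (and blastx, whose X-drop the intervening
  valley does not reach) legitimately bridges them into one alignment, and
  "one alignment per planted fragment" stops being a well-defined truth;
  distinct frames make the ground truth unambiguous by construction.
* Spacers are host-like (same GC), so merging is exercised on realistic
  gaps rather than sentinel bases.

The standard fixture plants 10 intact and 10 fragmented-into-3 insertions
from 8 proteins (150–250 aa) into 5 × 100 kb contigs, with at least 15 kb
between insertion sites so that separate events never fall within the
default merge distance of a same-family neighbor. At these sizes the full
pipeline completes in about two minutes on one core, which is also why the
recall-versus-decay property is checked on a smaller 2 × 30 kb fixture.

Evaluation follows a boundary-tolerance rule: a truth event is matched
when a prediction's start and end each lie within the tolerance (default
100 nt) of the event's overall span — or, for unmerged evaluation, of any
single fragment. Predictions are assigned to events greedily by nucleotide
overlap with deterministic tie-breaks; recall is over events, precision
over predictions.

What passing these fixtures does *not* show: robustness to indels and
frameshift decay inside elements (the mutation model is substitutions
only), to transposable-element landscapes, or to real host-gene homology
structure. The reciprocal-filter fixture approximates the latter by
planting exact copies of bait proteins while the database carries only
10%-diverged homologs of them.

## Numerical and degenerate-input choices

* Contigs exactly at the minimum length are kept (≥); records shorter than
  one codon translate to empty peptides with a warning; an empty result at
  any stage completes the run with empty, well-formed outputs rather than
  failing.
* Coordinates are 1-based inclusive on the forward strand internally; the
  reversed-coordinate tabular dialect exists only at the I/O boundary, and
  BED output converts to 0-based half-open at write time.
* Frame inference for 12-column hit tables (no frame column) uses
  `((raw_qstart − 1) mod 3) + 1` signed by strand; the true blast frame of
  a minus-strand hit also depends on contig length, which that format does
  not carry.
* Blank metadata cells become the explicit sentinel "NA" so unknowns form
  one visible group everywhere (annotation, merging, output).
* All randomness flows through seeded generators; fixture generation,
  search and merging are fully deterministic given a seed.

## Defaults

| Parameter | Default | Why |
| --- | --- | --- |
| `min_contig_length` | 10,000 nt | excludes likely symbiont-contaminant contigs and leaves room for flank analysis |
| matrix / gaps / word | BLOSUM45, 14/2, 3 | shallow scoring for highly diverged elements |
| `evalue_max` | 1e-5 | conventional reporting threshold for translated searches |
| `-rj` / `-lm` | 100 / 10,000 nt | distances that recover both a shattered single insertion and a fragmented whole-genome integration |
| merge level | family | coarsest taxon at which shared origin is plausible by default |
| `flank_length` | 10,000 nt | enough context for TE/host-gene annotation downstream |
| X-drop | 38 bits | blastx's gapped X-drop; controls HSP decomposition |
| ungapped trigger | raw 30 | tractability only; far below any reportable hit |
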