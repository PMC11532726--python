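# eescan

Detection and annotation of **endogenous viral and bacterial elements**
(EVEs/EBEs) in eukaryotic genome assemblies.

Viruses and bacteria that live closely with eukaryotes occasionally leave
fragments of their genomes integrated in the host germ line. These
endogenized elements are molecular fossils of past infections, raw material
for host innovation (antiviral piRNAs, even new sex chromosomes), and a
common source of false positives in metagenomic studies. `eescan` is a
library and command-line tool for finding them systematically, aimed at
researchers in paleovirology, symbiont genomics and comparative genomics
who would otherwise stitch this screen together from ad-hoc scripts.

## What it does

Six steps, each exposed as library functions and orchestrated by one CLI:

1. **Clean** — drop contigs/scaffolds below a minimum length (default
   10 kb); these are frequently unintegrated symbiont contamination.
2. **Search** — compare all six reading frames of each contig against a
   viral/bacterial protein database (blastx semantics). Detection runs in
   protein space with shallow scoring (BLOSUM45, word size 3) because
   endogenized elements are typically highly diverged. A builtin
   Smith–Waterman seed-and-extend backend needs no external binary;
   `blastx` and `diamond` can be used instead.
3. **Filter** — re-search every candidate against a host "bait" protein
   set and keep it only if its bitscore against the viral/bacterial
   database is *strictly higher*:

       retained  ⇔  no host hit  ∨  bits_forward > bits_host

   Bitscores, `bits = (λS − ln K)/ln 2`, are database-size independent,
   which makes the two searches comparable.
4. **Annotate** — transfer species/genus/family/molecule-type/product/host
   from the metadata row of the best-hit protein.
5. **Merge** — join fragmented loci: same-subject neighbors within
   `-rj` nt (default 100), then same-family/genus neighbors within
   `-lm` nt (default 10,000), each pass equal to the transitive closure of
   its pairwise relation.
6. **Flanks** — extract up to `--flank-length` nt (default 10 kb) on each
   side of every final element for downstream TE/host-gene analysis.

A deterministic synthetic-fixture generator (`eescan simulate`) plants
reverse-translated protein copies — intact or shattered into fragments —
into random host contigs with ground truth, so the whole pipeline is
verifiable without downloading any genome.

## Worked example

Generate a fixture (5 × 100 kb contigs, 10 intact + 10 fragmented-into-3
planted insertions from 8 synthetic proteins), run the pipeline, score it:

```
$ eescan simulate --out fx --seed 11
fixture with 20 planted events written to fx

$ eescan run --genome fx/genome.fna --db fx/proteins.faa \
             --metadata fx/metadata.tsv --baits fx/baits.faa \
             --out run -ml family -lm 10000 -rj 100
20 element(s) written to run

$ eescan evaluate --elements run/elements.tsv --truth fx/truth.tsv
truth_events    20
predicted       20
matched         20
recall          1.0000
precision       1.0000
mean_boundary_error_nt  0.00
tolerance_nt    100
```

All 20 planted events are recovered with exact boundaries; each
fragmented event is reported as a single merged locus (`n_fragments` = 3).
The element table carries coordinates, scores, taxonomy and fragment
structure:

```
$ head -3 run/elements.tsv | cut -f1-9,16
element_id           contig_id  start  end    strand  subject_accession  bit_score  e_value      percent_identity  n_fragments
contig1:2706-3194:-  contig1    2706   3194   -       SYNV001            331.0      3.65655e-91  100.000           1
contig1:35707-36414:- contig1   35707  36414  -       SYNV006            471.7      1.65714e-133 100.000           1
```

`run/` also contains `elements.bed`, `elements.fna`, `flanks.fna`,
`flanks.tsv`, the per-candidate `filter_decisions.tsv`, and a JSON
`manifest.json` with per-stage counts.

Real inputs follow the same shape: an assembly FASTA, a protein FASTA, a
metadata table (TSV/CSV with header columns `accession, species, genus,
family, molecule_type, protein_product, host`; blanks become `NA`), and a
host-proteome bait FASTA. `--filter-baits` additionally excludes baits
annotated "hypothetical"/"uncharacterized" — often unannotated endogenized
elements themselves — which can only increase the number of retained
elements.

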