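# tehits

Batch post-processing of transposable-element (TE) search hits.

Repeat searches with BLAST or RepeatMasker against a genome assembly
routinely return thousands to millions of matches per element family.
Turning that raw hit report into usable sequence — the matching genomic
intervals, optionally extended by flanking sequence, grouped by query or
by repeat family — is mechanical but tedious to do by hand. `tehits`
automates it for people curating repeat libraries, extending de novo
consensus sequences toward full-length elements, or analysing TE flanks.

## What it does

The pipeline runs in a fixed order:

1. **Parse** a hit report — BLAST tabular (12-column outfmt 6), a
   RepeatMasker `.out` file, or e-PCR tabular — into a uniform hit model:
   1-based inclusive coordinates on the database sequence, with
   orientation normalized so start ≤ end always and a minus-strand match
   (BLAST subject start > end; RepeatMasker `C`) recorded on the strand
   field.
2. **Merge** hits on the same sequence, query and strand whose gap
   (`next.start − prev.end − 1`) is at most the merge distance *d*
   (`-overlap d`); *d* = 0 still joins overlapping and directly adjacent
   hits. Merged loci span min(start)–max(end), sum mismatch/gap counts,
   and keep the best (max) bit score and best (min) E-value.
3. **Filter** on span length, mismatches, gap opens, bit score, E-value —
   applied *after* merging, so a minimum-length filter sees whole merged
   loci — and optionally keep only the *N* best hits per query by
   E-value.
4. **Split** the survivors per query sequence (`-splitquery`) or per
   repeat class/family (`-splittype`, RepeatMasker).
5. **Extract** each hit from the indexed FASTA database, widened by a
   flank buffer *b*: coordinates become `max(1, start − b)` to
   `min(L, end + b)` where *L* is the sequence length, so flanks extend
   only where data is available. Minus-strand extracts are
   reverse-complemented so output reads in element orientation. Output is
   wrapped multi-FASTA, one file per group when splitting, with the
   original query/consensus sequence prepended when `-qseq` is given; a
   `-print` table re-serializes the surviving hits in the input dialect.

A synthetic fixture generator (`tehits.generate_fixture`) builds random
genomes with planted, optionally diverged and fragmented repeat copies
plus matching hit files, and records the ground truth for every copy.

## Worked example

Generate a small fixture (3 × 10 kb genome, 20 planted copies of four TE
families at 5% divergence), then run the typical initial-search workflow:
keep hits at least 100 bp long with bit score ≥ 100, extract each with
200 bp of flank, split per query, and write the surviving hit table:

```sh
python -c "from tehits import generate_fixture; generate_fixture('.', n_insertions=20, divergence=0.05, seed=42)"
process-hits -input blast -v -buffer 200 -bit 100 -minlength 100 \
    -splitquery -print surviving.tsv -outdir out hits.blast.tsv genome.fa
```

which prints:

```
INFO parsed 20 hit(s) from 1 file(s)
INFO filter: 20 hits -> 15
INFO split (by_query): 15 hits -> 3 group(s)
INFO wrote 15 hit(s) to table surviving.tsv
INFO pipeline done in 0.00s: parsed 20, merged 20, filtered 15, best-N 15, groups 3, extracted 15
parsed 20, after merge 20, after filter 15, after best-N 15, groups 3, extracted 15 (0.00s)
```

Five of the twenty planted copies are 80 bp SINE fragments whose length
and bit score fall below the thresholds, so 15 hits survive, in 3 query
groups (`out/AluYx.fa`, `out/hAT1x.fa`, `out/L1MAx.fa`). Each FASTA
header carries the unique hit id and the *buffered* genomic interval,
e.g.

```
>L1MAx_seq2_5778_6977 seq2:5578-7177(-)
```

— a 1200 bp L1 copy on the minus strand of `seq2` at 5778–6977, written
as the 1600 bp extract 5578–7177 (200 bp flank each side),
reverse-complemented into element orientation. `surviving.tsv` holds the
same 15 hits as 12-column BLAST lines with minus-strand subject
coordinates re-inverted, so it re-parses to exactly the extracted set.

The consensus-extension workflow for RepeatMasker data is the same idea
with merging and family splitting:

```sh
process-hits -input repeatmasker -splittype -overlap 100 -buffer 1000 \
    -minlength 500 -qseq library.fa -outdir fam hits.rm.out genome.fa
```

Fragmented annotations within 100 bp of each other are first combined
into single loci, loci shorter than 500 bp are dropped, and each
per-family file begins with the matching consensus from `library.fa`,
ready for alignment and consensus extension.

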