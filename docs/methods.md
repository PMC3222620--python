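# Methods

## The hit model

Every supported report format describes a match between a query (a TE
consensus, probe or STS marker) and a database sequence. `tehits`
normalizes each line to one `Hit` with:

* `location`, `seq_start`, `seq_end` — 1-based inclusive coordinates on
  the database sequence, with `seq_start <= seq_end` enforced by
  construction. Orientation never lives in coordinate order: a BLAST
  line with subject start > end, or a RepeatMasker `C` strand glyph,
  sets `strand = minus` and stores ordered coordinates.
* `seq_length = seq_end − seq_start + 1`. The span is counted
  inclusively, matching BLAST alignment-length semantics on 1-based
  inclusive coordinates; an exclusive reading (`end − start`) would be
  off by one against every BLAST `length` column.
* `group_label` — the BLAST query id, the RepeatMasker
  `name#class/family` string, or the e-PCR marker id. Splitting by
  family takes the component after `#`.
* quality fields (`mismatches`, `gaps`, `bit_score`, `e_value`) that are
  `None` for dialects that do not report them. A filter threshold on an
  absent field is a configuration error at startup, never a silent pass.

Hit ids are `label_location_start_end`; a repeated identical locus within
one run gets a numeric `_k` suffix so ids stay unique across all input
files of a run (one shared id factory).

Internal coordinates stay 1-based inclusive throughout; the single
conversion to 0-based half-open happens inside the sequence store when
slicing.

### Dialect notes

* **BLAST tabular**: the standard 12 columns. Query coordinates are read
  but not retained — all downstream processing is in subject (genome)
  space. `#` comment lines are skipped.
* **RepeatMasker `.out`**: split on whitespace runs (the format is
  space-aligned); the 2–3 caption lines and blanks are skipped by token
  match. Only columns 5–11 are consumed.
* **e-PCR**: e-PCR tabular layouts vary between versions, so the package
  fixes a documented 5-column dialect — sequence id, marker id, strand,
  start, end — and orders coordinates on input. No mismatch/gap counts
  are assumed.

## Merging

Hits are bucketed by sequence, and by default also by group label and
strand; within a bucket sorted by start, a chain is extended while the
gap `next.start − run_end − 1` is at most the merge distance *d*, and
each maximal chain becomes one locus. Distance 0 therefore merges
overlapping and directly adjacent hits and nothing else. The output is
closed under the merge condition (verified against a brute-force
union-to-fixpoint oracle), idempotent, and never loses covered bases;
for *d* > 0 the merged locus also covers the bridged gaps, which is the
point of the operation — nearby fragments separated by small indels
become one extractable locus.

Merging across different element families or strands would corrupt both
the later split and the orientation of extracts, so same-label and
same-strand are required by default; `MergePolicy` flags relax either
for the permissive reading.

Merged-locus score aggregation is a design choice: mismatches and gap
counts are summed (the merged span contains all of them), bit score
takes the member maximum and E-value the member minimum (the locus is at
least as well supported as its best fragment). This keeps post-merge
filters meaningful.

## Filtering, best-N, splitting

Filters run after merging, so a minimum-length threshold applies to
merged spans. Best-N selection (BLAST only) keeps the N smallest
E-values per query; ties break by larger bit score, then input order,
and survivors keep their relative input order, making the operation
deterministic. Splitting partitions the surviving hits — every hit in
exactly one group, first-seen key order, input order within groups.

## Extraction

The database FASTA is indexed with pyfaidx; lookups are random-access
slices, so memory stays bounded by one extract rather than the
assembly. Duplicate sequence names are fatal at indexing time.

The flank buffer *b* widens a hit to `max(1, start − b)` …
`min(L, end + b)`: flanks extend only where sequence exists, and no
extracted coordinate can leave `[1, L]` for any buffer. Buffering is
applied after merging and per surviving hit; overlapping buffered
extracts are deliberately *not* re-merged — each surviving hit yields
exactly one output record, so record counts match the run report.

Minus-strand extracts are reverse-complemented by default so that output
sequences read in query/element orientation; this is what makes
prepending the query consensus (`-qseq`) and downstream alignment
meaningful. The `-genomic` flag preserves genomic orientation for
flank-analysis workflows instead.

FASTA output is 60-column wrapped with headers
`>{hit_id} {location}:{extract_start}-{extract_end}({strand})`; the
fixed format makes byte-exact round-trip tests possible. Query matching
for split files is by exact header token against the group key, with
RepeatMasker labels matched on the element-name component before `#`;
family groups prepend the consensi of their member elements.

### Hit tables

`-print` re-serializes the surviving hits in the input dialect. The
model intentionally does not retain every input column (BLAST %identity
and query coordinates; RepeatMasker SW score and divergences), so the
writers emit deterministic placeholders derived from the hit — %identity
recomputed from the mismatch count, query coordinates as `1..length`,
zeroed RepeatMasker score columns. Floats are written with `repr`, which
round-trips exactly in Python; consequently parse → write → parse is a
fixpoint on every retained field for unmerged hits. Merged BLAST hits
serialize with their aggregated scores behind a `#` comment noting the
merge count.

## Pipeline and CLI

Stages always run in the order parse → merge → filter → best-N → split →
table → extract → optional align hook, and the run report counts form a
non-increasing chain (`hits_parsed ≥ … ≥ hits_after_best_n`, with
`sequences_extracted` equal to the final count unless extraction is
disabled); the chain is asserted on every run. Verbose mode changes
logging only — outputs are byte-identical with and without `-v`.

The `-align` hook shells out to an external command template per output
FASTA (default template uses mafft). Alignment is out of the package's
scope: a missing aligner downgrades to a warning and all other outputs
are produced. Exit codes: 0 success, 2 usage error, 1 runtime failure.

## The fixture generator

`generate_fixture` is the package's test oracle. It emulates a repeat
search at desk scale: uniform-random background sequences (default
3 × 10 kb), a four-element library spanning the common size classes
(80 nt SINE fragment, 250 nt Alu-sized SINE, 600 nt DNA transposon,
1200 nt LINE fragment), and by default 20 planted copies drawn
round-robin, each on a uniform random sequence/position/strand. Copies
are mutated by substitution only, at a configurable divergence, so the
recorded per-copy mismatch count is exact; the generator writes matching
BLAST-tabular and RepeatMasker hit files describing the planted loci,
plus a truth table carrying each mutated copy in element orientation.
The library lengths straddle the usual thresholds (100 nt minimum
length, bit 100, 500 nt minimum length) so filtering behaviour is
observable on defaults. Emitted bit scores follow a fixed affine rule
(+1.2 per matching base, −2 per mismatch) with E-values derived from
them; they are internally consistent, not a BLAST statistics model.

`fragments_per_hit` reports each planted (contiguous) copy as several
sub-hits separated by gaps up to `fragment_max_gap`, emulating the
fragmented annotations real indels produce — the input for testing the
merge-then-extend workflow. Insertions keep 300 background bases apart
so no two planted loci can interact under the merge distances used.

What the generator does *not* emulate: indels within copies, nested
insertions, 5′-truncation length distributions, GC/composition bias, or
BLAST's actual scoring statistics. Green tests on these fixtures show
the bookkeeping (coordinates, strands, merging, filtering, extraction)
is exact; they say nothing about search sensitivity on real genomes,
which belongs to the upstream search tool anyway.

## Problem sizes and numerical choices

The default verification sizes — 200 random interval sets of ≤ 50
intervals for the merge oracle, 20 planted copies per fixture, 100
random hit files for the round-trip check — were chosen as the smallest
sets that exercise every branch (empty/one-element buckets, chain
extension past multiple members, clamping at both sequence ends, both
strands, ties in best-N) while keeping the whole suite near-instant.
All randomness is seeded; hypothesis properties run derandomized.

Degenerate inputs: empty hit files parse to empty runs with a warning;
an empty extraction writes an empty FASTA (warning, count 0); single-base
hits (`start == end`) are legal everywhere; buffer 0 and merge distance
0 are identities except for overlap/adjacency merging.

## Known limitations

* The e-PCR dialect is this package's fixed 5-column convention; other
  e-PCR layouts need a new parser entry.
* Pairwise/XML BLAST reports, RepeatMasker `.align` files and
  cross-match output are unsupported.
* No competitive overlap resolution between families (RepeatMasker-style
  masking precedence) — merging is within-family by default.
* The hit-table writers reconstruct non-retained columns from
  placeholders; they are faithful to the hit set, not byte-faithful to
  the original report.
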