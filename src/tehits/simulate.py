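"""Synthetic fixture generator: genomes with planted repeat copies.

Builds a random background assembly, plants mutated copies of a small
transposable-element library at recorded coordinates and strands, and
emits hit files in the BLAST-tabular and RepeatMasker dialects describing
the planted loci exactly.  The truth table (one row per planted copy,
including the mutated copy sequence in element orientation) is the oracle
for extraction tests: at divergence 0 every buffer-0 extract must equal
its library element byte for byte.

The mutation model is substitution-only, so the recorded mismatch count
per copy equals the mutations actually applied; indels are future work.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from Bio.Seq import reverse_complement

from .model import Strand, TEHitsError

_BASES = "ACGT"

#: Default element library: (name, class/family, length).  Lengths are
#: chosen to straddle the common quality thresholds — an 80 nt SINE
#: fragment fails a 100 nt minimum-length filter while the LINE passes a
#: 500 nt one — so filter behaviour is observable on the fixture.
DEFAULT_LIBRARY: tuple[tuple[str, str, int], ...] = (
    ("MIR3x", "SINE/MIR", 80),
    ("AluYx", "SINE/Alu", 250),
    ("hAT1x", "DNA/hAT", 600),
    ("L1MAx", "LINE/L1", 1200),
)


@dataclass
class PlantedCopy:
    """Ground truth for one planted repeat copy."""

    element: str
    family: str
    location: str
    start: int            # 1-based inclusive on the genome sequence
    end: int
    strand: Strand
    mismatches: int
    sequence: str         # mutated copy, element orientation

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Fixture:
    """Paths and ground truth for one generated fixture."""

    genome_fasta: Path
    library_fasta: Path
    truth_table: Path
    blast_hits: Path
    repeatmasker_hits: Path
    copies: list[PlantedCopy] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(n))


def _mutate(rng: random.Random, seq: str,
            divergence: float) -> tuple[str, list[int]]:
    """Substitute bases at rate ``divergence``; returns the mutated copy
    and the 0-based positions changed."""
    chars = list(seq)
    positions = []
    for i, c in enumerate(chars):
        if rng.random() < divergence:
            chars[i] = rng.choice([b for b in _BASES if b != c])
            positions.append(i)
    return "".join(chars), positions


def _read_library(path: str | Path) -> list[tuple[str, str, str]]:
    """(name, family, sequence) triples from a library FASTA; headers of
    the form ``name#class/family`` carry the family, otherwise Unknown."""
    from Bio import SeqIO
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "#" in rec.id:
            name, family = rec.id.split("#", 1)
        else:
            name, family = rec.id, "Unknown"
        out.append((name, family, str(rec.seq).upper()))
    if not out:
        raise TEHitsError(f"{path}: element library is empty")
    return out


def _blast_score(length: int, mismatches: int) -> tuple[float, float]:
    """Deterministic bit score and E-value for an emitted hit line:
    roughly +1.2 per matching base and -2 per mismatch, with the E-value
    derived from the bit score."""
    bit = max(0.0, round(1.2 * (length - mismatches) - 2.0 * mismatches, 1))
    e_value = 10.0 ** (-min(180.0, bit / 3.0))
    return bit, e_value


def _fragment_spans(rng: random.Random, start: int, end: int,
                    fragments: int, max_gap: int) -> list[tuple[int, int]]:
    """Split [start, end] into ``fragments`` sub-spans separated by gaps
    of 1..max_gap bases (each sub-span >= 30 nt); falls back to the whole
    span when it is too short to fragment."""
    length = end - start + 1
    min_frag = 30
    if fragments <= 1 or max_gap < 1 or length < fragments * min_frag + (
            fragments - 1):
        return [(start, end)]
    gaps = []
    for _ in range(fragments - 1):
        gaps.append(rng.randint(1, max_gap))
    while length - sum(gaps) < fragments * min_frag:
        gaps = [max(1, g // 2) for g in gaps]
        if all(g == 1 for g in gaps):
            break
    usable = length - sum(gaps)
    if usable < fragments * min_frag:
        return [(start, end)]
    # random composition of `usable` into `fragments` parts, each >= min_frag
    extra = usable - fragments * min_frag
    cuts = sorted(rng.randint(0, extra) for _ in range(fragments - 1))
    sizes = []
    prev = 0
    for c in list(cuts) + [extra]:
        sizes.append(min_frag + (c - prev))
        prev = c
    spans = []
    pos = start
    for i, size in enumerate(sizes):
        spans.append((pos, pos + size - 1))
        pos += size
        if i < len(gaps):
            pos += gaps[i]
    return spans


def generate_fixture(outdir: str | Path,
                     n_sequences: int = 3,
                     seq_length: int = 10_000,
                     n_insertions: int = 20,
                     element_library: Optional[str | Path] = None,
                     divergence: float = 0.0,
                     seed: int = 0,
                     fragments_per_hit: int = 1,
                     fragment_max_gap: int = 0,
                     min_spacing: int = 300) -> Fixture:
    """Generate a synthetic genome with planted repeat copies.

    Copies are drawn round-robin from the element library, assigned a
    uniform random sequence, position and strand, and mutated by random
    substitution at rate ``divergence``.  Insertions never overlap and
    keep ``min_spacing`` background bases between them so each planted
    locus is unambiguous.  ``fragments_per_hit`` > 1 reports each planted
    copy as several sub-hits separated by gaps of at most
    ``fragment_max_gap`` bases (the planted locus itself is contiguous),
    emulating the fragmented annotations that small indels produce.

    Everything is driven by one seeded generator: the same seed yields
    byte-identical files.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0, 1]")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)

    if element_library is not None:
        library = _read_library(element_library)
    else:
        library = [(name, family, _random_seq(rng, length))
                   for name, family, length in DEFAULT_LIBRARY]

    seq_names = [f"seq{i + 1}" for i in range(n_sequences)]
    backgrounds = {name: list(_random_seq(rng, seq_length))
                   for name in seq_names}
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in seq_names}

    copies: list[PlantedCopy] = []
    mutation_positions: list[list[int]] = []
    for i in range(n_insertions):
        name, family, consensus = library[i % len(library)]
        mutated, positions = _mutate(rng, consensus, divergence)
        length = len(mutated)
        placed = False
        for _ in range(2000):
            loc = rng.choice(seq_names)
            if seq_length < length:
                continue
            start = rng.randint(1, seq_length - length + 1)  # 1-based
            end = start + length - 1
            ok = all(end + min_spacing < s or start - min_spacing > e
                     for s, e in occupied[loc])
            if ok:
                occupied[loc].append((start, end))
                placed = True
                break
        if not placed:
            raise TEHitsError(
                f"cannot place insertion {i + 1}/{n_insertions} "
                f"(element {name}, {length} nt) without overlap: "
                f"n_sequences={n_sequences}, seq_length={seq_length}, "
                f"min_spacing={min_spacing}")
        strand = Strand.PLUS if rng.random() < 0.5 else Strand.MINUS
        genomic = mutated if strand is Strand.PLUS else reverse_complement(
            mutated)
        backgrounds[loc][start - 1:end] = list(genomic)
        copies.append(PlantedCopy(element=name, family=family, location=loc,
                                  start=start, end=end, strand=strand,
                                  mismatches=len(positions),
                                  sequence=mutated))
        mutation_positions.append(positions)

    sequences = {n: "".join(chars) for n, chars in backgrounds.items()}

    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        for name in seq_names:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for j in range(0, len(seq), 60):
                fh.write(seq[j:j + 60] + "\n")

    library_fasta = outdir / "library.fa"
    with open(library_fasta, "w") as fh:
        for name, _family, consensus in library:
            fh.write(f">{name}\n")
            for j in range(0, len(consensus), 60):
                fh.write(consensus[j:j + 60] + "\n")

    truth_table = outdir / "truth.tsv"
    with open(truth_table, "w") as fh:
        fh.write("location\tstart\tend\tstrand\telement\tfamily\t"
                 "mismatches\tcopy_sequence\n")
        for c in copies:
            fh.write(f"{c.location}\t{c.start}\t{c.end}\t{c.strand.value}\t"
                     f"{c.element}\t{c.family}\t{c.mismatches}\t"
                     f"{c.sequence}\n")

    blast_hits = outdir / "hits.blast.tsv"
    rm_hits = outdir / "hits.rm.out"
    with open(blast_hits, "w") as bfh, open(rm_hits, "w") as rfh:
        rfh.write("   SW  perc perc perc  query     position in query "
                  "  matching  repeat         position in repeat\n"
                  "score  div. del. ins.  sequence  begin end (left) "
                  "  repeat    class/family   begin end (left) ID\n\n")
        hit_index = 0
        for c, positions in zip(copies, mutation_positions):
            spans = _fragment_spans(rng, c.start, c.end, fragments_per_hit,
                                    fragment_max_gap)
            for span_start, span_end in spans:
                hit_index += 1
                frag_len = span_end - span_start + 1
                # mutations falling inside this sub-span (element coords)
                lo = span_start - c.start
                hi = span_end - c.start
                mm = sum(1 for p in positions if lo <= p <= hi)
                bit, e_value = _blast_score(frag_len, mm)
                pident = 100.0 * (frag_len - mm) / frag_len
                q_start, q_end = lo + 1, hi + 1
                if c.strand is Strand.PLUS:
                    s_start, s_end = span_start, span_end
                else:
                    s_start, s_end = span_end, span_start
                bfh.write("\t".join([
                    c.element, c.location, f"{pident:.2f}", str(frag_len),
                    str(mm), "0", str(q_start), str(q_end), str(s_start),
                    str(s_end), f"{e_value:.2g}", f"{bit:.1f}"]) + "\n")
                sw = int(10 * (frag_len - mm))
                div = 100.0 * mm / frag_len
                glyph = "+" if c.strand is Strand.PLUS else "C"
                left = len(sequences[c.location]) - span_end
                rfh.write(f"{sw:>6} {div:4.1f}  0.0  0.0  {c.location} "
                          f"{span_start} {span_end} ({left}) {glyph} "
                          f"{c.element} {c.family} {q_start} {q_end} (0) "
                          f"{hit_index}\n")

    return Fixture(genome_fasta=genome_fasta, library_fasta=library_fasta,
                   truth_table=truth_table, blast_hits=blast_hits,
                   repeatmasker_hits=rm_hits, copies=copies,
                   sequences=sequences)
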