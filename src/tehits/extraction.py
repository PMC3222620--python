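"""Sequence extraction: indexed FASTA access, flank buffering, and the
FASTA / hit-table writers.

The database FASTA is indexed (pyfaidx ``.fai``) so each hit is fetched by
random access rather than by holding the assembly in memory.  A hit's
coordinates may be widened by a symmetric flank *buffer*, clamped to the
sequence ends — flanks extend only "where data is available".  Minus-strand
hits are reverse-complemented on output by default so extracts read in
query/element orientation; a flag preserves genomic orientation for
flank-analysis workflows.
"""

from __future__ import annotations

import logging
import random
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, TextIO

from Bio.Seq import reverse_complement
from pyfaidx import Fasta, FastaIndexingError

from .model import (Dialect, ExtractionError, Hit, HitGroup, Strand,
                    TEHitsError)

logger = logging.getLogger(__name__)

FASTA_WRAP = 60


class SequenceStore:
    """Random-access view of a FASTA database.

    Retrieval is by (sequence name, start, end) with 1-based inclusive
    coordinates; memory stays bounded by one fetched slice, not the file.
    Duplicate sequence names in the database are a fatal error.
    """

    def __init__(self, fasta_path: str | Path):
        self.path = Path(fasta_path)
        if not self.path.is_file():
            raise TEHitsError(f"FASTA database not found: {self.path}")
        self._check_headers()
        try:
            self._fasta = Fasta(str(self.path), as_raw=True,
                                sequence_always_upper=False)
        except FastaIndexingError as err:
            raise TEHitsError(
                f"{self.path}: cannot index as FASTA ({err})") from None
        if len(self._fasta.keys()) == 0:
            raise TEHitsError(f"{self.path}: no sequences found")
        self.lengths: dict[str, int] = {
            name: len(rec) for name, rec in self._fasta.items()}

    def _check_headers(self) -> None:
        seen: set[str] = set()
        first_char: Optional[str] = None
        with open(self.path) as fh:
            for line in fh:
                if first_char is None and line.strip():
                    first_char = line.lstrip()[0]
                if line.startswith(">"):
                    name = line[1:].split()[0] if line[1:].split() else ""
                    if name in seen:
                        raise TEHitsError(
                            f"{self.path}: duplicate sequence name in "
                            f"header {line.strip()!r}")
                    seen.add(name)
        if first_char != ">":
            raise TEHitsError(f"{self.path}: not FASTA (no leading '>')")
        if not seen:
            raise TEHitsError(f"{self.path}: no FASTA headers found")

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def length(self, name: str) -> int:
        try:
            return self.lengths[name]
        except KeyError:
            raise ExtractionError(
                f"sequence {name!r} absent from {self.path}") from None

    def fetch(self, name: str, start: int, end: int) -> str:
        """Residues at 1-based inclusive [start, end] on ``name``."""
        length = self.length(name)
        if not (1 <= start <= end <= length):
            raise ExtractionError(
                f"coordinates {start}-{end} outside [1, {length}] "
                f"on {name!r}")
        return str(self._fasta[name][start - 1:end])

    def close(self) -> None:
        self._fasta.close()


def build_store(fasta_path: str | Path) -> SequenceStore:
    """Index a FASTA database for random access."""
    return SequenceStore(fasta_path)


@dataclass
class ExtractionRecord:
    """One extracted sequence: the hit, its buffered genomic coordinates,
    and the residues in output orientation."""

    hit: Hit
    extract_start: int
    extract_end: int
    sequence: str

    @property
    def header(self) -> str:
        return (f"{self.hit.hit_id} {self.hit.location}:"
                f"{self.extract_start}-{self.extract_end}"
                f"({self.hit.strand.value})")


def buffered_coordinates(hit: Hit, buffer: int,
                         store: SequenceStore) -> tuple[int, int]:
    """Widen a hit by ``buffer`` bases each side, clamped to [1, length]."""
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    length = store.length(hit.location)
    return (max(1, hit.seq_start - buffer),
            min(length, hit.seq_end + buffer))


def extract_hit(hit: Hit, buffer: int, store: SequenceStore,
                genomic_orientation: bool = False) -> ExtractionRecord:
    """Fetch a hit's (buffered) slice from the database.

    Minus-strand hits are reverse-complemented so the output reads in the
    query/element orientation, unless ``genomic_orientation`` is set.
    """
    start, end = buffered_coordinates(hit, buffer, store)
    seq = store.fetch(hit.location, start, end)
    if hit.strand is Strand.MINUS and not genomic_orientation:
        seq = reverse_complement(seq)
    return ExtractionRecord(hit=hit, extract_start=start, extract_end=end,
                            sequence=seq)


def extract_hits(hits: Sequence[Hit], buffer: int, store: SequenceStore,
                 genomic_orientation: bool = False
                 ) -> tuple[list[ExtractionRecord], list[str]]:
    """Extract many hits; unknown locations are skipped with a warning
    (the run continues) and reported in the second return value."""
    records, skipped = [], []
    for h in hits:
        try:
            records.append(extract_hit(h, buffer, store,
                                       genomic_orientation))
        except ExtractionError as err:
            logger.warning("skipping hit %s: %s", h.hit_id, err)
            skipped.append(f"{h.hit_id}: {err}")
    return records, skipped


def _write_wrapped(fh: TextIO, seq: str) -> None:
    for i in range(0, len(seq), FASTA_WRAP):
        fh.write(seq[i:i + FASTA_WRAP] + "\n")


def write_fasta(records: Sequence[ExtractionRecord],
                out: str | Path) -> int:
    """Write extraction records as 60-column-wrapped FASTA; returns the
    number of records written."""
    out = Path(out)
    with open(out, "w") as fh:
        for rec in records:
            fh.write(f">{rec.header}\n")
            _write_wrapped(fh, rec.sequence)
    if not records:
        logger.warning("%s: wrote an empty FASTA (no surviving hits)", out)
    return len(records)


def _sanitize(key: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", key)


def load_query_sequences(qseq_path: str | Path) -> dict[str, str]:
    """Query/consensus sequences keyed by the first header token."""
    from Bio import SeqIO
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(qseq_path), "fasta"):
        out[rec.id] = str(rec.seq)
    return out


def _query_candidates(group: HitGroup) -> list[str]:
    """Names under which a group's query sequence may appear in the
    query FASTA: the group key itself, its pre-'#' element component,
    and the distinct element names of member hits (for family groups)."""
    names: list[str] = [group.key]
    if "#" in group.key:
        names.append(group.key.split("#", 1)[0])
    for h in group.hits:
        elem = h.group_label.split("#", 1)[0]
        if elem not in names:
            names.append(elem)
    return names


def write_split_fasta(groups: Mapping[str, HitGroup], buffer: int,
                      store: SequenceStore, outdir: str | Path,
                      qseq: str | Path | None = None,
                      genomic_orientation: bool = False
                      ) -> dict[str, Path]:
    """One FASTA per group (sanitized key as filename).

    When a query FASTA is supplied, each group file begins with the
    matching query/consensus sequence(s); a group with no match in the
    query file triggers a warning, not an error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    queries = load_query_sequences(qseq) if qseq is not None else None
    written: dict[str, Path] = {}
    for key, group in groups.items():
        path = outdir / f"{_sanitize(key)}.fa"
        records, _ = extract_hits(group.hits, buffer, store,
                                  genomic_orientation)
        with open(path, "w") as fh:
            if queries is not None:
                matched = [n for n in _query_candidates(group)
                           if n in queries]
                if not matched:
                    logger.warning(
                        "group %r: no query sequence found in %s", key, qseq)
                for name in matched:
                    fh.write(f">{name}\n")
                    _write_wrapped(fh, queries[name])
            for rec in records:
                fh.write(f">{rec.header}\n")
                _write_wrapped(fh, rec.sequence)
        written[key] = path
    return written


def _format_blast_line(h: Hit) -> str:
    length = h.seq_length
    mism = h.mismatches if h.mismatches is not None else 0
    pident = 100.0 * (length - mism) / length if length else 100.0
    if h.strand is Strand.MINUS:
        s_start, s_end = h.seq_end, h.seq_start
    else:
        s_start, s_end = h.seq_start, h.seq_end
    cols = [h.group_label, h.location, f"{pident:.2f}", str(length),
            str(mism), str(h.gaps if h.gaps is not None else 0),
            "1", str(length), str(s_start), str(s_end),
            repr(h.e_value if h.e_value is not None else 0.0),
            repr(h.bit_score if h.bit_score is not None else 0.0)]
    return "\t".join(cols)


def _format_repeatmasker_line(h: Hit, index: int) -> str:
    if "#" in h.group_label:
        name, family = h.group_label.split("#", 1)
    else:
        name, family = h.group_label, "Unknown"
    glyph = "+" if h.strand is Strand.PLUS else "C"
    cols = ["0", "0.0", "0.0", "0.0", h.location, str(h.seq_start),
            str(h.seq_end), "(0)", glyph, name, family, "1",
            str(h.seq_length), "(0)", str(index)]
    return " ".join(cols)


def _format_epcr_line(h: Hit) -> str:
    if h.strand is Strand.MINUS:
        start, end = h.seq_end, h.seq_start
    else:
        start, end = h.seq_start, h.seq_end
    return "\t".join([h.location, h.group_label, h.strand.value,
                      str(start), str(end)])


def write_hit_table(hits: Sequence[Hit], dialect: Dialect,
                    out: str | Path) -> int:
    """Serialize surviving hits back into their input dialect's layout.

    Minus-strand BLAST hits have their subject coordinates re-inverted,
    RepeatMasker lines use the 'C' strand glyph, so re-parsing the file
    reproduces the hit set.  Columns the model does not retain (BLAST
    %identity and query coordinates; RepeatMasker scores and divergences)
    are emitted as deterministic placeholders derived from the hit.
    Merged BLAST hits carry aggregated scores and are annotated with a
    comment line noting the merge count.
    """
    dialect = Dialect(dialect)
    out = Path(out)
    with open(out, "w") as fh:
        if dialect is Dialect.REPEATMASKER:
            fh.write("   SW  perc perc perc  query     position in query "
                     "  matching  repeat         position in repeat\n"
                     "score  div. del. ins.  sequence  begin end (left) "
                     "  repeat    class/family   begin end (left) ID\n\n")
        for i, h in enumerate(hits, start=1):
            if dialect is Dialect.BLAST:
                if h.merged_count > 1:
                    fh.write(f"# {h.hit_id}: merged from "
                             f"{h.merged_count} raw hits\n")
                fh.write(_format_blast_line(h) + "\n")
            elif dialect is Dialect.REPEATMASKER:
                fh.write(_format_repeatmasker_line(h, i) + "\n")
            else:
                fh.write(_format_epcr_line(h) + "\n")
    return len(hits)


def sample_records(records: Sequence, k: int, seed: int) -> list:
    """Draw ``k`` records without replacement with a seeded generator;
    ``k`` >= size returns everything, in original order."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= len(records):
        return list(records)
    rng = random.Random(seed)
    chosen = sorted(rng.sample(range(len(records)), k))
    return [records[i] for i in chosen]
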