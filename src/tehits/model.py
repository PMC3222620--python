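"""Core data model for transposable-element hit processing.

A *hit* is one reported match between a query (a TE consensus, probe, or
STS marker) and a database sequence (typically a genome assembly), carried
as 1-based inclusive coordinates on the database sequence.  Orientation is
stored on the ``strand`` field; coordinates always satisfy ``start <= end``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterator, Optional, Sequence


class Strand(str, enum.Enum):
    """Orientation of a hit relative to the database sequence."""

    PLUS = "+"
    MINUS = "-"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Dialect(str, enum.Enum):
    """Supported hit-report formats."""

    BLAST = "blast"
    REPEATMASKER = "repeatmasker"
    EPCR = "epcr"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SplitMode(str, enum.Enum):
    NONE = "none"
    BY_QUERY = "by_query"
    BY_TYPE = "by_type"


class TEHitsError(Exception):
    """Base class for all package errors."""


class ParseError(TEHitsError):
    """A malformed line in a hit file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None,
                 path: str | Path | None = None):
        self.line_number = line_number
        self.path = str(path) if path is not None else None
        where = ""
        if path is not None:
            where += f"{path}:"
        if line_number is not None:
            where += f"{line_number}: "
        super().__init__(f"{where}{message}")


class ConfigurationError(TEHitsError):
    """An option that is incompatible with the input dialect or data."""


class ExtractionError(TEHitsError):
    """A hit that cannot be extracted (e.g. unknown database sequence)."""


@dataclass
class Hit:
    """One normalized match locus on a database sequence.

    Coordinates are 1-based inclusive on ``location``; ``seq_start`` is
    always <= ``seq_end`` and a minus-strand match is recorded via
    ``strand``, never by reversed coordinates.  ``group_label`` carries
    the BLAST query id, the RepeatMasker ``name#class/family`` string, or
    the e-PCR marker id.  Quality fields are ``None`` for dialects that
    do not report them.
    """

    hit_id: str
    location: str
    seq_start: int
    seq_end: int
    strand: Strand
    group_label: str
    mismatches: Optional[int] = None
    gaps: Optional[int] = None
    bit_score: Optional[float] = None
    e_value: Optional[float] = None
    merged_count: int = 1

    def __post_init__(self) -> None:
        if self.seq_start > self.seq_end:
            raise ValueError(
                f"hit {self.hit_id!r}: seq_start {self.seq_start} > "
                f"seq_end {self.seq_end} (orientation belongs in strand)")
        if self.seq_start < 1:
            raise ValueError(f"hit {self.hit_id!r}: coordinates are 1-based, "
                             f"got seq_start={self.seq_start}")
        if self.merged_count < 1:
            raise ValueError("merged_count must be >= 1")
        for name in ("mismatches", "gaps"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.e_value is not None and self.e_value < 0:
            raise ValueError(f"e_value must be >= 0, got {self.e_value}")

    @property
    def seq_length(self) -> int:
        """Inclusive span length, seq_end - seq_start + 1."""
        return self.seq_end - self.seq_start + 1

    def locus(self) -> tuple[str, int, int, Strand, str]:
        """The (location, start, end, strand, label) identity tuple."""
        return (self.location, self.seq_start, self.seq_end, self.strand,
                self.group_label)


@dataclass(frozen=True)
class FilterParams:
    """Quality-control thresholds; ``None`` means the filter is off.

    Length thresholds apply to the (possibly merged) inclusive span;
    score thresholds require the dialect to carry the field and raise
    :class:`ConfigurationError` otherwise.
    """

    min_length: Optional[int] = None
    max_length: Optional[int] = None
    max_gaps: Optional[int] = None
    max_mismatches: Optional[int] = None
    min_bit_score: Optional[float] = None
    max_e_value: Optional[float] = None
    best_n: Optional[int] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and v < 0:
                raise ValueError(f"{f.name} must be non-negative, got {v}")
        if (self.min_length is not None and self.max_length is not None
                and self.min_length > self.max_length):
            raise ValueError(
                f"min_length {self.min_length} > max_length {self.max_length}")
        if self.best_n is not None and self.best_n < 1:
            raise ValueError("best_n must be >= 1")

    def is_empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in fields(self))


@dataclass
class HitGroup:
    """A named, ordered collection of hits sharing one group key."""

    key: str
    hits: list[Hit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self) -> Iterator[Hit]:
        return iter(self.hits)


@dataclass
class MergePolicy:
    """How overlapping/adjacent hits are combined into one locus.

    ``distance`` is the maximum number of intervening bases still allowing
    a merge (0 merges overlapping and directly adjacent hits).  By default
    only hits on the same sequence, with the same group label and strand,
    are candidates; the flags relax that to the permissive reading.
    """

    distance: int = 0
    require_same_group: bool = True
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("merge distance must be >= 0")


@dataclass
class PipelineConfig:
    """Full run configuration for the processing pipeline."""

    input_dialect: Dialect = Dialect.BLAST
    merge_distance: Optional[int] = None
    buffer: int = 0
    split_mode: SplitMode = SplitMode.NONE
    filters: FilterParams = field(default_factory=FilterParams)
    emit_table: Optional[Path] = None
    no_extract: bool = False
    qseq_path: Optional[Path] = None
    align_hook: Optional[str] = None
    out_fasta: Optional[Path] = None
    out_dir: Optional[Path] = None
    skip_bad_lines: bool = False
    list_input: bool = False
    genomic_orientation: bool = False
    sample_k: Optional[int] = None
    verbose: bool = False
    log_path: Optional[Path] = None
    rng_seed: int = 0

    def validate(self) -> None:
        """Reject dialect-incompatible option combinations up front."""
        d = self.input_dialect
        f = self.filters
        if d is not Dialect.BLAST:
            for name, v in (("-bit", f.min_bit_score),
                            ("-evalue", f.max_e_value),
                            ("-best", f.best_n),
                            ("-gaps", f.max_gaps),
                            ("-mismatch", f.max_mismatches)):
                if v is not None:
                    raise ConfigurationError(
                        f"{name} requires BLAST input; the {d.value} dialect "
                        "does not report that field")
        if self.split_mode is SplitMode.BY_TYPE and d is not Dialect.REPEATMASKER:
            raise ConfigurationError(
                "-splittype requires RepeatMasker input (class/family labels)")
        if self.no_extract and self.emit_table is None:
            raise ConfigurationError("-noextract requires -print (otherwise "
                                     "the run would produce no output)")
        if self.buffer < 0:
            raise ConfigurationError("buffer must be >= 0")
        if self.merge_distance is not None and self.merge_distance < 0:
            raise ConfigurationError("merge distance must be >= 0")


class HitIdFactory:
    """Issues run-unique hit identifiers ``label_location_start_end``.

    Identical loci occurring more than once within a run receive a numeric
    ``_k`` suffix (k = 1, 2, ...) so every id stays unique.
    """

    def __init__(self) -> None:
        self._issued: dict[str, int] = {}

    def make(self, group_label: str, location: str, seq_start: int,
             seq_end: int) -> str:
        base = f"{group_label}_{location}_{seq_start}_{seq_end}"
        n = self._issued.get(base, 0)
        self._issued[base] = n + 1
        return base if n == 0 else f"{base}_{n}"


def make_hit_id(group_label: str, location: str, seq_start: int,
                seq_end: int, disambiguator: int = 0) -> str:
    """Stateless form of the id scheme: ``label_location_start_end``
    with ``_k`` appended when ``disambiguator`` k > 0."""
    base = f"{group_label}_{location}_{seq_start}_{seq_end}"
    return base if disambiguator == 0 else f"{base}_{disambiguator}"


def hits_sorted(hits: Sequence[Hit]) -> list[Hit]:
    """Hits ordered by (location, seq_start, seq_end)."""
    return sorted(hits, key=lambda h: (h.location, h.seq_start, h.seq_end))
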