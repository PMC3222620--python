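"""Parsers turning hit-report lines into :class:`~tehits.model.Hit` records.

Three dialects are supported:

* BLAST tabular (outfmt 6 style, 12 whitespace-separated columns);
  minus-strand subject matches arrive with subject start > end and are
  normalized to ordered coordinates plus ``strand = minus``.
* RepeatMasker ``.out`` annotation lines (space-aligned, 14-15 columns,
  strand ``+`` or ``C`` for complement).
* e-PCR tabular, here fixed as 5 columns: sequence id, marker id,
  strand (+/-), start, end.

Header, comment ('#') and blank lines are skipped silently at debug level.
All dialects are split on runs of whitespace.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

from .model import (Dialect, Hit, HitIdFactory, ParseError, Strand)

logger = logging.getLogger(__name__)

_RM_HEADER_TOKENS = {"SW", "score", "perc", "bit"}


def _int(value: str, what: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {value!r}") from None


def _float(value: str, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {value!r}") from None


def parse_blast_line(line: str, ids: HitIdFactory | None = None) -> Hit:
    """Parse one 12-column BLAST tabular line.

    Subject id becomes the hit location and query id the group label.
    When subject start > subject end the coordinates are swapped and the
    strand recorded as minus — tabular BLAST encodes orientation in
    coordinate order.
    """
    cols = line.split()
    if len(cols) != 12:
        raise ParseError(f"expected 12 BLAST tabular columns, got {len(cols)}")
    query, subject = cols[0], cols[1]
    mismatches = _int(cols[4], "mismatch count")
    gaps = _int(cols[5], "gap-open count")
    s_start = _int(cols[8], "subject start")
    s_end = _int(cols[9], "subject end")
    e_value = _float(cols[10], "E-value")
    bit_score = _float(cols[11], "bit score")
    if s_start > s_end:
        strand, lo, hi = Strand.MINUS, s_end, s_start
    else:
        strand, lo, hi = Strand.PLUS, s_start, s_end
    ids = ids or HitIdFactory()
    return Hit(hit_id=ids.make(query, subject, lo, hi), location=subject,
               seq_start=lo, seq_end=hi, strand=strand, group_label=query,
               mismatches=mismatches, gaps=gaps, bit_score=bit_score,
               e_value=e_value)


def is_repeatmasker_header(line: str) -> bool:
    """True for the 2-3 column-caption lines atop a ``.out`` file."""
    first = line.split()
    return bool(first) and first[0] in _RM_HEADER_TOKENS


def parse_repeatmasker_line(line: str, ids: HitIdFactory | None = None) -> Hit:
    """Parse one RepeatMasker ``.out`` annotation line.

    Column 5 is the database sequence, 6-7 the match coordinates, column 9
    the strand glyph ('+' or 'C' for complement); the group label is
    ``repeatName#class/family``.  Mismatch/gap counts, bit scores and
    E-values are not reported by this format and stay absent.
    """
    cols = line.split()
    if len(cols) < 14:
        raise ParseError(
            f"expected >= 14 RepeatMasker columns, got {len(cols)}")
    location = cols[4]
    start = _int(cols[5], "begin coordinate")
    end = _int(cols[6], "end coordinate")
    glyph = cols[8]
    if glyph == "+":
        strand = Strand.PLUS
    elif glyph in ("C", "c"):
        strand = Strand.MINUS
    else:
        raise ParseError(f"unrecognized strand glyph {glyph!r}")
    if start > end:
        start, end = end, start
    label = f"{cols[9]}#{cols[10]}"
    ids = ids or HitIdFactory()
    return Hit(hit_id=ids.make(cols[9], location, start, end),
               location=location, seq_start=start, seq_end=end,
               strand=strand, group_label=label)


def parse_epcr_line(line: str, ids: HitIdFactory | None = None) -> Hit:
    """Parse one 5-column e-PCR tabular line (seq, marker, strand, start, end)."""
    cols = line.split()
    if len(cols) != 5:
        raise ParseError(f"expected 5 e-PCR columns, got {len(cols)}")
    location, marker, glyph = cols[0], cols[1], cols[2]
    if glyph == "+":
        strand = Strand.PLUS
    elif glyph == "-":
        strand = Strand.MINUS
    else:
        raise ParseError(f"unrecognized strand glyph {glyph!r}")
    start = _int(cols[3], "start coordinate")
    end = _int(cols[4], "end coordinate")
    if start > end:
        start, end = end, start
    ids = ids or HitIdFactory()
    return Hit(hit_id=ids.make(marker, location, start, end),
               location=location, seq_start=start, seq_end=end,
               strand=strand, group_label=marker)


_LINE_PARSERS = {
    Dialect.BLAST: parse_blast_line,
    Dialect.REPEATMASKER: parse_repeatmasker_line,
    Dialect.EPCR: parse_epcr_line,
}


def _is_skippable(line: str, dialect: Dialect) -> bool:
    stripped = line.strip()
    if not stripped:
        return True
    if dialect is Dialect.BLAST and stripped.startswith("#"):
        return True
    if dialect is Dialect.REPEATMASKER and is_repeatmasker_header(stripped):
        return True
    return False


def parse_hit_file(path: str | Path, dialect: Dialect,
                   skip_bad: bool = False,
                   ids: HitIdFactory | None = None) -> list[Hit]:
    """Parse a whole hit file into hits in file order.

    Malformed lines abort the run with a line-accurate :class:`ParseError`
    unless ``skip_bad`` is set, in which case they are counted and logged.
    An empty file yields an empty list with a warning.
    """
    path = Path(path)
    dialect = Dialect(dialect)
    if not path.is_file():
        raise ParseError("hit file not found or unreadable", path=path)
    parse_line = _LINE_PARSERS[dialect]
    ids = ids if ids is not None else HitIdFactory()
    hits: list[Hit] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_skippable(line, dialect):
                logger.debug("%s:%d: skipped header/comment/blank line",
                             path, lineno)
                continue
            try:
                hits.append(parse_line(line, ids))
            except ParseError as err:
                if not skip_bad:
                    raise ParseError(str(err), line_number=lineno,
                                     path=path) from None
                skipped += 1
                logger.warning("%s:%d: skipped malformed line (%s)",
                               path, lineno, err)
    if not hits:
        logger.warning("%s: no hits parsed (empty or all-header file)", path)
    if skipped:
        logger.info("%s: skipped %d malformed line(s)", path, skipped)
    return hits


def parse_hit_files(paths: Sequence[str | Path], dialect: Dialect,
                    skip_bad: bool = False,
                    ids: HitIdFactory | None = None) -> list[Hit]:
    """Parse several files of one dialect, concatenated in list order.

    All paths are checked for readability before any parsing begins, so a
    bad path late in the list cannot waste a long run.  Hit-id uniqueness
    is maintained across files by a shared id factory.
    """
    paths = [Path(p) for p in paths]
    for p in paths:
        if not p.is_file():
            raise ParseError("hit file not found or unreadable", path=p)
    ids = ids if ids is not None else HitIdFactory()
    hits: list[Hit] = []
    for p in paths:
        hits.extend(parse_hit_file(p, dialect, skip_bad=skip_bad, ids=ids))
    return hits


def read_file_list(path: str | Path) -> list[Path]:
    """Read a plain-text file list: one hit-file path per line, relative
    paths resolved against the list file's directory."""
    path = Path(path)
    base = path.parent
    out = []
    for raw in path.read_text().splitlines():
        entry = raw.strip()
        if not entry or entry.startswith("#"):
            continue
        p = Path(entry)
        out.append(p if p.is_absolute() else base / p)
    return out
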