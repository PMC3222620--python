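"""Helper operations: FASTA sanitising and hit-file splitting.

These mirror the small pre-formatting scripts that usually accompany a
repeat-annotation workflow: stripping stray characters from downloaded
FASTA files, and cutting a huge hit report into per-query or fixed-size
chunks for parallel processing.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path

from .model import Dialect, TEHitsError
from .parsers import _is_skippable, _LINE_PARSERS, is_repeatmasker_header

logger = logging.getLogger(__name__)

# Full IUPAC nucleotide alphabet, both cases; '-' optionally kept.
_IUPAC = "ACGTURYSWKMBDHVN"


def clean_fasta(in_path: str | Path, out_path: str | Path,
                keep_gaps: bool = False) -> tuple[int, int]:
    """Strip non-nucleotide characters from FASTA sequence lines.

    Whitespace, digits and anything outside the IUPAC nucleotide set are
    removed (case preserved); headers pass through untouched.  Returns
    (number of sequences, characters removed).  A file with no '>'
    headers is rejected.
    """
    alphabet = _IUPAC + _IUPAC.lower() + ("-" if keep_gaps else "")
    keep = set(alphabet)
    n_seqs = 0
    removed = 0
    out_lines: list[str] = []
    for line in Path(in_path).read_text().splitlines():
        if line.startswith(">"):
            n_seqs += 1
            out_lines.append(line)
            continue
        cleaned = "".join(c for c in line if c in keep)
        removed += len(line) - len(cleaned)
        out_lines.append(cleaned)
    if n_seqs == 0:
        raise TEHitsError(f"{in_path}: no FASTA headers found")
    Path(out_path).write_text("\n".join(out_lines) + "\n")
    logger.info("clean_fasta: %d sequence(s), %d character(s) removed",
                n_seqs, removed)
    return n_seqs, removed


def _query_of(line: str, dialect: Dialect) -> str:
    cols = line.split()
    if dialect is Dialect.BLAST:
        return cols[0]
    if dialect is Dialect.REPEATMASKER:
        return cols[9]
    return cols[1]  # e-PCR marker id


def _sanitize(key: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", key)


def split_hitfile(in_path: str | Path, dialect: Dialect,
                  by: str, outdir: str | Path,
                  chunk_size: int | None = None) -> list[Path]:
    """Break a hit file into subfiles, by query/element or by line count.

    Data lines are copied verbatim (headers and comments dropped), so the
    concatenation of the subfiles reproduces the input's data lines
    exactly.  ``by='query'`` writes one subfile per query/element name;
    ``by='chunk_size'`` writes ceil(lines / chunk_size) subfiles in input
    order.
    """
    dialect = Dialect(dialect)
    in_path = Path(in_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_lines = [line for line in in_path.read_text().splitlines()
                  if not _is_skippable(line + "\n", dialect)]
    stem = in_path.stem
    written: list[Path] = []
    if by == "query":
        buckets: dict[str, list[str]] = {}
        for line in data_lines:
            buckets.setdefault(_query_of(line, dialect), []).append(line)
        for key, lines in buckets.items():
            p = outdir / f"{stem}.{_sanitize(key)}{in_path.suffix}"
            p.write_text("\n".join(lines) + "\n")
            written.append(p)
    elif by == "chunk_size":
        if not chunk_size or chunk_size < 1:
            raise TEHitsError("chunk_size must be a positive integer")
        n_chunks = math.ceil(len(data_lines) / chunk_size)
        for i in range(n_chunks):
            p = outdir / f"{stem}.part{i + 1}{in_path.suffix}"
            chunk = data_lines[i * chunk_size:(i + 1) * chunk_size]
            p.write_text("\n".join(chunk) + "\n")
            written.append(p)
    else:
        raise TEHitsError(f"unknown split mode {by!r} "
                          "(expected 'query' or 'chunk_size')")
    logger.info("split_hitfile: %d data line(s) -> %d subfile(s)",
                len(data_lines), len(written))
    return written
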