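"""Pipeline orchestration: parse → merge → filter → best-N → split →
table output → extraction, with stage-accurate run accounting."""

from __future__ import annotations

import logging
import shutil
import subprocess
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

from . import extraction, parsers, processing
from .model import (Dialect, FilterParams, Hit, HitGroup, MergePolicy,
                    PipelineConfig, SplitMode, TEHitsError)

logger = logging.getLogger(__name__)


@dataclass
class RunReport:
    """Stage-by-stage accounting of one pipeline run.

    The counts form a non-increasing chain: parsing can only lose hits to
    merging, merging to filtering, filtering to best-N selection; the
    number of extracted sequences equals the final hit count unless
    extraction is disabled.
    """

    hits_parsed: int = 0
    hits_after_merge: int = 0
    hits_after_filter: int = 0
    hits_after_best_n: int = 0
    groups: int = 0
    sequences_extracted: int = 0
    elapsed: float = 0.0
    warnings: list[str] = field(default_factory=list)
    outputs: list[Path] = field(default_factory=list)

    def check_chain(self) -> None:
        chain = (self.hits_parsed, self.hits_after_merge,
                 self.hits_after_filter, self.hits_after_best_n)
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise AssertionError(f"stage counts increased: {chain}")


def _align_outputs(config: PipelineConfig, fasta_paths: Sequence[Path],
                   report: RunReport) -> None:
    """Optional external-aligner hook: run the configured command template
    on each output FASTA.  A missing aligner is a warning, never an error."""
    template = config.align_hook
    if not template:
        return
    program = template.split()[0]
    if shutil.which(program) is None:
        msg = (f"aligner {program!r} not found on PATH; skipping alignment "
               "(all other outputs are complete)")
        logger.warning(msg)
        report.warnings.append(msg)
        return
    for path in fasta_paths:
        cmd = template.format(fasta=path)
        logger.info("aligning %s: %s", path, cmd)
        try:
            subprocess.run(cmd, shell=True, check=True,
                           capture_output=True)
        except subprocess.CalledProcessError as err:  # pragma: no cover
            msg = f"aligner failed on {path}: {err}"
            logger.warning(msg)
            report.warnings.append(msg)


def run_pipeline(config: PipelineConfig,
                 hit_input: Union[str, Path, Sequence[Union[str, Path]]],
                 fasta_db: Union[str, Path]) -> RunReport:
    """Execute the full processing pipeline.

    ``hit_input`` is one hit file, a list of hit files, or (with
    ``config.list_input``) a text file naming one hit file per line.
    Stages run in fixed order; merge, best-N, split, table output and
    extraction each run only when configured.
    """
    t0 = time.monotonic()
    config.validate()
    report = RunReport()

    if isinstance(hit_input, (str, Path)):
        if config.list_input:
            paths = parsers.read_file_list(hit_input)
        else:
            paths = [Path(hit_input)]
    else:
        paths = [Path(p) for p in hit_input]
    hits: list[Hit] = parsers.parse_hit_files(
        paths, config.input_dialect, skip_bad=config.skip_bad_lines)
    report.hits_parsed = len(hits)
    logger.info("parsed %d hit(s) from %d file(s)", len(hits), len(paths))

    if config.merge_distance is not None:
        hits = processing.merge_hits(
            hits, MergePolicy(distance=config.merge_distance))
    report.hits_after_merge = len(hits)

    if not config.filters.is_empty():
        non_best = FilterParams(
            min_length=config.filters.min_length,
            max_length=config.filters.max_length,
            max_gaps=config.filters.max_gaps,
            max_mismatches=config.filters.max_mismatches,
            min_bit_score=config.filters.min_bit_score,
            max_e_value=config.filters.max_e_value)
        if not non_best.is_empty():
            hits = processing.apply_filters(hits, non_best)
    report.hits_after_filter = len(hits)

    if config.filters.best_n is not None:
        hits = processing.select_best(hits, config.filters.best_n)
    report.hits_after_best_n = len(hits)

    groups: dict[str, HitGroup] | None = None
    if config.split_mode is not SplitMode.NONE:
        groups = processing.split_hits(hits, config.split_mode)
    report.groups = len(groups) if groups is not None else 0

    if config.emit_table is not None:
        n = extraction.write_hit_table(hits, config.input_dialect,
                                       config.emit_table)
        logger.info("wrote %d hit(s) to table %s", n, config.emit_table)
        report.outputs.append(Path(config.emit_table))

    fasta_outputs: list[Path] = []
    if not config.no_extract:
        store = extraction.build_store(fasta_db)
        try:
            if groups is not None:
                outdir = Path(config.out_dir
                              if config.out_dir is not None else ".")
                written = extraction.write_split_fasta(
                    groups, config.buffer, store, outdir,
                    qseq=config.qseq_path,
                    genomic_orientation=config.genomic_orientation)
                fasta_outputs.extend(written.values())
                n_extracted = sum(len(g) for g in groups.values())
            else:
                records, skipped = extraction.extract_hits(
                    hits, config.buffer, store,
                    genomic_orientation=config.genomic_orientation)
                report.warnings.extend(skipped)
                if config.sample_k is not None:
                    records = extraction.sample_records(
                        records, config.sample_k, config.rng_seed)
                out = Path(config.out_fasta
                           if config.out_fasta is not None else "hits.fa")
                extraction.write_fasta(records, out)
                fasta_outputs.append(out)
                n_extracted = len(records)
            report.sequences_extracted = n_extracted
        finally:
            store.close()
        report.outputs.extend(fasta_outputs)
        _align_outputs(config, fasta_outputs, report)

    report.elapsed = time.monotonic() - t0
    report.check_chain()
    logger.info(
        "pipeline done in %.2fs: parsed %d, merged %d, filtered %d, "
        "best-N %d, groups %d, extracted %d",
        report.elapsed, report.hits_parsed, report.hits_after_merge,
        report.hits_after_filter, report.hits_after_best_n, report.groups,
        report.sequences_extracted)
    return report
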