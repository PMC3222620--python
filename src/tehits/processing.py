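"""Hit processing: merge overlapping/adjacent loci, quality-filter,
select best-N by E-value, and split into groups.

The pipeline order is fixed — merge, then filter, then best-N, then split
— so that length filters apply to merged spans (this is what lets
fragmented LINE hits separated by small indels pass a minimum-length
filter as one locus).
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from typing import Optional, Sequence

from .model import (ConfigurationError, FilterParams, Hit, HitGroup,
                    HitIdFactory, MergePolicy, SplitMode, hits_sorted)

logger = logging.getLogger(__name__)


def _bucket_key(hit: Hit, policy: MergePolicy):
    key = [hit.location]
    if policy.require_same_group:
        key.append(hit.group_label)
    if policy.require_same_strand:
        key.append(hit.strand)
    return tuple(key)


def _combine(run: list[Hit], ids: HitIdFactory) -> Hit:
    """Collapse a gap-connected run of hits into one locus.

    Coordinates span min start to max end; merged counts sum; mismatch and
    gap counts sum over members that report them; bit score takes the max
    and E-value the min, so quality filters stay meaningful afterwards.
    """
    if len(run) == 1:
        return run[0]
    first = run[0]
    start = min(h.seq_start for h in run)
    end = max(h.seq_end for h in run)

    def agg(values, op):
        present = [v for v in values if v is not None]
        return op(present) if present else None

    return Hit(
        hit_id=ids.make(first.group_label, first.location, start, end),
        location=first.location, seq_start=start, seq_end=end,
        strand=first.strand, group_label=first.group_label,
        mismatches=agg((h.mismatches for h in run), sum),
        gaps=agg((h.gaps for h in run), sum),
        bit_score=agg((h.bit_score for h in run), max),
        e_value=agg((h.e_value for h in run), min),
        merged_count=sum(h.merged_count for h in run),
    )


def merge_hits(hits: Sequence[Hit], policy: MergePolicy,
               ids: HitIdFactory | None = None) -> list[Hit]:
    """Combine overlapping/adjacent hits within each merge bucket.

    Two hits merge when the number of intervening bases,
    ``next.seq_start - prev.seq_end - 1``, is at most ``policy.distance``;
    distance 0 still merges overlapping and directly adjacent hits.  The
    result is closed under the merge condition and sorted by
    (location, seq_start).
    """
    ids = ids if ids is not None else HitIdFactory()
    buckets: "OrderedDict[tuple, list[Hit]]" = OrderedDict()
    for h in hits:
        buckets.setdefault(_bucket_key(h, policy), []).append(h)
    merged: list[Hit] = []
    for bucket in buckets.values():
        bucket = sorted(bucket, key=lambda h: (h.seq_start, h.seq_end))
        run: list[Hit] = []
        run_end = None
        for h in bucket:
            if run and h.seq_start - run_end - 1 <= policy.distance:
                run.append(h)
                run_end = max(run_end, h.seq_end)
            else:
                if run:
                    merged.append(_combine(run, ids))
                run = [h]
                run_end = h.seq_end
        if run:
            merged.append(_combine(run, ids))
    out = hits_sorted(merged)
    logger.info("merge: %d hits -> %d loci (distance %d)",
                len(hits), len(out), policy.distance)
    return out


def _require_field(hits: Sequence[Hit], attr: str, flag: str) -> None:
    missing = next((h for h in hits if getattr(h, attr) is None), None)
    if missing is not None:
        raise ConfigurationError(
            f"{flag} threshold set but hit {missing.hit_id!r} carries no "
            f"{attr}; this filter requires a dialect reporting it")


def apply_filters(hits: Sequence[Hit], params: FilterParams) -> list[Hit]:
    """Keep hits passing every set threshold; order preserved.

    A score/mismatch/gap threshold combined with hits that lack the field
    is a configuration error, never a silent pass.  ``best_n`` is handled
    separately by :func:`select_best`.
    """
    if params.max_gaps is not None:
        _require_field(hits, "gaps", "max_gaps")
    if params.max_mismatches is not None:
        _require_field(hits, "mismatches", "max_mismatches")
    if params.min_bit_score is not None:
        _require_field(hits, "bit_score", "min_bit_score")
    if params.max_e_value is not None:
        _require_field(hits, "e_value", "max_e_value")

    def keep(h: Hit) -> bool:
        if params.min_length is not None and h.seq_length < params.min_length:
            return False
        if params.max_length is not None and h.seq_length > params.max_length:
            return False
        if params.max_gaps is not None and h.gaps > params.max_gaps:
            return False
        if (params.max_mismatches is not None
                and h.mismatches > params.max_mismatches):
            return False
        if (params.min_bit_score is not None
                and h.bit_score < params.min_bit_score):
            return False
        if params.max_e_value is not None and h.e_value > params.max_e_value:
            return False
        return True

    out = [h for h in hits if keep(h)]
    logger.info("filter: %d hits -> %d", len(hits), len(out))
    return out


def select_best(hits: Sequence[Hit], n: int) -> list[Hit]:
    """Keep the ``n`` best hits per group by smallest E-value.

    Ties are broken by larger bit score, then by input order, and the
    survivors keep their relative input order.  Requires a dialect that
    reports E-values.
    """
    if n < 1:
        raise ConfigurationError("best-N requires n >= 1")
    _require_field(hits, "e_value", "best_n")
    by_group: "OrderedDict[str, list[tuple[int, Hit]]]" = OrderedDict()
    for idx, h in enumerate(hits):
        by_group.setdefault(h.group_label, []).append((idx, h))
    winners: set[int] = set()
    for members in by_group.values():
        ranked = sorted(members, key=lambda ih: (
            ih[1].e_value,
            -(ih[1].bit_score if ih[1].bit_score is not None else 0.0),
            ih[0]))
        winners.update(idx for idx, _ in ranked[:n])
    out = [h for idx, h in enumerate(hits) if idx in winners]
    logger.info("best-N (n=%d): %d hits -> %d", n, len(hits), len(out))
    return out


def family_of(group_label: str) -> str:
    """The class/family component of a RepeatMasker ``name#class/family``
    label."""
    if "#" not in group_label:
        raise ConfigurationError(
            f"label {group_label!r} carries no class/family component; "
            "split-by-type requires RepeatMasker-style labels")
    return group_label.split("#", 1)[1]


def split_hits(hits: Sequence[Hit],
               mode: SplitMode) -> "OrderedDict[str, HitGroup]":
    """Partition hits into groups by query (group label) or by the
    RepeatMasker class/family component of the label.

    Every hit lands in exactly one group and within-group order follows
    input order; group keys appear in first-seen order.
    """
    mode = SplitMode(mode)
    if mode is SplitMode.NONE:
        raise ConfigurationError("split_hits called with split mode 'none'")
    groups: "OrderedDict[str, HitGroup]" = OrderedDict()
    for h in hits:
        key = h.group_label if mode is SplitMode.BY_QUERY else family_of(
            h.group_label)
        groups.setdefault(key, HitGroup(key=key)).hits.append(h)
    logger.info("split (%s): %d hits -> %d group(s)",
                mode.value, len(hits), len(groups))
    return groups
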