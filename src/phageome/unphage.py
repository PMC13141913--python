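"""Unphaging of a bacterial reference database.

Viral genomes aligned onto bacterial contigs at sufficient identity and
coverage mark prophage regions; those regions are excised and the residual
bacterial sequence is split into fragments.  Removing integrated prophages
from the bacterial reference prevents genuinely viral assembly contigs from
being misclassified as bacterial downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from phageome.io import AlignmentHit, ContigRecord, PipelineConfig

logger = logging.getLogger("phageome")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region on a contig, tagged with the viral query responsible."""

    contig_id: str
    start: int
    end: int
    source_query: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UnphageResult:
    """Output of unphaging: residual bacterial fragments plus excised prophages."""

    fragments: list[ContigRecord]
    prophages: list[ContigRecord]
    removed_count: int
    per_contig_log: dict[str, tuple[int, int]] = field(default_factory=dict)
    dropped_fragment_bp: dict[str, int] = field(default_factory=dict)


def filter_hits(
    hits: Iterable[AlignmentHit],
    min_identity: float = 70.0,
    min_coverage: float = 0.70,
) -> list[GenomicInterval]:
    """Turn alignment hits into excisable subject intervals.

    A hit qualifies iff its percent identity is >= ``min_identity`` and the
    aligned fraction of the *viral query* (aln_length / query_length) is
    >= ``min_coverage``; both thresholds are inclusive.  Subject coordinates
    are strand-normalised to 0-based half-open.
    """
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    intervals: list[GenomicInterval] = []
    for hit in hits:
        if hit.query_length is None:
            raise ValueError(f"query {hit.query_id!r} has no known length")
        if hit.pct_identity < min_identity:
            continue
        if hit.aln_length / hit.query_length < min_coverage:
            continue
        start, end = hit.subject_interval()
        intervals.append(GenomicInterval(hit.subject_id, start, end, hit.query_id))
    return intervals


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union overlapping or adjacent intervals per contig.

    Output is sorted by (contig, start), pairwise disjoint, and covers
    exactly the union of the input bases.  Source queries of merged
    intervals are joined with ``,``.
    """
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig_id, []).append(iv)
    merged: list[GenomicInterval] = []
    for contig_id in sorted(by_contig):
        ivs = sorted(by_contig[contig_id], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        cur_sources = [ivs[0].source_query]
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or adjacency
                cur_end = max(cur_end, iv.end)
                if iv.source_query not in cur_sources:
                    cur_sources.append(iv.source_query)
            else:
                merged.append(
                    GenomicInterval(contig_id, cur_start, cur_end, ",".join(cur_sources))
                )
                cur_start, cur_end = iv.start, iv.end
                cur_sources = [iv.source_query]
        merged.append(
            GenomicInterval(contig_id, cur_start, cur_end, ",".join(cur_sources))
        )
    return merged


def excise_and_split(
    contig: ContigRecord,
    merged: Sequence[GenomicInterval],
    min_fragment_len: int = 2000,
    prophage_suffix: str = "_prophage",
) -> tuple[list[ContigRecord], list[ContigRecord], int]:
    """Excise merged viral intervals from a contig and split the remainder.

    Returns ``(fragments, prophages, dropped_bp)``.  Prophages are the
    interval substrings (IDs ``<contig>_prophage<k>``); fragments are the
    complement substrings of length >= ``min_fragment_len``, numbered
    left-to-right as ``<contig>_frag<k>``.  Shorter complements are dropped
    and their base count returned.
    """
    ivs = sorted(merged, key=lambda iv: iv.start)
    if not ivs:
        return [contig], [], 0
    for a, b in zip(ivs, ivs[1:]):
        if b.start < a.end:
            raise ValueError(f"intervals overlap on {contig.contig_id}")
    if ivs and (ivs[0].start < 0 or ivs[-1].end > contig.length):
        raise ValueError(
            f"interval out of bounds on {contig.contig_id} (length {contig.length})"
        )
    prophages = [
        ContigRecord(f"{contig.contig_id}{prophage_suffix}{k}", contig.sequence[iv.start : iv.end])
        for k, iv in enumerate(ivs, start=1)
    ]
    fragments: list[ContigRecord] = []
    dropped_bp = 0
    frag_no = 0
    cursor = 0
    bounds = [(iv.start, iv.end) for iv in ivs] + [(contig.length, contig.length)]
    for start, end in bounds:
        piece = contig.sequence[cursor:start]
        if piece:
            if len(piece) >= min_fragment_len:
                frag_no += 1
                fragments.append(ContigRecord(f"{contig.contig_id}_frag{frag_no}", piece))
            else:
                dropped_bp += len(piece)
        cursor = end
    return fragments, prophages, dropped_bp


def unphage_database(
    contigs: Sequence[ContigRecord],
    hits: Iterable[AlignmentHit],
    config: PipelineConfig | None = None,
) -> UnphageResult:
    """Run the full unphaging cascade over a contig database.

    Hits are filtered at the configured identity/coverage thresholds, merged
    per contig, and excised; residual fragments shorter than
    ``min_fragment_len`` are dropped.  A contig with no qualifying hits
    passes through unchanged (no fragment suffix).  Base conservation holds
    exactly: fragment bp + prophage bp + dropped bp == original bp.
    """
    config = config or PipelineConfig()
    intervals = filter_hits(hits, config.min_identity, config.min_coverage)
    merged = merge_intervals(intervals)
    by_contig: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_contig.setdefault(iv.contig_id, []).append(iv)
    result = UnphageResult(fragments=[], prophages=[], removed_count=0)
    for contig in contigs:
        ivs = by_contig.get(contig.contig_id, [])
        if not ivs:
            result.fragments.append(contig)
            result.per_contig_log[contig.contig_id] = (0, 0)
            continue
        frags, pps, dropped = excise_and_split(contig, ivs, config.min_fragment_len)
        result.fragments.extend(frags)
        result.prophages.extend(pps)
        result.removed_count += len(pps)
        result.per_contig_log[contig.contig_id] = (
            len(ivs),
            sum(iv.length for iv in ivs),
        )
        if dropped:
            result.dropped_fragment_bp[contig.contig_id] = dropped
    logger.info(
        "unphage_database: %d contigs -> %d fragments, %d prophages removed",
        len(contigs),
        len(result.fragments),
        result.removed_count,
    )
    return result
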