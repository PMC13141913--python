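"""Greedy dereplication of phage contigs.

Near-identical contigs (by default >= 98% alignment identity over >= 85% of
the shorter sequence) are collapsed to a representative set.  Identity and
coverage come from a local pairwise alignment; phage contigs are unoriented,
so both strands are tried and the better-scoring one used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from phageome.io import ContigRecord

logger = logging.getLogger("phageome")


@dataclass
class DerepCluster:
    """One dereplication cluster: the longest member represents the rest."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    pairwise_stats: dict[str, tuple[float, float]] = field(default_factory=dict)


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _alignment_stats(aligner: PairwiseAligner, a: str, b: str) -> tuple[float, int, float]:
    """(identity, aligned bases of b, score) for the best local alignment of b on a."""
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return 0.0, 0, 0.0
    aln = alignments[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = counts.identities / columns if columns else 0.0
    aligned_b = sum(end - start for start, end in aln.aligned[1])
    return identity, aligned_b, alignments.score


def pairwise_identity_coverage(a: ContigRecord, b: ContigRecord) -> tuple[float, float]:
    """Alignment identity and coverage between two contigs.

    Identity is matched bases over aligned columns of the best local
    alignment (forward or reverse strand, whichever scores higher);
    coverage is the aligned span of the *shorter* sequence divided by its
    length, making the statistic symmetric in which contig is longer and
    equal to 1 for exact containment.
    """
    aligner = _make_aligner()
    # align the shorter onto the longer so coverage reads off the query span
    if a.length >= b.length:
        long_seq, short_seq = a.sequence, b.sequence
    else:
        long_seq, short_seq = b.sequence, a.sequence
    fwd = _alignment_stats(aligner, long_seq, short_seq)
    rev = _alignment_stats(aligner, long_seq, reverse_complement(short_seq))
    identity, aligned_short, _ = max(fwd, rev, key=lambda t: t[2])
    coverage = aligned_short / len(short_seq)
    return identity, coverage


def greedy_derep(
    contigs: Sequence[ContigRecord],
    min_identity: float = 0.98,
    min_coverage: float = 0.85,
) -> list[DerepCluster]:
    """Longest-first greedy clustering at the identity/coverage thresholds.

    Contigs are visited by decreasing length (ties broken by contig ID);
    each joins the first existing cluster whose representative it matches at
    >= both thresholds, otherwise it founds a new cluster.  Deterministic
    given the input set.
    """
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    ordered = sorted(contigs, key=lambda c: (-c.length, c.contig_id))
    by_id = {c.contig_id: c for c in ordered}
    if len(by_id) != len(ordered):
        raise ValueError("duplicate contig IDs in dereplication input")
    clusters: list[DerepCluster] = []
    for contig in ordered:
        placed = False
        for cluster in clusters:
            rep = by_id[cluster.representative_id]
            identity, coverage = pairwise_identity_coverage(rep, contig)
            if identity >= min_identity and coverage >= min_coverage:
                cluster.member_ids.append(contig.contig_id)
                cluster.pairwise_stats[contig.contig_id] = (identity, coverage)
                placed = True
                break
        if not placed:
            clusters.append(
                DerepCluster(
                    representative_id=contig.contig_id,
                    member_ids=[contig.contig_id],
                    pairwise_stats={contig.contig_id: (1.0, 1.0)},
                )
            )
    logger.info("greedy_derep: %d contigs -> %d clusters", len(ordered), len(clusters))
    return clusters
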