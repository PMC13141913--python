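"""Contig-level phage mining cascade.

Assembly contigs pass a length floor, predicted prophage regions are excised
into candidate phage contigs, contigs classified as bacterial are removed,
and the survivors are called phage / non-phage by a consensus over two
primary classifier scores (a threshold on the first plus a strict score-sum
agreement), with two auxiliary classifiers recorded as supporting evidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from phageome.io import ContigRecord, FormatError, PipelineConfig
from phageome.unphage import GenomicInterval, excise_and_split, merge_intervals

logger = logging.getLogger("phageome")

PROPHAGE_SUFFIX = "_pp"


@dataclass
class ClassifierScores:
    """Per-contig classifier outputs consumed by the consensus caller.

    ``phamer`` and ``metaphapred`` are the primary [0, 1] phage scores;
    ``deepvirfinder`` and ``virsorter2_viral`` are auxiliary;
    ``kraken_bacterial`` marks contigs assigned to bacteria by taxonomic
    read classification; ``prophage_regions`` are predicted integrated-phage
    coordinates (0-based half-open).
    """

    contig_id: str
    phamer: float | None = None
    metaphapred: float | None = None
    deepvirfinder: float | None = None
    virsorter2_viral: bool | None = None
    kraken_bacterial: bool = False
    prophage_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("phamer", "metaphapred", "deepvirfinder"):
            val = getattr(self, name)
            if val is not None and not 0.0 <= val <= 1.0:
                raise ValueError(f"{self.contig_id}: {name} score {val} outside [0, 1]")


@dataclass(frozen=True)
class MiningDecision:
    contig_id: str
    verdict: str  # "phage" | "non_phage"
    reason: str


def length_filter(
    contigs: Iterable[ContigRecord], min_len: int = 2000
) -> list[ContigRecord]:
    """Keep contigs of length >= ``min_len`` (inclusive boundary)."""
    contigs = list(contigs)
    kept = [c for c in contigs if c.length >= min_len]
    logger.info(
        "length_filter: kept %d contigs (dropped %d)", len(kept), len(contigs) - len(kept)
    )
    return kept


def extract_prophages(
    contigs: Sequence[ContigRecord],
    scores: Mapping[str, ClassifierScores],
) -> tuple[list[ContigRecord], list[ContigRecord], dict[str, list[str]]]:
    """Excise predicted prophage regions into candidate phage contigs.

    Overlapping region predictions (e.g. from two detectors) are merged
    before excision.  Returns ``(host_fragments, candidates, children)``
    where ``children`` maps a parent contig to its excised candidate IDs
    (``<parent>_pp<k>``).  Host-side fragments are retained (no length
    floor here) so the bacterial filter still sees them.
    """
    host_fragments: list[ContigRecord] = []
    candidates: list[ContigRecord] = []
    children: dict[str, list[str]] = {}
    for contig in contigs:
        sc = scores.get(contig.contig_id)
        regions = sc.prophage_regions if sc else []
        if not regions:
            host_fragments.append(contig)
            continue
        merged = merge_intervals(regions)
        frags, pps, _ = excise_and_split(
            contig, merged, min_fragment_len=1, prophage_suffix=PROPHAGE_SUFFIX
        )
        host_fragments.extend(frags)
        candidates.extend(pps)
        children[contig.contig_id] = [p.contig_id for p in pps]
    return host_fragments, candidates, children


def remove_bacterial(
    contigs: Sequence[ContigRecord],
    scores: Mapping[str, ClassifierScores],
) -> list[ContigRecord]:
    """Drop contigs flagged bacterial by taxonomic classification.

    Excised prophage candidates (IDs carrying the ``_pp`` suffix) survive
    even when their parent contig is bacterial: the parent is removed, the
    candidate is kept.  A contig with no score row is treated as
    non-bacterial.
    """
    kept: list[ContigRecord] = []
    for contig in contigs:
        parent_id = _parent_id(contig.contig_id)
        if parent_id is not None:  # excised candidate: always survives this step
            kept.append(contig)
            continue
        sc = scores.get(contig.contig_id)
        if sc is not None and sc.kraken_bacterial:
            continue
        kept.append(contig)
    logger.info("remove_bacterial: kept %d of %d contigs", len(kept), len(contigs))
    return kept


def _parent_id(contig_id: str) -> str | None:
    """Parent contig ID if this is an excised prophage candidate, else None."""
    stem, sep, tail = contig_id.rpartition(PROPHAGE_SUFFIX)
    if sep and tail.isdigit():
        return stem
    return None


def consensus_classify(
    scores: ClassifierScores,
    phamer_threshold: float = 0.9,
    agreement_min: float = 1.0,
    dvf_rescue: bool = False,
) -> MiningDecision:
    """Consensus phage call from the two primary classifier scores.

    Verdict is ``phage`` iff the primary score meets its threshold
    (``phamer >= phamer_threshold``) *and* the score-sum agreement is strict
    (``phamer + metaphapred > agreement_min``).  A missing secondary score
    counts as 0 (it cannot contribute agreement); a missing primary score is
    an error.  Auxiliary classifiers are recorded in the reason trace; with
    ``dvf_rescue`` they may additionally rescue a rejected contig when both
    agree it is viral (off by default).
    """
    if scores.phamer is None:
        raise ValueError(
            f"{scores.contig_id}: primary classifier score missing, cannot classify"
        )
    phamer = scores.phamer
    metaphapred = scores.metaphapred if scores.metaphapred is not None else 0.0
    total = phamer + metaphapred
    is_phage = phamer >= phamer_threshold and total > agreement_min
    aux = (
        f"dvf={scores.deepvirfinder if scores.deepvirfinder is not None else 'NA'},"
        f"vs2={scores.virsorter2_viral if scores.virsorter2_viral is not None else 'NA'}"
    )
    if is_phage:
        reason = (
            f"phamer {phamer:.3f} >= {phamer_threshold} and sum {total:.3f} > "
            f"{agreement_min} [{aux}]"
        )
    else:
        reason = (
            f"phamer {phamer:.3f} vs {phamer_threshold}, sum {total:.3f} vs "
            f"{agreement_min} [{aux}]"
        )
        if (
            dvf_rescue
            and scores.deepvirfinder is not None
            and scores.deepvirfinder >= phamer_threshold
            and scores.virsorter2_viral
        ):
            is_phage = True
            reason += " rescued by auxiliary classifiers"
    return MiningDecision(
        scores.contig_id, "phage" if is_phage else "non_phage", reason
    )


def mine_phages(
    contigs: Sequence[ContigRecord],
    scores: Mapping[str, ClassifierScores],
    config: PipelineConfig | None = None,
) -> tuple[list[ContigRecord], list[MiningDecision]]:
    """Full mining cascade: length filter, prophage extraction, bacterial
    removal, consensus classification.

    Excised prophage candidates inherit their parent's classifier scores
    when they carry none of their own.  Returns the phage contig set and
    per-contig decisions for every contig that reached the classifier.
    """
    config = config or PipelineConfig()
    sized = length_filter(contigs, config.min_contig_len)
    hosts, candidates, _ = extract_prophages(sized, scores)
    survivors = remove_bacterial(hosts + candidates, scores)
    survivors = length_filter(survivors, config.min_contig_len)
    phages: list[ContigRecord] = []
    decisions: list[MiningDecision] = []
    for contig in survivors:
        sc = scores.get(contig.contig_id)
        if sc is None:
            parent = _parent_id(contig.contig_id) or _frag_parent(contig.contig_id)
            if parent is not None and parent in scores:
                parent_sc = scores[parent]
                sc = ClassifierScores(
                    contig.contig_id,
                    phamer=parent_sc.phamer,
                    metaphapred=parent_sc.metaphapred,
                    deepvirfinder=parent_sc.deepvirfinder,
                    virsorter2_viral=parent_sc.virsorter2_viral,
                )
        if sc is None:
            raise ValueError(f"{contig.contig_id}: no classifier scores available")
        decision = consensus_classify(
            sc, config.phamer_threshold, config.agreement_min, config.dvf_rescue
        )
        decisions.append(decision)
        if decision.verdict == "phage":
            phages.append(contig)
    logger.info("mine_phages: %d phage contigs of %d classified", len(phages), len(decisions))
    return phages, decisions


def _frag_parent(contig_id: str) -> str | None:
    stem, sep, tail = contig_id.rpartition("_frag")
    if sep and tail.isdigit():
        return stem
    return None


# ---------------------------------------------------------------------------
# Score-table I/O (TSV dialect)


def read_scores_table(path: str | Path) -> dict[str, ClassifierScores]:
    """Read the per-contig classifier score TSV.

    Columns: contig_id, phamer, metaphapred, deepvirfinder, virsorter2_viral,
    kraken_bacterial, prophage_regions (semicolon-separated ``start-end``
    pairs, 0-based half-open).  Empty cells mean "missing".
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"contig_id", "phamer", "metaphapred"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {sorted(missing)}")
    out: dict[str, ClassifierScores] = {}
    for row in df.itertuples():
        cid = row.contig_id
        regions = []
        raw_regions = getattr(row, "prophage_regions", "")
        if raw_regions:
            for pair in raw_regions.split(";"):
                start, _, end = pair.partition("-")
                regions.append(GenomicInterval(cid, int(start), int(end), "predicted"))
        out[cid] = ClassifierScores(
            contig_id=cid,
            phamer=float(row.phamer) if row.phamer != "" else None,
            metaphapred=float(row.metaphapred) if row.metaphapred != "" else None,
            deepvirfinder=(
                float(row.deepvirfinder)
                if getattr(row, "deepvirfinder", "") != ""
                else None
            ),
            virsorter2_viral=(
                getattr(row, "virsorter2_viral", "").lower() in ("true", "1", "yes")
                if getattr(row, "virsorter2_viral", "") != ""
                else None
            ),
            kraken_bacterial=getattr(row, "kraken_bacterial", "").lower()
            in ("true", "1", "yes"),
            prophage_regions=regions,
        )
    return out


def write_decisions(decisions: Sequence[MiningDecision], path: str | Path) -> None:
    pd.DataFrame(
        {
            "contig_id": [d.contig_id for d in decisions],
            "verdict": [d.verdict for d in decisions],
            "reason": [d.reason for d in decisions],
        }
    ).to_csv(path, sep="\t", index=False)
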