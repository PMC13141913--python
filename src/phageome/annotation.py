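"""Post-processing of taxonomy, lifestyle and host predictions.

Raw classifier calls are filtered by rejection score and whitelist, taxonomy
is arbitrated between two predictors, propagated across genome bins (with
conflicting bins voided), and host predictions from an alignment-based and a
read-classification source are merged with a fixed precedence.  Filtered
calls are nulled, never deleted: every contig keeps a traceable row so that
downstream quantification still counts it (as "unclassified").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger("phageome")

LIFESTYLES = ("temperate", "virulent")


@dataclass(frozen=True)
class TaxonomyCall:
    contig_id: str
    family: str | None
    score: float | None
    source: str = "phagcn_like"  # "phagcn_like" | "virotaxo_like"

    def __post_init__(self) -> None:
        if self.family is not None and self.score is None:
            raise ValueError(f"{self.contig_id}: taxonomy call without a score")


@dataclass(frozen=True)
class LifestyleCall:
    contig_id: str
    lifestyle: str | None
    score: float | None

    def __post_init__(self) -> None:
        if self.lifestyle is not None:
            if self.score is None:
                raise ValueError(f"{self.contig_id}: lifestyle call without a score")
            if self.lifestyle not in LIFESTYLES:
                raise ValueError(
                    f"{self.contig_id}: lifestyle {self.lifestyle!r} not in {LIFESTYLES}"
                )


@dataclass(frozen=True)
class HostCall:
    contig_id: str
    host_genus: str | None
    host_species: str | None = None
    confidence: float = 0.0
    shared_proteins: int = 0
    source: str = "iphop_like"  # "iphop_like" | "kraken_like"
    conflict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 100.0:
            raise ValueError(f"{self.contig_id}: confidence outside [0, 100]")
        if self.shared_proteins < 0:
            raise ValueError(f"{self.contig_id}: negative shared protein count")


@dataclass
class PhageBin:
    """A cluster of contigs presumed to form one viral genome."""

    bin_id: str
    member_ids: list[str] = field(default_factory=list)
    family: str | None = None
    discarded: bool = False


def filter_taxonomy(
    calls: Iterable[TaxonomyCall],
    reject_below: float = 0.7,
    allowed_families: set[str] | frozenset[str] = frozenset(),
) -> list[TaxonomyCall]:
    """Null family calls below the rejection score or outside the whitelist.

    The rejection threshold is inclusive (score >= threshold passes).  Rows
    are retained with ``family=None`` for traceability.
    """
    if not allowed_families:
        raise ValueError("allowed_families must be non-empty")
    out: list[TaxonomyCall] = []
    for call in calls:
        if call.family is None:
            out.append(call)
        elif call.score < reject_below or call.family not in allowed_families:
            out.append(replace(call, family=None, score=None))
        else:
            out.append(call)
    return out


def merge_taxonomy_sources(
    primary: Iterable[TaxonomyCall],
    secondary: Iterable[TaxonomyCall],
    policy: str = "agreement",
) -> list[TaxonomyCall]:
    """Arbitrate family calls from two taxonomy predictors.

    ``agreement`` (default): where both predictors assign a family and they
    disagree, the call is nulled; a single-source family stands.
    ``primary_priority``: the primary predictor wins on conflict.
    """
    if policy not in ("agreement", "primary_priority"):
        raise ValueError(f"unknown merge policy {policy!r}")
    by_id = {c.contig_id: c for c in primary}
    sec_by_id = {c.contig_id: c for c in secondary}
    out: list[TaxonomyCall] = []
    for cid in sorted(set(by_id) | set(sec_by_id)):
        p, s = by_id.get(cid), sec_by_id.get(cid)
        p_fam = p.family if p else None
        s_fam = s.family if s else None
        if p_fam is not None and s_fam is not None and p_fam != s_fam:
            if policy == "primary_priority":
                out.append(p)
            else:
                out.append(TaxonomyCall(cid, None, None, source="phagcn_like"))
        elif p_fam is not None:
            out.append(p)
        elif s_fam is not None:
            out.append(s)
        else:
            out.append(p or s or TaxonomyCall(cid, None, None))
    return out


def propagate_bin_taxonomy(
    bins: Sequence[PhageBin],
    calls: Iterable[TaxonomyCall],
) -> tuple[list[PhageBin], dict[str, str | None], float]:
    """Propagate a bin's single family to all members; void conflicted bins.

    For each bin the distinct non-null member families are collected:
    exactly one family -> assigned to every member; two or more -> the bin is
    discarded (member families nulled, bin flagged); none -> the bin stays
    unannotated.  Returns the updated bins, a per-contig family table
    (covering bin members and unbinned contigs), and the fraction of bins
    discarded.
    """
    family_of: dict[str, str | None] = {c.contig_id: c.family for c in calls}
    seen: dict[str, str] = {}
    for b in bins:
        for cid in b.member_ids:
            if cid in seen:
                raise ValueError(f"contig {cid} in bins {seen[cid]} and {b.bin_id}")
            seen[cid] = b.bin_id
    out_bins: list[PhageBin] = []
    n_discarded = 0
    result = dict(family_of)
    for b in bins:
        families = sorted(
            {family_of[cid] for cid in b.member_ids if family_of.get(cid) is not None}
        )
        new_bin = PhageBin(b.bin_id, list(b.member_ids))
        if len(families) == 1:
            new_bin.family = families[0]
            for cid in b.member_ids:
                result[cid] = families[0]
        elif len(families) > 1:
            new_bin.discarded = True
            n_discarded += 1
            for cid in b.member_ids:
                result[cid] = None
        out_bins.append(new_bin)
    discarded_fraction = n_discarded / len(bins) if bins else 0.0
    logger.info(
        "propagate_bin_taxonomy: %d/%d bins discarded for conflicting taxonomy",
        n_discarded,
        len(bins),
    )
    return out_bins, result, discarded_fraction


def filter_lifestyle(
    calls: Iterable[LifestyleCall], reject_below: float = 0.7
) -> list[LifestyleCall]:
    """Null lifestyle calls below the (inclusive) rejection score."""
    out: list[LifestyleCall] = []
    for call in calls:
        if call.lifestyle is not None and call.score < reject_below:
            out.append(replace(call, lifestyle=None, score=None))
        else:
            out.append(call)
    return out


def filter_hosts(
    calls: Iterable[HostCall],
    min_confidence: float = 95.0,
    require_shared_proteins: bool = True,
) -> list[HostCall]:
    """Keep only high-quality alignment-based host predictions.

    An ``iphop_like`` call survives iff confidence >= ``min_confidence`` and
    (when required) at least one shared protein was reported.  Calls from
    read classification (``kraken_like``) pass untouched.
    """
    out: list[HostCall] = []
    for call in calls:
        if call.source != "iphop_like":
            out.append(call)
            continue
        if call.confidence < min_confidence:
            continue
        if require_shared_proteins and call.shared_proteins <= 0:
            continue
        out.append(call)
    return out


def merge_host_sources(
    iphop_calls: Iterable[HostCall], kraken_calls: Iterable[HostCall]
) -> dict[str, HostCall]:
    """Merge filtered host calls: alignment-based predictions take precedence.

    Read-classification calls fill contigs with no surviving alignment-based
    call; when both exist and disagree on the genus, the alignment-based
    call wins and the conflict is flagged on the returned record.
    """
    merged: dict[str, HostCall] = {}
    kraken_by_id = {c.contig_id: c for c in kraken_calls}
    for call in iphop_calls:
        other = kraken_by_id.get(call.contig_id)
        conflict = (
            other is not None
            and other.host_genus is not None
            and call.host_genus is not None
            and other.host_genus != call.host_genus
        )
        merged[call.contig_id] = replace(call, conflict=conflict)
        if conflict:
            logger.info(
                "merge_host_sources: %s genus conflict (%s vs %s), keeping %s",
                call.contig_id,
                call.host_genus,
                other.host_genus,
                call.host_genus,
            )
    for cid, call in kraken_by_id.items():
        if cid not in merged:
            merged[cid] = call
    return merged


def annotation_rates(
    n_total: int,
    n_family: int | None = None,
    n_lifestyle: int | None = None,
    n_host_genus: int | None = None,
    n_host_species: int | None = None,
) -> dict[str, float]:
    """Percent of contigs annotated at each level, from integer counts.

    Any count may instead be derived from call collections with
    :func:`count_annotated`.  Percentages are on the 0-100 scale.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    rates: dict[str, float] = {}
    for name, n in (
        ("family", n_family),
        ("lifestyle", n_lifestyle),
        ("host_genus", n_host_genus),
        ("host_species", n_host_species),
    ):
        if n is None:
            continue
        if not 0 <= n <= n_total:
            raise ValueError(f"count {name}={n} outside [0, {n_total}]")
        rates[name] = 100.0 * n / n_total
    return rates


# ---------------------------------------------------------------------------
# TSV dialects


def read_taxonomy_tsv(path, source: str = "phagcn_like") -> list[TaxonomyCall]:
    """Columns: contig_id, family, score (empty family = no call)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        TaxonomyCall(
            row.contig_id,
            row.family or None,
            float(row.score) if row.family else None,
            source=source,
        )
        for row in df.itertuples()
    ]


def read_lifestyle_tsv(path) -> list[LifestyleCall]:
    """Columns: contig_id, lifestyle, score."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        LifestyleCall(
            row.contig_id,
            row.lifestyle or None,
            float(row.score) if row.lifestyle else None,
        )
        for row in df.itertuples()
    ]


def read_hosts_tsv(path, source: str) -> list[HostCall]:
    """Columns: contig_id, host_genus, host_species, confidence, shared_proteins."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        HostCall(
            row.contig_id,
            row.host_genus or None,
            getattr(row, "host_species", "") or None,
            float(getattr(row, "confidence", "") or 0.0),
            int(getattr(row, "shared_proteins", "") or 0),
            source=source,
        )
        for row in df.itertuples()
    ]


def read_bins_tsv(path) -> list[PhageBin]:
    """Columns: bin_id, member_id (one row per membership)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    bins: dict[str, PhageBin] = {}
    for row in df.itertuples():
        bins.setdefault(row.bin_id, PhageBin(row.bin_id)).member_ids.append(
            row.member_id
        )
    return list(bins.values())


def read_whitelist(path) -> frozenset[str]:
    """Flat text list of allowed family names, one per line."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def count_annotated(
    taxonomy: Iterable[TaxonomyCall] = (),
    lifestyle: Iterable[LifestyleCall] = (),
    hosts: Iterable[HostCall] = (),
) -> dict[str, int]:
    """Integer counts of non-null annotations per level."""
    return {
        "family": sum(1 for c in taxonomy if c.family is not None),
        "lifestyle": sum(1 for c in lifestyle if c.lifestyle is not None),
        "host_genus": sum(1 for c in hosts if c.host_genus is not None),
        "host_species": sum(1 for c in hosts if c.host_species is not None),
    }
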