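"""Readers and writers for the external formats the pipeline touches.

All downstream modules consume only the domain types built here:
:class:`ContigRecord` (sequences), :class:`AlignmentHit` (BLAST tabular
rows), :class:`DepthSummary` (per-contig mapping depth/coverage) and
:class:`SampleMeta` (the fixed/random-effect design of the cohort).

Coordinate convention: everything internal is 0-based half-open; BLAST
tabular coordinates (1-based inclusive, possibly reversed on the minus
strand) are normalised on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("phageome")

_VALID_AGES = (6, 12)
_VALID_DELIVERY = ("cesarean", "vaginal")
_VALID_TREATMENT = ("control", "PE")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ContigRecord:
    """A nucleotide sequence with an identifier; the unit flowing through mining."""

    contig_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"contig {self.contig_id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentHit:
    """One row of a 12-column BLAST tabular (outfmt 6) alignment.

    ``query_id`` is the viral reference, ``subject_id`` the bacterial contig.
    Subject coordinates are kept as read (1-based inclusive; start may exceed
    end on the minus strand) and order-normalised downstream.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    query_length: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: identity "
                f"{self.pct_identity} outside [0, 100]"
            )
        if self.aln_length < 1:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: alignment length < 1"
            )

    def subject_interval(self) -> tuple[int, int]:
        """Subject coordinates as a 0-based half-open interval, strand-normalised."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass(frozen=True)
class DepthSummary:
    """Mean mapping depth over covered bases and covered fraction of a contig."""

    contig_id: str
    mdepth: float
    coverage: float
    contig_length: int

    def __post_init__(self) -> None:
        if self.mdepth < 0:
            raise FormatError(f"{self.contig_id}: negative mean depth")
        if not 0.0 <= self.coverage <= 1.0:
            raise FormatError(f"{self.contig_id}: coverage {self.coverage} outside [0, 1]")
        if self.coverage == 0 and self.mdepth != 0:
            raise FormatError(f"{self.contig_id}: zero coverage but nonzero depth")


@dataclass(frozen=True)
class SampleMeta:
    """One sample of the longitudinal infant cohort.

    ``infant_id`` is the time-series identifier (infant x age window) that
    defines the random-intercept grouping of the mixed models; ``treatment``
    distinguishes phage-enriched (PE) from standard-extraction (control)
    samples.
    """

    sample_id: str
    infant_id: str
    age_months: int
    delivery: str
    treatment: str

    def __post_init__(self) -> None:
        if not self.infant_id:
            raise FormatError(f"sample {self.sample_id}: empty infant_id")
        if self.age_months not in _VALID_AGES:
            raise FormatError(
                f"sample {self.sample_id}: age_months {self.age_months} not in {_VALID_AGES}"
            )
        if self.delivery not in _VALID_DELIVERY:
            raise FormatError(
                f"sample {self.sample_id}: delivery {self.delivery!r} not in {_VALID_DELIVERY}"
            )
        if self.treatment not in _VALID_TREATMENT:
            raise FormatError(
                f"sample {self.sample_id}: treatment {self.treatment!r} not in {_VALID_TREATMENT}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[ContigRecord]:
    """Read a FASTA file into :class:`ContigRecord` objects.

    Sequences are uppercased; duplicate identifiers and empty sequences are
    rejected with the offending line named.
    """
    path = Path(path)
    records: list[ContigRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(
                f"{path.name}: duplicate contig ID {rec.id!r} "
                f"(line {_find_header_line(path, rec.id)})"
            )
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(
                f"{path.name}: empty sequence for {rec.id!r} "
                f"(line {_find_header_line(path, rec.id)})"
            )
        seen.add(rec.id)
        records.append(ContigRecord(rec.id, seq))
    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def _find_header_line(path: Path, contig_id: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0:1] == [contig_id]:
                return i
    return -1


def write_fasta(records: Iterable[ContigRecord], path: str | Path, width: int = 80) -> None:
    """Write contigs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

_BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]


def read_blast_tab(
    path: str | Path, qlen_map: Mapping[str, int] | None = None
) -> list[AlignmentHit]:
    """Read 12-column BLAST tabular output.

    ``qlen_map`` maps viral query IDs to their sequence lengths, required
    downstream by the identity/coverage filter.  Queries absent from the map
    get ``query_length=None`` and are logged.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(_BLAST_COLUMNS):
                raise FormatError(
                    f"{path.name} line {lineno}: expected {len(_BLAST_COLUMNS)} "
                    f"tab-separated columns, found {len(parts)}"
                )
            row = dict(zip(_BLAST_COLUMNS, parts))
            qlen = None if qlen_map is None else qlen_map.get(row["query_id"])
            if qlen_map is not None and qlen is None:
                logger.warning(
                    "read_blast_tab: query %s has no known length", row["query_id"]
                )
            try:
                hits.append(
                    AlignmentHit(
                        query_id=row["query_id"],
                        subject_id=row["subject_id"],
                        pct_identity=float(row["pct_identity"]),
                        aln_length=int(row["aln_length"]),
                        q_start=int(row["q_start"]),
                        q_end=int(row["q_end"]),
                        s_start=int(row["s_start"]),
                        s_end=int(row["s_end"]),
                        e_value=float(row["e_value"]),
                        query_length=qlen,
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from exc
    logger.info("read_blast_tab: %d hits from %s", len(hits), path)
    return hits


# ---------------------------------------------------------------------------
# samtools-depth-style tables


def read_depth_table(
    path: str | Path, lengths: Mapping[str, int]
) -> list[DepthSummary]:
    """Summarise a 3-column (contig, 1-based position, depth) table.

    ``mdepth`` is the mean depth over positions with depth > 0 and
    ``coverage`` the fraction of contig positions with depth > 0; rows for
    zero-depth positions may be absent.  Contigs in ``lengths`` with no rows
    get ``(0, 0)``.
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig_id", "pos", "depth"],
        dtype={"contig_id": str, "pos": int, "depth": float},
    )
    summaries: list[DepthSummary] = []
    covered = df[df["depth"] > 0]
    grouped = covered.groupby("contig_id", sort=False)
    stats = {
        cid: (float(g["depth"].mean()), int(len(g)), int(g["pos"].max()))
        for cid, g in grouped
    }
    for cid, length in lengths.items():
        if cid in stats:
            mdepth, n_cov, max_pos = stats[cid]
            if max_pos > length:
                raise FormatError(
                    f"{path.name}: position {max_pos} exceeds length {length} of {cid}"
                )
            summaries.append(DepthSummary(cid, mdepth, n_cov / length, length))
        else:
            summaries.append(DepthSummary(cid, 0.0, 0.0, length))
    unknown = set(df["contig_id"]) - set(lengths)
    if unknown:
        raise FormatError(
            f"{path.name}: contigs absent from the lengths map: {sorted(unknown)[:5]}"
        )
    return summaries


# ---------------------------------------------------------------------------
# Metadata and score TSVs


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the sample metadata TSV (sample_id, infant_id, age_months, delivery, treatment)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "infant_id", "age_months", "delivery", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"{Path(path).name}: duplicate sample_id {dup!r}")
    return [
        SampleMeta(
            sample_id=row.sample_id,
            infant_id=row.infant_id,
            age_months=int(row.age_months),
            delivery=row.delivery,
            treatment=row.treatment,
        )
        for row in df.itertuples()
    ]


def meta_to_frame(meta: Sequence[SampleMeta]) -> pd.DataFrame:
    """Sample metadata as a DataFrame indexed by sample_id."""
    return pd.DataFrame(
        {
            "infant_id": [m.infant_id for m in meta],
            "age_months": [m.age_months for m in meta],
            "delivery": [m.delivery for m in meta],
            "treatment": [m.treatment for m in meta],
        },
        index=pd.Index([m.sample_id for m in meta], name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, loadable from YAML."""

    min_identity: float = 70.0        # % identity for unphaging hits
    min_coverage: float = 0.70        # viral-query coverage fraction for unphaging
    min_fragment_len: int = 2000      # bp floor for residual bacterial fragments
    min_contig_len: int = 2000        # bp floor for assembly contigs
    phamer_threshold: float = 0.9     # primary classifier score cutoff
    agreement_min: float = 1.0        # required sum of the two primary scores (strict >)
    dvf_rescue: bool = False          # allow auxiliary classifiers to rescue a contig
    derep_min_identity: float = 0.98  # ANI fraction for dereplication
    derep_min_coverage: float = 0.85  # aligned fraction of the shorter sequence
    taxonomy_reject: float = 0.7      # rejection score, family level
    lifestyle_reject: float = 0.7     # rejection score, lifestyle
    host_min_confidence: float = 95.0 # host-prediction confidence cutoff
    presence_threshold: float = 0.0   # VRU strictly above this counts as present

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
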