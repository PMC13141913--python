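"""Synthetic fixtures with planted ground truth.

Three generators emulate the pipeline's upstream inputs so that every stage
can be scored against a known truth without any external data:

* :func:`simulate_database` -- random bacterial contigs with prophage
  insertions at recorded coordinates, plus matching BLAST-style hits.
* :func:`simulate_scores` -- classifier score tables drawn from separate
  Beta distributions for true phages and non-phages, with stated flip rates.
* :func:`simulate_cohort` -- a miniature longitudinal infant cohort with
  per-infant random intercepts and planted treatment/delivery/age effects,
  emitting Gaussian log-abundance responses, Bernoulli presence responses,
  or a family-level VRU table.

All generators are pure functions of :class:`SimConfig`: the same seed
gives byte-identical output.

The cohort defaults mirror the sampled study population in miniature: two
age windows (with roughly 40% of samples in the younger), a minority of
cesarean-born infants (~17%), and roughly a quarter of samples receiving
the phage-enrichment (PE) treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from phageome.io import AlignmentHit, ContigRecord, SampleMeta
from phageome.mining import ClassifierScores
from phageome.quantify import VRUTable
from phageome.unphage import GenomicInterval

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic-data generators (all rates as fractions)."""

    seed: int = 0
    # database / mining fixtures
    n_bacterial_contigs: int = 100
    prophage_rate: float = 0.4
    contig_length_range: tuple[int, int] = (4000, 12000)
    prophage_length_range: tuple[int, int] = (1000, 3000)
    hit_identity: float = 95.0          # % identity written on synthetic hits
    hit_coverage: float = 1.0           # aligned fraction of the viral query
    # classifier score model
    score_beta_high: tuple[float, float] = (8.0, 1.0)
    score_beta_low: tuple[float, float] = (1.0, 8.0)
    degenerate_scores: bool = False     # draw exactly 1.0 / 0.0 instead of Beta
    classifier_error: Mapping[str, float] = field(
        default_factory=lambda: {"phamer": 0.0, "metaphapred": 0.0, "kraken": 0.0}
    )
    # cohort (miniaturized longitudinal design)
    n_infants: int = 8
    samples_per_infant: int = 10
    cesarean_fraction: float = 7 / 41
    pe_fraction: float = 340 / 1271
    age6_fraction: float = 506 / 1271
    n_families: int = 12
    family_dropout: float = 0.3         # P(family absent in a sample), vru mode
    effect_sizes: Mapping[str, float] = field(
        default_factory=lambda: {"treatment": 0.0, "delivery": 0.0, "age": 0.0}
    )
    intercept: float = 0.0
    random_intercept_sd: float = 0.5
    residual_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.n_infants < 2:
            raise ValueError("n_infants must be >= 2")
        for name in ("prophage_rate", "hit_coverage", "cesarean_fraction",
                     "pe_fraction", "age6_fraction", "family_dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.contig_length_range[0] <= 0 or self.prophage_length_range[0] <= 0:
            raise ValueError("length ranges must be positive")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def mutate_sequence(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Uniform substitution of a fraction ``rate`` of positions (derep fixtures)."""
    arr = np.array(list(sequence))
    k = rng.random(arr.size) < rate
    if k.any():
        subs = rng.choice(_BASES, size=int(k.sum()))
        arr[k] = subs
    return "".join(arr)


def simulate_database(
    config: SimConfig,
) -> tuple[list[ContigRecord], list[GenomicInterval], list[AlignmentHit]]:
    """Bacterial contigs with prophage insertions at recorded coordinates.

    Each contig carries a planted prophage with probability
    ``prophage_rate``; the viral segment is inserted at a random interior
    position and a matching BLAST-style hit is emitted at the configured
    identity and query coverage, so threshold behaviour of the unphaging
    filter is directly testable (e.g. hits written at 60% identity must
    yield zero excisions at a 70% threshold).
    """
    rng = np.random.default_rng(config.seed)
    contigs: list[ContigRecord] = []
    truth: list[GenomicInterval] = []
    hits: list[AlignmentHit] = []
    lo, hi = config.contig_length_range
    plo, phi = config.prophage_length_range
    for i in range(config.n_bacterial_contigs):
        cid = f"bact_{i:04d}"
        backbone = _random_seq(rng, int(rng.integers(lo, hi + 1)))
        if rng.random() < config.prophage_rate:
            vlen = int(rng.integers(plo, phi + 1))
            viral = _random_seq(rng, vlen)
            pos = int(rng.integers(0, len(backbone) + 1))
            seq = backbone[:pos] + viral + backbone[pos:]
            qid = f"virus_{i:04d}"
            truth.append(GenomicInterval(cid, pos, pos + vlen, qid))
            aln_len = max(1, int(round(config.hit_coverage * vlen)))
            hits.append(
                AlignmentHit(
                    query_id=qid,
                    subject_id=cid,
                    pct_identity=config.hit_identity,
                    aln_length=aln_len,
                    q_start=1,
                    q_end=aln_len,
                    s_start=pos + 1,
                    s_end=pos + vlen,
                    e_value=0.0,
                    query_length=vlen,
                )
            )
        else:
            seq = backbone
        contigs.append(ContigRecord(cid, seq))
    return contigs, truth, hits


def simulate_scores(
    truth_table: Mapping[str, bool],
    config: SimConfig,
) -> dict[str, ClassifierScores]:
    """Classifier score tables for contigs with known phage/non-phage labels.

    For each tool independently, the score is drawn from the high-score
    distribution for true phages and the low-score one for non-phages --
    unless that tool's label flips (probability ``classifier_error[tool]``),
    in which case the opposite distribution is used.  With
    ``degenerate_scores`` the distributions collapse to exactly 1.0 / 0.0,
    making consensus recovery of the truth deterministic at zero error.
    """
    rng = np.random.default_rng(config.seed + 1)
    a_hi, b_hi = config.score_beta_high
    a_lo, b_lo = config.score_beta_low

    def draw(high: bool) -> float:
        if config.degenerate_scores:
            return 1.0 if high else 0.0
        return float(rng.beta(a_hi, b_hi) if high else rng.beta(a_lo, b_lo))

    err = dict(config.classifier_error)
    out: dict[str, ClassifierScores] = {}
    for cid, is_phage in truth_table.items():
        flip_phamer = rng.random() < err.get("phamer", 0.0)
        flip_meta = rng.random() < err.get("metaphapred", 0.0)
        flip_kraken = rng.random() < err.get("kraken", 0.0)
        out[cid] = ClassifierScores(
            contig_id=cid,
            phamer=draw(is_phage != flip_phamer),
            metaphapred=draw(is_phage != flip_meta),
            deepvirfinder=draw(is_phage),
            virsorter2_viral=bool(is_phage),
            kraken_bacterial=(not is_phage) != flip_kraken,
        )
    return out


def _simulate_meta(config: SimConfig, rng: np.random.Generator) -> list[SampleMeta]:
    meta: list[SampleMeta] = []
    for j in range(config.n_infants):
        infant = f"infant_{j:03d}"
        delivery = "cesarean" if rng.random() < config.cesarean_fraction else "vaginal"
        for s in range(config.samples_per_infant):
            age = 6 if rng.random() < config.age6_fraction else 12
            treatment = "PE" if rng.random() < config.pe_fraction else "control"
            meta.append(
                SampleMeta(
                    sample_id=f"{infant}_s{s:03d}",
                    infant_id=infant,
                    age_months=age,
                    delivery=delivery,
                    treatment=treatment,
                )
            )
    return meta


def _linear_predictor(
    meta: list[SampleMeta], config: SimConfig, intercepts: Mapping[str, float]
) -> np.ndarray:
    eff = dict(config.effect_sizes)
    eta = np.full(len(meta), config.intercept)
    for i, m in enumerate(meta):
        eta[i] += intercepts[m.infant_id]
        eta[i] += eff.get("treatment", 0.0) * (m.treatment == "PE")
        eta[i] += eff.get("delivery", 0.0) * (m.delivery == "vaginal")
        eta[i] += eff.get("age", 0.0) * (m.age_months == 12)
    return eta


def simulate_cohort(
    config: SimConfig,
    family: str = "gaussian",
) -> tuple[pd.Series | pd.DataFrame | VRUTable, list[SampleMeta]]:
    """A miniature longitudinal cohort with planted covariate effects.

    ``family="gaussian"`` returns a log-abundance Series
    (eta + N(0, residual_sd)); ``family="binomial"`` a 0/1 presence Series
    (Bernoulli(logit^-1(eta))); ``family="vru"`` a family-level
    :class:`VRUTable` in which the treatment effect shifts the log weights
    of the first half of the families.  All modes share the per-infant
    random intercepts ~ N(0, random_intercept_sd).
    """
    rng = np.random.default_rng(config.seed + 2)
    meta = _simulate_meta(config, rng)
    infants = sorted({m.infant_id for m in meta})
    intercepts = {
        inf: config.random_intercept_sd * rng.standard_normal() for inf in infants
    }
    sample_ids = [m.sample_id for m in meta]
    eta = _linear_predictor(meta, config, intercepts)
    if family == "gaussian":
        y = eta + config.residual_sd * rng.standard_normal(len(meta))
        return pd.Series(y, index=sample_ids, name="log_abundance"), meta
    if family == "binomial":
        p = 1.0 / (1.0 + np.exp(-eta))
        y = (rng.random(len(meta)) < p).astype(int)
        return pd.Series(y, index=sample_ids, name="presence"), meta
    if family == "vru":
        n_f = config.n_families
        base = rng.normal(0.0, 1.0, size=n_f)  # family-level mean log weight
        affected = np.arange(n_f) < n_f // 2
        rows = []
        for i, m in enumerate(meta):
            shift = dict(config.effect_sizes).get("treatment", 0.0) * (
                m.treatment == "PE"
            )
            logw = (
                base
                + intercepts[m.infant_id]
                + np.where(affected, shift, 0.0)
                + config.residual_sd * rng.standard_normal(n_f)
            )
            w = np.exp(logw)
            absent = rng.random(n_f) < config.family_dropout
            if absent.all():  # keep at least the dominant family
                absent[int(np.argmax(w))] = False
            w = np.where(absent, 0.0, w)
            rows.append(w / w.sum())
        values = pd.DataFrame(
            rows,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=pd.MultiIndex.from_tuples(
                [(f"Family_{k:02d}", "unclassified", "unclassified") for k in range(n_f)],
                names=["family", "lifestyle", "host_genus"],
            ),
        )
        return VRUTable(values=values), meta
    raise ValueError(f"unknown family {family!r}")
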