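"""Viral relative units (VRU).

Mapped-read abundance of viral contigs is summarised per sample as
``weight_i = mdepth_i * coverage_i`` (mean depth over covered bases times
covered fraction, i.e. total mapped bases over contig length) and normalised
to ``VRU_i = weight_i / sum_i weight_i`` so each sample's VRUs sum to 1.
Contigs are then aggregated into phage groups sharing taxonomy, lifestyle
and host, which preserves the row sums exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phageome.io import DepthSummary

logger = logging.getLogger("phageome")

UNCLASSIFIED = "unclassified"

GroupKey = tuple[str, str, str]  # (family, lifestyle, host_genus)


@dataclass
class VRUTable:
    """Sample x phage-group relative-abundance matrix.

    ``values`` is a DataFrame with sample IDs as the row index and
    (family, lifestyle, host_genus) tuples as the column MultiIndex; every
    row with signal sums to 1.  ``empty_samples`` lists samples in which no
    contig had any mapped reads (their rows are all-zero).
    """

    values: pd.DataFrame
    empty_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def groups(self) -> list[GroupKey]:
        return [tuple(c) for c in self.values.columns]

    def family_table(self) -> pd.DataFrame:
        """Collapse groups to the family level (sample x family)."""
        return self.values.T.groupby(level="family").sum().T


def compute_vru(depths: Sequence[DepthSummary]) -> tuple[pd.Series, bool]:
    """Per-contig VRU vector for one sample.

    Returns ``(vru, empty)``: a Series indexed by contig ID summing to 1,
    or an all-zero vector with ``empty=True`` when no contig carries signal.
    """
    ids = [d.contig_id for d in depths]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig IDs in one sample's depth summaries")
    weights = np.array([d.mdepth * d.coverage for d in depths], dtype=float)
    total = weights.sum()
    if total <= 0:
        return pd.Series(np.zeros(len(ids)), index=ids, name="vru"), True
    return pd.Series(weights / total, index=ids, name="vru"), False


def group_phages(
    vru_by_sample: Mapping[str, pd.Series],
    annotations: Mapping[str, tuple[str | None, str | None, str | None]],
) -> VRUTable:
    """Aggregate per-contig VRUs into (family, lifestyle, host_genus) groups.

    Null annotation levels map to the explicit ``"unclassified"`` level so
    row sums stay exactly 1.  A contig carrying VRU but lacking an
    annotation row is an error.
    """
    group_of: dict[str, GroupKey] = {}
    frames: dict[str, pd.Series] = {}
    empty_samples: list[str] = []
    for sample_id, vru in vru_by_sample.items():
        missing = [cid for cid in vru.index if cid not in annotations]
        if missing:
            raise ValueError(
                f"sample {sample_id}: contigs without annotation rows: {missing[:5]}"
            )
        for cid in vru.index:
            fam, ls, host = annotations[cid]
            group_of[cid] = (
                fam or UNCLASSIFIED,
                ls or UNCLASSIFIED,
                host or UNCLASSIFIED,
            )
        keys = pd.Series([group_of[c] for c in vru.index], index=vru.index)
        grouped = vru.groupby(keys).sum()
        frames[sample_id] = grouped
        if vru.sum() == 0:
            empty_samples.append(sample_id)
    df = pd.DataFrame(frames).T.fillna(0.0)
    df.index.name = "sample_id"
    df.columns = pd.MultiIndex.from_tuples(
        df.columns, names=["family", "lifestyle", "host_genus"]
    )
    df = df.sort_index(axis=1)
    return VRUTable(values=df, empty_samples=sorted(empty_samples))


def presence_table(vru_table: VRUTable, threshold: float = 0.0) -> pd.DataFrame:
    """Binary sample x group matrix: present iff VRU strictly above threshold."""
    return (vru_table.values > threshold).astype(int)


def write_vru_tsv(vru_table: VRUTable, path) -> None:
    """Long-format TSV: sample_id, family, lifestyle, host_genus, vru."""
    long = vru_table.values.stack(["family", "lifestyle", "host_genus"], future_stack=True)
    long = long[long > 0].rename("vru").reset_index()
    long.to_csv(path, sep="\t", index=False)


def read_vru_tsv(path) -> VRUTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    wide = df.pivot_table(
        index="sample_id",
        columns=["family", "lifestyle", "host_genus"],
        values="vru",
        fill_value=0.0,
        aggfunc="sum",
    )
    empty = [s for s in wide.index if wide.loc[s].sum() == 0]
    return VRUTable(values=wide, empty_samples=empty)
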