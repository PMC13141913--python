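"""Bookkeeping reports: cohort summaries and cross-tabulation checks.

The cohort validator recomputes study-level totals (samples per age window,
per delivery mode, per treatment arm, infants per delivery mode) from the
sample metadata and verifies that the marginal counts are consistent --
every breakdown of the cohort must sum to the same total.
"""

from __future__ import annotations

from typing import Sequence

from phageome.io import SampleMeta


def cohort_summary(meta: Sequence[SampleMeta]) -> dict[str, int]:
    """Totals and subgroup counts of a sample cohort.

    Raises if any subgroup breakdown fails to sum to the overall total
    (which cannot happen for well-formed metadata, but catches corrupted
    or double-counted tables).
    """
    n_samples = len(meta)
    by_age = {age: sum(1 for m in meta if m.age_months == age) for age in (6, 12)}
    by_delivery = {
        d: sum(1 for m in meta if m.delivery == d) for d in ("cesarean", "vaginal")
    }
    by_treatment = {
        t: sum(1 for m in meta if m.treatment == t) for t in ("control", "PE")
    }
    infants = {m.infant_id for m in meta}
    infants_by_delivery = {
        d: len({m.infant_id for m in meta if m.delivery == d})
        for d in ("cesarean", "vaginal")
    }
    for name, counts in (
        ("age", by_age),
        ("delivery", by_delivery),
        ("treatment", by_treatment),
    ):
        if sum(counts.values()) != n_samples:
            raise ValueError(f"inconsistent {name} breakdown: {counts} vs {n_samples}")
    summary = {
        "n_samples": n_samples,
        "n_infants": len(infants),
        "samples_age6": by_age[6],
        "samples_age12": by_age[12],
        "samples_cesarean": by_delivery["cesarean"],
        "samples_vaginal": by_delivery["vaginal"],
        "samples_control": by_treatment["control"],
        "samples_PE": by_treatment["PE"],
        "infants_cesarean": infants_by_delivery["cesarean"],
        "infants_vaginal": infants_by_delivery["vaginal"],
    }
    return summary


def totals_from_subgroups(**subgroup_counts: int) -> int:
    """Sum subgroup counts into a total, rejecting negatives."""
    for name, n in subgroup_counts.items():
        if n < 0:
            raise ValueError(f"negative count for {name}")
    return sum(subgroup_counts.values())
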