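import numpy as np
import pytest

from phageome.annotation import (
    HostCall,
    LifestyleCall,
    PhageBin,
    TaxonomyCall,
    annotation_rates,
    count_annotated,
    filter_hosts,
    filter_lifestyle,
    filter_taxonomy,
    merge_host_sources,
    merge_taxonomy_sources,
    propagate_bin_taxonomy,
)

WHITELIST = frozenset({"Fam_A", "Fam_B", "Fam_C"})


class TestFilterTaxonomy:
    @pytest.mark.parametrize(
        "family,score,expect_family",
        [
            ("Fam_A", 0.85, "Fam_A"),   # confident and whitelisted
            ("Fam_A", 0.65, None),      # below rejection score
            ("EnvFamX", 0.90, None),    # not in the whitelist
            ("Fam_B", 0.70, "Fam_B"),   # boundary inclusive
        ],
    )
    def test_rejection_and_whitelist(self, family, score, expect_family):
        (out,) = filter_taxonomy(
            [TaxonomyCall("c", family, score)], 0.7, WHITELIST
        )
        assert out.family == expect_family

    def test_rows_retained_for_traceability(self):
        out = filter_taxonomy(
            [TaxonomyCall("c1", "Fam_A", 0.1), TaxonomyCall("c2", None, None)],
            0.7,
            WHITELIST,
        )
        assert [c.contig_id for c in out] == ["c1", "c2"]

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            filter_taxonomy([TaxonomyCall("c", "Fam_A", 0.9)], 0.7, frozenset())

    def test_idempotent(self):
        calls = [
            TaxonomyCall("c1", "Fam_A", 0.9),
            TaxonomyCall("c2", "Fam_B", 0.3),
        ]
        once = filter_taxonomy(calls, 0.7, WHITELIST)
        assert filter_taxonomy(once, 0.7, WHITELIST) == once


class TestMergeTaxonomySources:
    def test_agreement_policy_nulls_conflicts(self):
        primary = [TaxonomyCall("c", "Fam_A", 0.9)]
        secondary = [TaxonomyCall("c", "Fam_B", 0.8, source="virotaxo_like")]
        (out,) = merge_taxonomy_sources(primary, secondary)
        assert out.family is None

    def test_single_source_family_stands(self):
        primary = [TaxonomyCall("c", "Fam_A", 0.9)]
        secondary = [TaxonomyCall("c", None, None, source="virotaxo_like")]
        (out,) = merge_taxonomy_sources(primary, secondary)
        assert out.family == "Fam_A"

    def test_primary_priority_policy(self):
        primary = [TaxonomyCall("c", "Fam_A", 0.9)]
        secondary = [TaxonomyCall("c", "Fam_B", 0.8, source="virotaxo_like")]
        (out,) = merge_taxonomy_sources(primary, secondary, policy="primary_priority")
        assert out.family == "Fam_A"


class TestPropagateBinTaxonomy:
    def test_single_family_propagates(self):
        bins = [PhageBin("b1", ["c1", "c2", "c3"])]
        calls = [
            TaxonomyCall("c1", "Fam_A", 0.9),
            TaxonomyCall("c2", None, None),
            TaxonomyCall("c3", None, None),
        ]
        out_bins, families, frac = propagate_bin_taxonomy(bins, calls)
        assert out_bins[0].family == "Fam_A"
        assert families == {"c1": "Fam_A", "c2": "Fam_A", "c3": "Fam_A"}
        assert frac == 0.0

    def test_conflicting_bin_discarded(self):
        bins = [PhageBin("b1", ["c1", "c2"])]
        calls = [TaxonomyCall("c1", "Fam_A", 0.9), TaxonomyCall("c2", "Fam_B", 0.9)]
        out_bins, families, frac = propagate_bin_taxonomy(bins, calls)
        assert out_bins[0].discarded
        assert families == {"c1": None, "c2": None}
        assert frac == 1.0

    def test_unannotated_bin_retained(self):
        bins = [PhageBin("b1", ["c1"])]
        out_bins, families, _ = propagate_bin_taxonomy(
            bins, [TaxonomyCall("c1", None, None)]
        )
        assert not out_bins[0].discarded and out_bins[0].family is None

    def test_contig_in_two_bins_rejected(self):
        bins = [PhageBin("b1", ["c1"]), PhageBin("b2", ["c1"])]
        with pytest.raises(ValueError, match="c1"):
            propagate_bin_taxonomy(bins, [TaxonomyCall("c1", "Fam_A", 0.9)])

    def test_planted_conflict_fraction(self, rng):
        """100 synthetic bins with 5 planted conflicts -> fraction 0.05."""
        bins, calls = [], []
        conflicted = set(rng.choice(100, size=5, replace=False))
        for b in range(100):
            members = [f"b{b}_c{k}" for k in range(3)]
            bins.append(PhageBin(f"bin{b}", members))
            fams = ["Fam_A", "Fam_B"] if b in conflicted else ["Fam_A", "Fam_A"]
            calls.append(TaxonomyCall(members[0], fams[0], 0.9))
            calls.append(TaxonomyCall(members[1], fams[1], 0.9))
            calls.append(TaxonomyCall(members[2], None, None))
        _, _, frac = propagate_bin_taxonomy(bins, calls)
        assert frac == pytest.approx(0.05)

    def test_never_invents_a_family(self, rng):
        bins = [PhageBin(f"b{i}", [f"b{i}_c{k}" for k in range(4)]) for i in range(20)]
        fams = ["Fam_A", "Fam_B", "Fam_C", None]
        calls = [
            TaxonomyCall(f"b{i}_c{k}", f, 0.9 if f else None)
            for i in range(20)
            for k, f in enumerate(rng.choice(fams, size=4))
        ]
        out_bins, families, _ = propagate_bin_taxonomy(bins, calls)
        member_families = {c.contig_id: c.family for c in calls}
        for b in out_bins:
            if b.family is not None:
                present = {member_families[m] for m in b.member_ids} - {None}
                assert b.family in present


class TestFilterLifestyle:
    @pytest.mark.parametrize(
        "score,expected",
        [(0.71, "temperate"), (0.70, "temperate"), (0.69, None)],
    )
    def test_rejection_boundary(self, score, expected):
        (out,) = filter_lifestyle([LifestyleCall("c", "temperate", score)], 0.7)
        assert out.lifestyle == expected

    def test_idempotent(self):
        calls = [LifestyleCall("c", "virulent", 0.5)]
        once = filter_lifestyle(calls)
        assert filter_lifestyle(once) == once


class TestFilterHosts:
    @pytest.mark.parametrize(
        "confidence,shared,kept",
        [(97.0, 12, True), (97.0, 0, False), (94.9, 5, False), (95.0, 1, True)],
    )
    def test_confidence_and_shared_proteins(self, confidence, shared, kept):
        calls = [HostCall("c", "Bacteroides", confidence=confidence,
                          shared_proteins=shared)]
        assert len(filter_hosts(calls)) == (1 if kept else 0)

    def test_kraken_calls_pass_untouched(self):
        calls = [HostCall("c", "Veillonella", confidence=0, source="kraken_like")]
        assert filter_hosts(calls) == calls


class TestMergeHostSources:
    def test_agreeing_sources_no_flag(self):
        merged = merge_host_sources(
            [HostCall("c", "Bacteroides", confidence=97, shared_proteins=3)],
            [HostCall("c", "Bacteroides", source="kraken_like")],
        )
        assert merged["c"].host_genus == "Bacteroides"
        assert not merged["c"].conflict

    def test_kraken_fills_missing(self):
        merged = merge_host_sources(
            [], [HostCall("c", "Veillonella", source="kraken_like")]
        )
        assert merged["c"].host_genus == "Veillonella"

    def test_conflict_resolved_toward_alignment_source(self):
        merged = merge_host_sources(
            [HostCall("c", "Streptococcus", confidence=97, shared_proteins=3)],
            [HostCall("c", "Clostridium", source="kraken_like")],
        )
        assert merged["c"].host_genus == "Streptococcus"
        assert merged["c"].conflict


class TestAnnotationRates:
    def test_manual_counts_exact(self):
        tax = [TaxonomyCall(f"c{i}", "Fam_A" if i < 3 else None,
                            0.9 if i < 3 else None) for i in range(10)]
        ls = [LifestyleCall(f"c{i}", "temperate" if i < 7 else None,
                            0.9 if i < 7 else None) for i in range(10)]
        hosts = [HostCall(f"c{i}", "Bacteroides" if i < 8 else None,
                          "B. fragilis" if i < 2 else None,
                          confidence=99, shared_proteins=5) for i in range(10)]
        counts = count_annotated(tax, ls, hosts)
        assert counts == {
            "family": 3, "lifestyle": 7, "host_genus": 8, "host_species": 2
        }
        rates = annotation_rates(10, **{f"n_{k}": v for k, v in counts.items()})
        assert rates == {
            "family": 30.0, "lifestyle": 70.0, "host_genus": 80.0, "host_species": 20.0
        }

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            annotation_rates(0, n_family=0)
        with pytest.raises(ValueError):
            annotation_rates(10, n_family=11)
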