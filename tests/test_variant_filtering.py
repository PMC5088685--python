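"""Germline filter cascade, somatic subtraction, and characterization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_variant
from oncocase.variants import (
    GeneLists,
    apply_frequency_filter,
    apply_reference_range_filter,
    apply_reportable_range_filter,
    call_somatic_by_subtraction,
    characterize_somatic,
    records_from_frame,
    run_filter_cascade,
)

LISTS = GeneLists.from_iterables(reference_range=["APC", "TP53", "BRCA1"],
                                 acmg=["MLH1", "RET"])


class TestFilterCascade:
    def test_reference_range_buckets_on_panel_gene(self):
        # a germline APC frameshift must surface through the predisposition panel
        var = make_variant(gene="APC", consequence="frameshift")
        (dec,) = apply_reference_range_filter([var], LISTS)
        assert dec.report_bucket == "reference_range"

    def test_off_panel_variant_passes_through(self):
        (dec,) = apply_reference_range_filter([make_variant(gene="NOTALIST")], LISTS)
        assert dec.report_bucket == "frequency_pass"
        assert "reference_range" in dec.passed_filters

    def test_reference_range_counts_match_set_intersection(self):
        on = [make_variant(pos=i + 1, gene="TP53") for i in range(5)]
        off = [make_variant(pos=100 + i, gene=f"OTHER{i}") for i in range(15)]
        decisions = apply_reference_range_filter(on + off, LISTS)
        assert sum(d.report_bucket == "reference_range" for d in decisions) == 5

    def test_empty_reference_list_is_config_error(self):
        with pytest.raises(ValueError):
            apply_reference_range_filter([make_variant()], GeneLists())

    @pytest.mark.parametrize("in_cosmic,gene,expected", [
        (True, "NOTALIST", "reportable_range"),   # COSMIC membership alone
        (False, "MLH1", "reportable_range"),      # ACMG secondary-findings gene
        (False, "NOTALIST", "frequency_pass"),    # neither
    ])
    def test_reportable_range_rule(self, in_cosmic, gene, expected):
        var = make_variant(gene=gene, in_cosmic=in_cosmic)
        (dec,) = apply_reportable_range_filter([var], LISTS)
        assert dec.report_bucket == expected

    @pytest.mark.parametrize("paf,retained", [
        (0.009, True),
        (0.01, False),   # strict less-than at the 1% boundary
        (0.02, False),
        (None, True),    # missing frequency treated as rare
    ])
    def test_frequency_filter_boundary(self, paf, retained):
        (dec,) = apply_frequency_filter([make_variant(population_af=paf)])
        assert (dec.report_bucket != "excluded") is retained

    def test_frequency_threshold_validated(self):
        with pytest.raises(ValueError):
            apply_frequency_filter([make_variant()], threshold=0.0)

    def test_cascade_partitions_every_variant(self, paired_records):
        normal, _ = paired_records
        decisions = run_filter_cascade(normal, LISTS)
        assert len(decisions) == len(normal)
        buckets = {"reference_range", "reportable_range", "frequency_pass", "excluded"}
        assert all(d.report_bucket in buckets for d in decisions)
        for d in decisions:
            assert (d.failed_filter is not None) == (d.report_bucket == "excluded")

    def test_tightening_frequency_filter_shrinks_retained_set(self, paired_records):
        normal, _ = paired_records
        loose = {d.variant.key for d in run_filter_cascade(normal, LISTS, 0.05)
                 if d.report_bucket != "excluded"}
        tight = {d.variant.key for d in run_filter_cascade(normal, LISTS, 0.01)
                 if d.report_bucket != "excluded"}
        assert tight <= loose


class TestSomaticSubtraction:
    def test_tumor_only_variant_is_somatic(self):
        tumor = [make_variant(tumor_af=0.45)]
        normal = [make_variant(normal_af=0.02)]
        out = call_somatic_by_subtraction(tumor, normal)
        assert len(out) == 1
        assert out[0].normal_af == 0.02

    def test_below_tumor_cutoff_dropped(self):
        assert call_somatic_by_subtraction([make_variant(tumor_af=0.08)], []) == []

    def test_exact_threshold_variants_included(self):
        # "output at" 5% / 10% means inclusive at the boundary
        tumor = [make_variant(tumor_af=0.10)]
        assert len(call_somatic_by_subtraction(tumor, [])) == 1
        normal = [make_variant(normal_af=0.05)]
        assert call_somatic_by_subtraction(tumor, normal) == []

    def test_germline_site_not_somatic(self):
        out = call_somatic_by_subtraction([make_variant(tumor_af=0.5)],
                                          [make_variant(normal_af=0.5)])
        assert out == []

    def test_duplicate_keys_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            call_somatic_by_subtraction([make_variant(), make_variant()], [])

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_matches_brute_force_subtraction(self, data):
        """Keyed subtraction equals the double loop over all key pairs."""
        def table(role):
            n = data.draw(st.integers(0, 12))
            seen = set()
            records = []
            for i in range(n):
                pos = data.draw(st.integers(1, 6))
                alt = data.draw(st.sampled_from("TG"))
                if ("chr1", pos, "A", alt) in seen:
                    continue
                seen.add(("chr1", pos, "A", alt))
                af = data.draw(st.floats(0, 1, allow_nan=False))
                records.append(make_variant(pos=pos, alt=alt,
                                            **{f"{role}_af": af}))
            return records

        tumor, normal = table("tumor"), table("normal")
        got = {r.key for r in call_somatic_by_subtraction(tumor, normal)}
        expected = set()
        for t in tumor:
            if t.tumor_af < 0.10:
                continue
            germline = any(n.key == t.key and n.normal_af >= 0.05 for n in normal)
            if not germline:
                expected.add(t.key)
        assert got == expected

    def test_synthetic_recovery_is_exact(self, variant_case, paired_records):
        _, _, _, truth = variant_case
        normal, tumor = paired_records
        somatic = call_somatic_by_subtraction(tumor, normal)
        called = {r.key for r in somatic}
        true = {
            (r.chrom, int(r.pos), r.ref, r.alt)
            for r in truth[truth["label"] == "somatic"].itertuples(index=False)
        }
        assert called == true


class TestCharacterization:
    def test_de_novo_requires_absent_in_both_parents(self):
        var = make_variant(gene="APC", consequence="frameshift")
        trio = {var.key: ("het", "ref", "ref")}
        (ann,) = characterize_somatic([var], trio=trio)
        assert ann.de_novo is True
        trio = {var.key: ("het", "het", "ref")}
        (ann,) = characterize_somatic([var], trio=trio)
        assert ann.de_novo is False

    def test_missing_parent_genotype_is_indeterminate(self):
        var = make_variant()
        (ann,) = characterize_somatic([var], trio={var.key: ("het", "missing", "ref")})
        assert ann.de_novo is None
        (ann,) = characterize_somatic([var], trio={})
        assert ann.de_novo is None

    def test_compound_heterozygous_needs_two_non_hom_in_gene(self):
        a = make_variant(pos=10, gene="MSH6", tumor_af=0.4)
        b = make_variant(pos=20, gene="MSH6", tumor_af=0.5)
        c = make_variant(pos=30, gene="OTHER", tumor_af=0.5)
        anns = characterize_somatic([a, b, c])
        assert [x.compound_heterozygous for x in anns] == [True, True, False]

    def test_homozygous_excluded_from_compound_het(self):
        a = make_variant(pos=10, gene="MSH6", tumor_af=0.9)
        b = make_variant(pos=20, gene="MSH6", tumor_af=0.5)
        anns = characterize_somatic([a, b])
        assert anns[0].homozygous and not anns[0].compound_heterozygous
        assert not anns[1].compound_heterozygous

    def test_loh_suggestive_when_high_af_over_het_normal(self):
        # TP53-like: tumor AF 0.85 over a heterozygous germline background
        var = make_variant(gene="TP53", tumor_af=0.85, genotype_normal="het")
        (ann,) = characterize_somatic([var])
        assert ann.loh_suggestive

    @pytest.mark.parametrize("consequence,expected", [
        ("nonsense", True), ("frameshift", True), ("splice", True),
        ("missense", False), ("synonymous", False),
    ])
    def test_disruptive_consequence_classes(self, consequence, expected):
        (ann,) = characterize_somatic([make_variant(consequence=consequence)])
        assert ann.disruptive is expected


def test_records_from_frame_round_trip(variant_case):
    _, normal, _, _ = variant_case
    records = records_from_frame(normal, "normal")
    assert len(records) == len(normal)
    assert records[0].normal_af == normal["af"].iloc[0]
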