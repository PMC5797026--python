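"""Somatic filter: Fisher exact test, retention rules, profile building."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nkaml import (
    FilterReason,
    VariantCall,
    VariantClass,
    apply_filter,
    build_profiles,
    filter_variants,
    fisher_two_sided,
)


def fisher_oracle(t_ref, t_alt, n_ref, n_alt):
    """Independent brute-force enumeration of the two-sided hypergeometric tail.

    Walks every table with the observed margins, computing each probability
    directly from log-factorials, and sums those no more probable than the
    observed table.
    """
    total = t_ref + t_alt + n_ref + n_alt
    alt_total = t_alt + n_alt
    tumor_total = t_ref + t_alt

    def log_p(x):
        # P(X = x) for X hypergeometric(total, alt_total, tumor_total)
        return (
            math.lgamma(alt_total + 1) - math.lgamma(x + 1) - math.lgamma(alt_total - x + 1)
            + math.lgamma(total - alt_total + 1)
            - math.lgamma(tumor_total - x + 1)
            - math.lgamma(total - alt_total - tumor_total + x + 1)
            - (math.lgamma(total + 1) - math.lgamma(tumor_total + 1)
               - math.lgamma(total - tumor_total + 1))
        )

    lo = max(0, tumor_total + alt_total - total)
    hi = min(alt_total, tumor_total)
    p_obs = math.exp(log_p(t_alt))
    p = sum(
        math.exp(log_p(x))
        for x in range(lo, hi + 1)
        if math.exp(log_p(x)) <= p_obs * (1 + 1e-10)
    )
    return min(p, 1.0)


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_two_sided(10, 10, 10, 10) == pytest.approx(1.0)

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_two_sided(100, 0, 100, 0) == pytest.approx(1.0)

    def test_all_zero_table_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_two_sided(0, 0, 0, 0)

    def test_negative_count_is_an_error(self):
        with pytest.raises(ValueError):
            fisher_two_sided(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_on_spec_table(self):
        assert fisher_two_sided(90, 10, 100, 0) == pytest.approx(
            fisher_oracle(90, 10, 100, 0), abs=1e-12
        )

    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_two_sided(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    @given(
        st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_under_row_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_two_sided(a, b, c, d) == pytest.approx(
            fisher_two_sided(c, d, a, b), abs=1e-12
        )


def _call(gene="NPM1", t_ref=70, t_alt=30, n_ref=100, n_alt=0, **kw):
    return VariantCall(
        patient_id=kw.pop("patient_id", "P1"),
        gene=gene,
        variant_class=kw.pop("variant_class", VariantClass.MISSENSE),
        tumor_ref_depth=t_ref,
        tumor_alt_depth=t_alt,
        normal_ref_depth=n_ref,
        normal_alt_depth=n_alt,
        **kw,
    )


class TestApplyFilter:
    def test_below_vaf_floor_rejected_even_with_strong_fisher(self, panel):
        v = _call(t_ref=971, t_alt=29, n_ref=1000, n_alt=0)  # VAF 0.029, p ~ 1e-9
        d = apply_filter(v, panel)
        assert not d.retained and d.reason is FilterReason.BELOW_VAF
        assert d.fisher_p < 1e-6

    def test_vaf_exactly_three_percent_passes_the_floor(self, panel):
        v = _call(t_ref=970, t_alt=30, n_ref=1000, n_alt=0)
        d = apply_filter(v, panel)
        assert d.retained and d.vaf == pytest.approx(0.03)

    def test_fisher_at_exact_threshold_fails(self, panel):
        # p_max equal to the variant's own p: the strict boundary rejects
        v = _call(t_ref=70, t_alt=30)
        d = apply_filter(v, panel)
        d2 = apply_filter(v, panel, p_max=d.fisher_p)
        assert not d2.retained and d2.reason is FilterReason.FISHER_NS

    def test_nonsignificant_fisher_rejected(self, panel):
        v = _call(t_ref=7, t_alt=3, n_ref=10, n_alt=1)  # VAF 0.3, p >> 0.001
        d = apply_filter(v, panel)
        assert not d.retained and d.reason is FilterReason.FISHER_NS

    def test_control_free_path_uses_the_flag(self, panel):
        v = _call(t_ref=55, t_alt=45, n_ref=None, n_alt=None,
                  control_free_somatic_flag=True)
        d = apply_filter(v, panel)
        assert d.retained and d.fisher_p is None
        v2 = _call(t_ref=55, t_alt=45, n_ref=None, n_alt=None,
                   control_free_somatic_flag=False)
        assert apply_filter(v2, panel).reason is FilterReason.CONTROL_FREE_FAIL

    def test_reason_order_panel_before_vaf_before_germline(self, panel):
        off_panel = _call(gene="BRAF", t_ref=999, t_alt=1, germline_suspect_flag=True)
        assert apply_filter(off_panel, panel).reason is FilterReason.NOT_IN_PANEL
        low_and_germline = _call(t_ref=999, t_alt=1, germline_suspect_flag=True)
        assert apply_filter(low_and_germline, panel).reason is FilterReason.BELOW_VAF
        germline = _call(germline_suspect_flag=True)
        assert apply_filter(germline, panel).reason is FilterReason.GERMLINE_SUSPECT

    def test_raising_vaf_floor_is_monotone(self, panel, rng):
        variants = [
            _call(
                patient_id=f"P{i}",
                t_ref=int(rng.integers(50, 400)),
                t_alt=int(rng.integers(1, 120)),
                n_ref=int(rng.integers(50, 400)),
                n_alt=int(rng.integers(0, 3)),
            )
            for i in range(80)
        ]
        kept_sets = []
        for vaf_min in (0.01, 0.03, 0.10, 0.25):
            kept_sets.append(
                {d.variant.patient_id
                 for d in filter_variants(variants, panel, vaf_min=vaf_min)
                 if d.retained}
            )
        for tighter, looser in zip(kept_sets[1:], kept_sets):
            assert tighter <= looser

    def test_retained_set_equals_brute_force_rule_conjunction(self, panel, rng):
        variants = []
        for i in range(120):
            has_control = rng.random() < 0.6
            variants.append(
                VariantCall(
                    patient_id=f"P{i}",
                    gene=str(rng.choice(["NPM1", "TP53", "BRAF", "SRSF2"])),
                    variant_class=VariantClass.MISSENSE,
                    tumor_ref_depth=int(rng.integers(10, 300)),
                    tumor_alt_depth=int(rng.integers(0, 60)),
                    normal_ref_depth=int(rng.integers(10, 300)) if has_control else None,
                    normal_alt_depth=int(rng.integers(0, 10)) if has_control else None,
                    germline_suspect_flag=bool(rng.random() < 0.2),
                    control_free_somatic_flag=bool(rng.random() < 0.5),
                )
            )
        variants = [v for v in variants if v.tumor_depth > 0]
        decisions = filter_variants(variants, panel)
        for d in decisions:
            v = d.variant
            expected = (
                v.gene in panel
                and v.vaf >= 0.03
                and not v.germline_suspect_flag
                and (
                    fisher_two_sided(
                        v.tumor_ref_depth, v.tumor_alt_depth,
                        v.normal_ref_depth, v.normal_alt_depth,
                    ) < 0.001
                    if v.has_control
                    else v.control_free_somatic_flag
                )
            )
            assert d.retained == expected


class TestBuildProfiles:
    def test_two_distinct_cebpa_variants_mark_biallelic(self, panel):
        vs = [
            _call(gene="CEBPA", protein_change="p.P23fs",
                  variant_class=VariantClass.FRAMESHIFT),
            _call(gene="CEBPA", protein_change="p.K313dup",
                  variant_class=VariantClass.INFRAME_INDEL),
        ]
        (p,) = build_profiles(vs, panel)
        assert p.biallelic_cebpa and p.n_driver_mutations == 2

    def test_single_cebpa_variant_is_not_biallelic(self, panel):
        (p,) = build_profiles([_call(gene="CEBPA")], panel)
        assert not p.biallelic_cebpa

    def test_explicit_biallelic_annotation_suffices(self, panel):
        (p,) = build_profiles(
            [_call(gene="CEBPA", biallelic_annotation=True)], panel
        )
        assert p.biallelic_cebpa

    def test_idh2_codon_172_flag(self, panel):
        (p,) = build_profiles([_call(gene="IDH2", protein_change="p.R172K")], panel)
        assert p.idh2_r172
        (q,) = build_profiles([_call(gene="IDH2", protein_change="p.R140Q")], panel)
        assert not q.idh2_r172

    def test_flt3_itd_flag_requires_itd_class(self, panel):
        (p,) = build_profiles(
            [_call(gene="FLT3", variant_class=VariantClass.ITD)], panel
        )
        assert p.flt3_itd
        (q,) = build_profiles(
            [_call(gene="FLT3", protein_change="p.D835Y")], panel
        )
        assert not q.flt3_itd

    def test_duplicate_rows_deduplicated_with_warning(self, panel):
        v = _call()
        with pytest.warns(UserWarning, match="duplicate"):
            (p,) = build_profiles([v, v], panel)
        assert p.n_driver_mutations == 1

    def test_roster_yields_empty_profiles_in_order(self, panel):
        profiles = build_profiles(
            [_call(patient_id="P2")], panel, patient_ids=["P1", "P2", "P3"]
        )
        assert [p.patient_id for p in profiles] == ["P1", "P2", "P3"]
        assert profiles[0].n_driver_mutations == 0
        assert profiles[1].n_driver_mutations == 1
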