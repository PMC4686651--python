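"""Filter cascade: per-rule behaviour, Fisher oracle agreement, monotonicity."""

import dataclasses
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import fisher_exact

from clonearch import (
    AlleleCountRecord,
    Detection,
    FilterConfig,
    UnpairedInputError,
    apply_read_filters,
    filter_cascade,
    fisher_somatic_test,
    hec_concordance_pass,
    pass_somatic_filters,
    wga_artifact_filters,
)
from conftest import make_normal, make_record


def brute_force_fisher(a, b, c, d):
    """Independent exhaustive enumeration of the two-sided Fisher p.

    Walks the whole hypergeometric support, accumulating exact rational
    probabilities of every table no more probable than the observed one.
    """
    n1, n2, k = a + b, c + d, a + c
    total = math.comb(n1 + n2, k)
    obs = math.comb(n1, a) * math.comb(n2, k - a)
    acc = Fraction(0)
    for x in range(max(0, k - n2), min(k, n1) + 1):
        w = math.comb(n1, x) * math.comb(n2, k - x)
        if w <= obs:
            acc += Fraction(w, total)
    return float(acc)


class TestFisherSomaticTest:
    @pytest.mark.parametrize("table,expected", [
        ((0, 100, 0, 100), 1.0),
        ((5, 95, 5, 95), 1.0),
    ])
    def test_identical_rows_give_one(self, table, expected):
        assert fisher_somatic_test(*table) == pytest.approx(expected)

    def test_clear_somatic_signal_significant(self):
        assert fisher_somatic_test(10, 90, 0, 100) < 0.01

    def test_all_zero_table_defined_as_one(self):
        with pytest.warns(UserWarning):
            assert fisher_somatic_test(0, 0, 0, 0) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_somatic_test(-1, 5, 5, 5)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_symmetry_under_row_swap(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_somatic_test(a, b, c, d) == pytest.approx(
            fisher_somatic_test(c, d, a, b))

    def test_matches_brute_force_enumeration_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            a, b, c, d = (int(x) for x in rng.integers(0, 50, 4))
            if a + b + c + d == 0:
                continue
            assert fisher_somatic_test(a, b, c, d) == pytest.approx(
                brute_force_fisher(a, b, c, d), rel=1e-10)

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 200, 4))
            if a + b + c + d == 0:
                continue
            assert fisher_somatic_test(a, b, c, d) == pytest.approx(
                fisher_exact([[a, b], [c, d]])[1], rel=1e-6, abs=1e-12)


class TestReadFilters:
    def test_low_base_quality_fails(self, filter_config):
        rec = make_record(mean_base_quality=14.0)
        v = apply_read_filters(rec, filter_config)
        assert not v.passed and v.fired == ["base_quality"]

    def test_strand_bias_20_to_1_fails(self, filter_config):
        rec = make_record(alt_reads=21, fwd_alt_reads=20, rev_alt_reads=1)
        v = apply_read_filters(rec, filter_config)
        assert "strand_bias" in v.fired

    def test_clean_record_passes(self, filter_config):
        rec = make_record(alt_reads=10, fwd_alt_reads=5, rev_alt_reads=5,
                          mean_align_score=60, mean_base_quality=30)
        assert apply_read_filters(rec, filter_config).passed

    def test_boundary_values_use_printed_directions(self, filter_config):
        # "<10", "<15", ">10": exact boundaries pass
        rec = make_record(mean_align_score=10.0, mean_base_quality=15.0,
                          alt_reads=11, fwd_alt_reads=10, rev_alt_reads=1)
        assert apply_read_filters(rec, filter_config).passed


class TestSomaticFilters:
    def test_two_supporting_reads_fail(self, filter_config):
        rec = make_record(alt_reads=2, fwd_alt_reads=1, rev_alt_reads=1)
        v = pass_somatic_filters(rec, make_normal(), filter_config)
        assert "min_supporting_reads" in v.fired

    def test_four_percent_burden_fails(self, filter_config):
        rec = make_record(alt_reads=32, total_reads=800,
                          fwd_alt_reads=16, rev_alt_reads=16)
        v = pass_somatic_filters(rec, make_normal(), filter_config)
        assert "tumour_min_burden" in v.fired

    def test_contaminated_skin_normal_fails(self, filter_config):
        normal = make_normal(alt_reads=200, total_reads=800)  # 25%
        v = pass_somatic_filters(make_record(), normal, filter_config)
        assert "normal_contamination" in v.fired

    def test_tcell_normal_uses_looser_bound(self, filter_config):
        # 25% in a T-cell-paired normal is allowed (<50%), though the
        # Fisher p then decides
        normal = make_normal(alt_reads=200, total_reads=800,
                             source_class="normal_tcell")
        v = pass_somatic_filters(make_record(), normal, filter_config)
        assert "normal_contamination" not in v.fired

    def test_common_population_variant_fails(self, filter_config):
        rec = make_record(pop_known=True, pop_af=0.01)
        v = pass_somatic_filters(rec, make_normal(), filter_config)
        assert "population_variant" in v.fired

    def test_duplicated_region_fails_unless_known(self, filter_config):
        rec = make_record(dup_region=True)
        assert "duplicated_region" in pass_somatic_filters(
            rec, make_normal(), filter_config).fired
        rec2 = make_record(dup_region=True, known_mutation=True)
        assert "duplicated_region" not in pass_somatic_filters(
            rec2, make_normal(), filter_config).fired

    def test_missing_normal_raises(self, filter_config):
        with pytest.raises(UnpairedInputError):
            pass_somatic_filters(make_record(), None, filter_config)

    def test_clean_somatic_variant_passes(self, filter_config):
        v = pass_somatic_filters(make_record(), make_normal(), filter_config)
        assert v.passed


class TestWgaFilters:
    def test_homopolymer_run_of_five_fails(self, filter_config):
        rec = make_record(wga=True, flank_left="TAAAAA")
        v = wga_artifact_filters(rec, filter_config)
        assert v.fired == ["homopolymer"]

    def test_run_of_four_passes(self, filter_config):
        rec = make_record(wga=True, flank_left="TAAAA", flank_right="GTCAGT")
        assert wga_artifact_filters(rec, filter_config).passed

    def test_run_not_adjacent_to_variant_ignored(self, filter_config):
        # the AAAAA run is interrupted before reaching the variant base
        rec = make_record(wga=True, flank_left="AAAAAT", flank_right="GTCAGT")
        assert wga_artifact_filters(rec, filter_config).passed

    def test_control_wga_set_membership_fails(self, filter_config):
        rec = make_record(wga=True)
        v = wga_artifact_filters(rec, filter_config,
                                 control_wga_variant_set={rec.mutation_id})
        assert "wga_control" in v.fired

    def test_bias_flag_fails(self, filter_config):
        rec = make_record(wga=True, bias_flag=True)
        assert "wga_bias" in wga_artifact_filters(rec, filter_config).fired

    def test_missing_flank_raises(self, filter_config):
        rec = make_record(wga=True, flank_left="", flank_right="")
        with pytest.raises(ValueError):
            wga_artifact_filters(rec, filter_config)


class TestHecConcordance:
    def test_wga_hec_plus_independent_nonwga_hec_passes(self, filter_config):
        ev = [
            Detection("mouseA", "s1", "HEC", True, True),
            Detection("mouseB", "s2", "HEC", False, True),
        ]
        assert hec_concordance_pass("m01", ev, filter_config)

    def test_single_wga_hec_alone_fails(self, filter_config):
        ev = [Detection("mouseA", "s1", "HEC", True, True)]
        assert not hec_concordance_pass("m01", ev, filter_config)

    def test_repeat_wga_same_experiment_passes(self, filter_config):
        ev = [
            Detection("mouseA", "wga_kit1", "HEC", True, True),
            Detection("mouseA", "wga_kit2", "HEC", True, True),
        ]
        assert hec_concordance_pass("m01", ev, filter_config)

    def test_wga_hec_plus_nonwga_ltc_passes(self, filter_config):
        ev = [
            Detection("mouseA", "s1", "HEC", True, True),
            Detection("patient", "ltc1", "LTC", False, True),
        ]
        assert hec_concordance_pass("m01", ev, filter_config)

    def test_nonwga_two_hec_samples_pass(self, filter_config):
        ev = [
            Detection("mouseA", "s1", "HEC", False, True),
            Detection("mouseB", "s2", "HEC", False, True),
        ]
        assert hec_concordance_pass("m01", ev, filter_config)

    def test_nonwga_hec_plus_cd34_passes(self, filter_config):
        ev = [
            Detection("mouseA", "s1", "HEC", False, True),
            Detection("patient", "bm", "CD34", False, True),
        ]
        assert hec_concordance_pass("m01", ev, filter_config)

    def test_mds3_like_requires_two_of_three_animals(self, filter_config):
        one_animal = [
            Detection("mouseA", "kit1", "HEC", True, True),
            Detection("mouseA", "kit2", "HEC", True, True),
            Detection("mouseB", "kit1", "HEC", True, False),
            Detection("mouseC", "kit1", "HEC", True, False),
        ]
        assert not hec_concordance_pass("m01", one_animal, filter_config,
                                        mds3_like=True)
        two_animals = [
            Detection("mouseA", "kit1", "HEC", True, True),
            Detection("mouseB", "kit1", "HEC", True, True),
        ]
        assert hec_concordance_pass("m01", two_animals, filter_config,
                                    mds3_like=True)

    def test_empty_evidence_rejected(self, filter_config):
        with pytest.raises(ValueError):
            hec_concordance_pass("m01", [], filter_config)


class TestFilterCascade:
    def test_empty_input(self, filter_config):
        passed, log = filter_cascade([], filter_config)
        assert passed == [] and log == []

    def test_pass_set_matches_empty_fired_lists(self, filter_config):
        records = [
            make_record(mutation_id="m01"),
            make_record(mutation_id="m02", alt_reads=2,
                        fwd_alt_reads=1, rev_alt_reads=1),
        ]
        normals = {"m01": make_normal(mutation_id="m01"),
                   "m02": make_normal(mutation_id="m02")}
        passed, log = filter_cascade(records, filter_config, normals=normals)
        assert [v.passed for v in log] == [True, False]
        assert passed == [records[0]]

    def test_unpaired_normal_logged_not_raised(self, filter_config):
        passed, log = filter_cascade([make_record()], filter_config, normals={})
        assert passed == [] and log[0].fired == ["unpaired_normal"]

    def test_order_independence(self, filter_config):
        records = [make_record(mutation_id=f"m{i:02d}", alt_reads=a,
                               fwd_alt_reads=a // 2, rev_alt_reads=a - a // 2)
                   for i, a in enumerate([368, 2, 50, 700], start=1)]
        normals = {r.mutation_id: make_normal(mutation_id=r.mutation_id)
                   for r in records}
        _, log_fwd = filter_cascade(records, filter_config, normals=normals)
        _, log_rev = filter_cascade(records[::-1], filter_config, normals=normals)
        fwd = {v.record.mutation_id: v.fired for v in log_fwd}
        rev = {v.record.mutation_id: v.fired for v in log_rev}
        assert fwd == rev

    @pytest.mark.parametrize("field,stricter", [
        ("somatic_p_max", 0.001),
        ("min_supporting_reads", 10),
        ("tumour_min_burden", 0.20),
        ("normal_max_fraction_skin", 0.05),
        ("max_fold_strand_bias", 2),
        ("pop_af_max", 0.0),
    ])
    def test_monotone_under_threshold_tightening(self, filter_config, field, stricter):
        rng = np.random.default_rng(2)
        records, normals = [], {}
        for i in range(40):
            alt = int(rng.integers(0, 400))
            fwd = int(rng.integers(0, alt + 1))
            rec = make_record(mutation_id=f"m{i:02d}", alt_reads=alt,
                              fwd_alt_reads=fwd, rev_alt_reads=alt - fwd,
                              pop_known=bool(rng.random() < 0.3),
                              pop_af=float(rng.random() * 0.01))
            records.append(rec)
            normals[rec.mutation_id] = make_normal(
                mutation_id=rec.mutation_id,
                alt_reads=int(rng.integers(0, 300)))
        loose, _ = filter_cascade(records, filter_config, normals=normals)
        tight_cfg = dataclasses.replace(filter_config, **{field: stricter})
        tight, _ = filter_cascade(records, tight_cfg, normals=normals)
        assert {r.mutation_id for r in tight} <= {r.mutation_id for r in loose}
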