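"""Literature pooling: median/range conversion, fixed-effect weighting,
population-target composition, and pooled-SE calibration."""
import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from norwoodlpn import meta, synth
from norwoodlpn.meta import (InvalidRecordError, NoDataError, StudyRecord,
                             build_population_targets,
                             estimate_mean_sd_from_median_range,
                             load_study_table, packaged_table,
                             pooled_fixed_effect)


def rec(m, sd, n, param="mean_pa_pressure", stage="pre_s2", sid="s"):
    form = "mean_sd" if sd is not None else "mean_only"
    return StudyRecord(f"{sid}{m}{n}", param, stage, n, form, m, sd)


class TestMedianRangeConversion:
    @pytest.mark.parametrize(
        "median, lo, hi, n, mean, sd",
        [
            (14, 13, 17, 170, 14.5, 4 / 6),     # large-n rule: range/6
            (15, 8, 22, 78, 15.0, 14 / 6),
            (40, 20, 57, 78, 39.25, 37 / 6),
            (11, 8, 16, 22, 11.5, 8 / 4),       # mid-n rule: range/4
            # small-n rule: full range-based variance formula
            (14, 14, 17, 10, 14.75,
             math.sqrt(((14 - 28 + 17) ** 2 / 4 + 9) / 12)),
        ],
    )
    def test_size_stratified_rules(self, median, lo, hi, n, mean, sd):
        m, s = estimate_mean_sd_from_median_range(median, lo, hi, n)
        assert m == pytest.approx(mean, abs=1e-12)
        assert s == pytest.approx(sd, rel=1e-12)

    @given(x=st.floats(-100, 100), n=st.integers(1, 500))
    def test_degenerate_zero_width_range(self, x, n):
        m, s = estimate_mean_sd_from_median_range(x, x, x, n)
        assert m == x and s == 0.0

    def test_ordering_violation_rejected(self):
        with pytest.raises(InvalidRecordError):
            estimate_mean_sd_from_median_range(5, 6, 10, 20)

    def test_quantile_method_close_to_size_stratified(self):
        m1, s1 = estimate_mean_sd_from_median_range(15, 8, 22, 78)
        m2, s2 = estimate_mean_sd_from_median_range(15, 8, 22, 78, method="quantile")
        assert m1 == m2
        assert s2 == pytest.approx(s1, rel=0.35)


class TestFixedEffectPooling:
    def test_identical_means_pool_exactly(self):
        est = pooled_fixed_effect([rec(1.7, 1.0, 24, "qp_qs", "post_s1"),
                                   rec(1.7, 0.9, 117, "qp_qs", "post_s1")])
        assert est.pooled_mean == pytest.approx(1.7, abs=1e-12)

    def test_single_record_identity(self):
        est = pooled_fixed_effect([rec(42.0, 3.0, 50)])
        assert est.pooled_mean == 42.0
        assert est.pooled_se == pytest.approx(3.0 / math.sqrt(50))

    @pytest.mark.parametrize("weighting", ["inverse_sd2", "inverse_se2", "n"])
    def test_equal_weight_symmetry(self, weighting):
        est = pooled_fixed_effect(
            [rec(10.0, 2.0, 100), rec(20.0, 2.0, 100)], weighting=weighting)
        assert est.pooled_mean == pytest.approx(15.0, abs=1e-12)

    def test_matches_statsmodels_fixed_effect(self):
        from statsmodels.stats.meta_analysis import combine_effects

        recs = [rec(14.5, 0.67, 170), rec(15.0, 2.33, 78), rec(16.6, 3.74, 10)]
        est = pooled_fixed_effect(recs, weighting="inverse_se2")
        effects = np.array([r.center for r in recs])
        variances = np.array([r.dispersion**2 / r.n for r in recs])
        sm = combine_effects(effects, variances)
        assert est.pooled_mean == pytest.approx(sm.mean_effect_fe, rel=1e-10)

    @given(st.lists(
        st.tuples(st.floats(1, 100), st.floats(0.1, 10), st.integers(2, 200)),
        min_size=1, max_size=8))
    def test_permutation_and_scale_invariance(self, entries):
        recs = [rec(m, sd, n, sid=f"r{i}") for i, (m, sd, n) in enumerate(entries)]
        est = pooled_fixed_effect(recs)
        perm = pooled_fixed_effect(list(reversed(recs)))
        assert perm.pooled_mean == pytest.approx(est.pooled_mean, rel=1e-12)
        k = 3.5
        scaled = [rec(m * k, sd * k, n, sid=f"r{i}")
                  for i, (m, sd, n) in enumerate(entries)]
        est_k = pooled_fixed_effect(scaled)
        assert est_k.pooled_mean == pytest.approx(k * est.pooled_mean, rel=1e-9)
        means = [r.center for r in recs]
        assert min(means) - 1e-9 <= est.pooled_mean <= max(means) + 1e-9

    @given(st.lists(
        st.tuples(st.floats(1, 100), st.floats(0.1, 10), st.integers(2, 200)),
        min_size=2, max_size=8))
    def test_se_shrinks_with_more_records(self, entries):
        recs = [rec(m, sd, n, sid=f"r{i}") for i, (m, sd, n) in enumerate(entries)]
        partial = pooled_fixed_effect(recs[:-1], weighting="inverse_se2")
        full = pooled_fixed_effect(recs, weighting="inverse_se2")
        assert full.pooled_se <= partial.pooled_se + 1e-12

    def test_empty_pool_rejected(self):
        with pytest.raises(NoDataError):
            pooled_fixed_effect([])

    def test_zero_sd_floored(self):
        est = pooled_fixed_effect([rec(10.0, 0.0, 30), rec(12.0, 1.0, 30)])
        assert "floored" in est.method_notes
        assert np.isfinite(est.pooled_mean)

    def test_missing_dispersion_falls_back_to_sample_size(self):
        recs = [StudyRecord("a", "mean_pressure", "post_s1", 37, "value_only", 47.0),
                rec(51.0, 6.0, 117, "mean_pressure", "post_s1"),
                StudyRecord("b", "mean_pressure", "post_s1", 20, "value_only", 52.3)]
        est = pooled_fixed_effect(recs)
        expected = (37 * 47 + 117 * 51 + 20 * 52.3) / 174
        assert est.pooled_mean == pytest.approx(expected, rel=1e-12)
        assert "sample-size" in est.method_notes

    def test_parameter_recovery_500_replicates(self):
        """|pooled - mu| <= 3 pooled_se in >= 99% of seeded tables."""
        hits = 0
        n_rep = 500
        for seed in range(n_rep):
            spec = synth.SyntheticStudySpec(seed=seed)
            est = pooled_fixed_effect(synth.generate_study_table(spec))
            hits += abs(est.pooled_mean - spec.true_mean) <= 3 * est.pooled_se
        assert hits / n_rep >= 0.99


class TestPopulationTargets:
    def test_bsa_pools_to_031(self):
        t3 = packaged_table("table3")
        est = pooled_fixed_effect([r for r in t3 if r.parameter == "bsa"])
        assert round(est.pooled_mean, 2) == 0.31

    def test_cardiac_output_composition_two_sig_figs(self):
        pop = meta.default_targets("pre_s2")
        assert f"{pop['cardiac_output']:.2g}" == "1.7"

    def test_post_s1_cardiac_output_uses_pooled_bsa(self):
        pop = meta.default_targets("post_s1")
        assert pop["bsa"] == pytest.approx(0.23)
        assert pop["cardiac_output"] == pytest.approx(5.5 * 0.23, rel=1e-9)

    def test_mean_pressure_composed_when_absent(self):
        pop = meta.default_targets("pre_s2")
        expected = (pop["systolic_pressure"] + 2 * pop["diastolic_pressure"]) / 3
        assert pop["mean_pressure"] == pytest.approx(expected, rel=1e-12)

    def test_empty_table_yields_no_targets(self):
        t = build_population_targets([], "post_s1")
        assert t.values == {}

    def test_tolerances_attached(self):
        pop = meta.default_targets("pre_s2")
        assert pop.tolerance("cardiac_output") == 0.05
        assert pop.tolerance("mean_pressure") == 0.10


class TestStudyTableIO:
    def test_packaged_tables_parse_to_frozen_counts(self):
        assert len(packaged_table("table2")) == 31
        assert len(packaged_table("table3")) == 42

    def test_round_trip_bit_identical(self):
        recs = synth.generate_study_table(synth.SyntheticStudySpec(seed=3))
        buf = io.StringIO()
        meta.write_study_csv(recs, buf)
        buf.seek(0)
        back = load_study_table(buf)
        assert back == recs

    def test_malformed_row_reports_line_number(self):
        csv = (
            "study_id,parameter,stage,n,value_form,center,dispersion,"
            "range_low,range_high\n"
            "ok,qp_qs,post_s1,10,mean_sd,1.5,0.3,,\n"
            "bad,qp_qs,post_s1,10,median_range,1.5,,2.0,1.0\n"
        )
        with pytest.raises(InvalidRecordError, match="line 3"):
            load_study_table(io.StringIO(csv))

    def test_unknown_parameter_lists_vocabulary(self):
        with pytest.raises(InvalidRecordError, match="known"):
            StudyRecord("x", "not_a_parameter", "post_s1", 5, "mean_only", 1.0)
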