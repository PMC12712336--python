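import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicevo.errors import MeasurementError, UnscorableSpecimenError
from mimicevo.simulate import synthesize_measurements
from mimicevo.traits import (
    CATEGORIES,
    ILLUSION_SCORES,
    TRAIT_NAMES,
    AccuracyRecord,
    SpecimenMeasurements,
    TraitScores,
    classify_accuracy,
    cohort_summary,
    make_record,
    overall_accuracy,
    read_measurements,
    score_table,
    score_traits,
)


def full_measurements(**overrides) -> SpecimenMeasurements:
    base = dict(
        specimen_id="s1",
        femur3_length=1.0,
        femur3_width=0.25,
        ceph_width=0.8,
        ceph_length=1.2,
        abd_width=0.9,
        abd_length=1.5,
        pedicel_length=0.1,
        ceph_width_constr=0.8,
        ceph_height_constr=0.5,
        ceph_height_max=0.5,
        abd_width_constr=0.9,
        abd_height_constr=0.6,
        abd_height_max=0.6,
        illusion_flags=(False, False, False),
    )
    base.update(overrides)
    return SpecimenMeasurements(**base)


class TestScoreTraits:
    def test_thin_legs_ratio(self):
        s = score_traits(full_measurements(femur3_length=1.0, femur3_width=0.25))
        assert s.thin_legs == pytest.approx(0.75)

    def test_two_illusion_flags(self):
        s = score_traits(full_measurements(illusion_flags=(True, True, False)))
        assert s.illusion_coloration == 0.667

    @pytest.mark.parametrize("n,expected", [(0, 0.0), (1, 0.334), (2, 0.667), (3, 1.0)])
    def test_illusion_values(self, n, expected):
        flags = tuple(i < n for i in range(3))
        s = score_traits(full_measurements(illusion_flags=flags))
        assert s.illusion_coloration == expected

    def test_no_constriction_scores_zero(self):
        s = score_traits(full_measurements(ceph_width_constr=0.8, ceph_width=0.8))
        assert s.constr_ceph_dors == 0.0

    def test_missing_constriction_scores_zero(self):
        s = score_traits(full_measurements(ceph_width_constr=None, abd_height_constr=None))
        assert s.constr_ceph_dors == 0.0
        assert s.constr_abd_lat == 0.0

    def test_pedicel_uses_total_body_length(self):
        s = score_traits(full_measurements(ceph_length=1.0, abd_length=1.0, pedicel_length=0.5))
        assert s.elong_pedicel == pytest.approx(0.5 / 2.5)

    def test_negative_ratio_clamped_to_zero(self):
        # abdomen wider than long
        s = score_traits(full_measurements(abd_width=2.0, abd_length=1.0))
        assert s.elong_abd == 0.0

    def test_nonpositive_measurement_rejected_naming_field(self):
        with pytest.raises(MeasurementError, match="femur3_length"):
            full_measurements(femur3_length=-1.0)
        with pytest.raises(MeasurementError, match="ceph_length"):
            full_measurements(ceph_length=0.0)

    def test_missing_required_measurement_unscorable(self):
        with pytest.raises(UnscorableSpecimenError, match="thin_legs"):
            score_traits(full_measurements(femur3_width=None))

    def test_allow_partial_gives_none_scores(self):
        s = score_traits(full_measurements(femur3_width=None), allow_partial=True)
        assert s.thin_legs is None
        assert not s.complete

    def test_wrong_flag_count_rejected(self):
        with pytest.raises(MeasurementError):
            full_measurements(illusion_flags=(True, False))

    @given(
        st.lists(
            st.floats(min_value=0.01, max_value=100.0, allow_nan=False),
            min_size=13,
            max_size=13,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_clamping_property(self, vals):
        m = SpecimenMeasurements(
            "h", *vals, illusion_flags=(False, True, False)
        )
        s = score_traits(m)
        arr = s.as_array()
        assert np.all(arr >= 0.0) and np.all(arr <= 1.0)


class TestOverallAccuracy:
    def test_all_zero(self):
        s = TraitScores(*([0.0] * 9))
        assert overall_accuracy(s) == 0.0

    def test_constant(self):
        s = TraitScores(*([0.3] * 9))
        assert overall_accuracy(s) == pytest.approx(0.3)

    def test_sum_divided_by_nine(self):
        vals = [0.5, 0.4, 0.3, 0.2, 0.1, 0.4, 0.3, 0.2, 0.334]
        s = TraitScores(*vals)
        assert overall_accuracy(s) == pytest.approx(sum(vals) / 9)

    def test_incomplete_raises_without_flag(self):
        s = TraitScores(0.5, None, *([0.1] * 7))
        with pytest.raises(UnscorableSpecimenError):
            overall_accuracy(s)
        assert overall_accuracy(s, allow_partial=True) == pytest.approx(
            np.mean([0.5] + [0.1] * 7)
        )


class TestClassify:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.10, "nonmimic"),
            (0.1499, "nonmimic"),
            (0.15, "inaccurate_low"),
            (0.19, "inaccurate_low"),
            (0.20, "inaccurate_moderate"),
            (0.29, "inaccurate_moderate"),
            (0.299, "inaccurate_moderate"),
            (0.30, "accurate"),
            (0.47, "accurate"),
        ],
    )
    def test_thresholds(self, x, expected):
        assert classify_accuracy(x) == expected

    def test_rounding_at_subbin_boundary(self):
        # 0.1951 prints as 0.20 -> moderate bin
        assert classify_accuracy(0.1951) == "inaccurate_moderate"
        assert classify_accuracy(0.1949) == "inaccurate_low"

    @pytest.mark.parametrize("x", [-0.01, 1.01, math.nan])
    def test_domain_errors(self, x):
        with pytest.raises(ValueError):
            classify_accuracy(x)

    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    @settings(max_examples=300, deadline=None)
    def test_partition_property(self, x):
        cat = classify_accuracy(x)
        assert cat in CATEGORIES
        # exactly one outer bin
        assert (x < 0.15) == (cat == "nonmimic")
        assert (x >= 0.30) == (cat == "accurate")


RATIO_TRAITS = [n for n in TRAIT_NAMES if n != "illusion_coloration"]


class TestRoundTrip:
    @given(
        st.lists(st.floats(min_value=0.0, max_value=0.999), min_size=8, max_size=8),
        st.sampled_from(ILLUSION_SCORES),
    )
    @settings(max_examples=150, deadline=None)
    def test_synthesize_then_score(self, ratios, illusion):
        targets = dict(zip(RATIO_TRAITS, ratios))
        targets["illusion_coloration"] = illusion
        m = synthesize_measurements(targets, seed=0)
        s = score_traits(m)
        for name in RATIO_TRAITS:
            assert s.as_dict()[name] == pytest.approx(targets[name], abs=1e-12)
        assert s.illusion_coloration == illusion

    def test_scale_noise_preserves_scores(self):
        targets = {n: 0.25 for n in RATIO_TRAITS}
        targets["illusion_coloration"] = 0.334
        m = synthesize_measurements(targets, seed=3, scale_noise=True)
        s = score_traits(m)
        for name in RATIO_TRAITS:
            assert s.as_dict()[name] == pytest.approx(0.25, abs=1e-12)


def _random_records(n, rng):
    records = []
    for i in range(n):
        targets = dict(zip(RATIO_TRAITS, rng.uniform(0, 0.9, size=8)))
        targets["illusion_coloration"] = ILLUSION_SCORES[rng.integers(4)]
        s = score_traits(synthesize_measurements(targets, specimen_id=f"s{i}"))
        records.append((s, make_record(f"s{i}", s)))
    return records


class TestCohortSummary:
    def test_against_brute_force(self):
        rng = np.random.default_rng(0)
        records = _random_records(25, rng)
        summary = cohort_summary(records, "clade")
        raw = np.vstack([s.as_array() for s, _ in records])
        acc = np.array([r.overall_accuracy for _, r in records])
        data = np.column_stack([raw, acc])
        assert np.allclose(summary.stats["min"], data.min(axis=0))
        assert np.allclose(summary.stats["max"], data.max(axis=0))
        assert np.allclose(summary.stats["mean"], data.mean(axis=0))
        assert np.allclose(summary.stats["sd"], data.std(axis=0, ddof=1))
        assert sum(summary.category_counts.values()) == 25

    def test_two_identical_records(self):
        rng = np.random.default_rng(1)
        (s, r), = _random_records(1, rng)
        summary = cohort_summary([(s, r), (s, r)])
        assert np.allclose(summary.stats["min"], summary.stats["max"])
        assert np.allclose(summary.stats["sd"], 0.0)

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cohort_summary([])

    def test_single_record_warns_sd_zero(self):
        rng = np.random.default_rng(2)
        records = _random_records(1, rng)
        with pytest.warns(UserWarning, match="single-record"):
            summary = cohort_summary(records)
        assert np.allclose(summary.stats["sd"], 0.0)

    def test_constriction_counts_both_conventions(self):
        rng = np.random.default_rng(3)
        records = _random_records(40, rng)
        summary = cohort_summary(records)
        per_region = summary.constriction_counts
        assert summary.n_with_any_constriction <= sum(per_region.values())
        assert summary.n_with_any_constriction >= max(per_region.values())


class TestTabularIO:
    def test_read_score_roundtrip(self, tmp_path):
        path = tmp_path / "meas.csv"
        path.write_text(
            "specimen_id,clade,femur3_length,femur3_width,ceph_width,ceph_length,"
            "abd_width,abd_length,pedicel_length,ceph_height_max,abd_height_max,"
            "band_abdomen,band_cephalothorax,eye_darkening\n"
            "sp1,CladeA,1.0,0.25,0.8,1.2,0.9,1.5,0.1,0.5,0.6,1,1,0\n"
            "sp2,CladeA,1.0,0.40,0.9,1.0,0.8,1.2,0.05,0.4,0.5,false,false,false\n"
        )
        ms = read_measurements(str(path))
        assert [m.specimen_id for m in ms] == ["sp1", "sp2"]
        assert ms[0].illusion_flags == (True, True, False)
        df = score_table(ms)
        assert list(df["specimen_id"]) == ["sp1", "sp2"]
        assert df.loc[0, "thin_legs"] == pytest.approx(0.75)
        assert df.loc[0, "illusion_coloration"] == 0.667
        assert set(df["category"]).issubset(set(CATEGORIES))

    def test_tab_separated_accepted(self, tmp_path):
        path = tmp_path / "meas.tsv"
        path.write_text(
            "specimen_id\tfemur3_length\tfemur3_width\tceph_width\tceph_length\t"
            "abd_width\tabd_length\tpedicel_length\n"
            "sp1\t1.0\t0.25\t0.8\t1.2\t0.9\t1.5\t0.1\n"
        )
        ms = read_measurements(str(path))
        assert ms[0].femur3_width == 0.25
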