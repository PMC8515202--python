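"""Synthetic cohort generator: shapes, curves, onsets, reproducibility."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import hdprogression as h
from hdprogression import ConfigurationError


def small_config(**kw):
    defaults = dict(n_per_group={"HC": 10, "PreHD": 10, "HD": 10}, seed=1)
    defaults.update(kw)
    return h.GeneratorConfig(**defaults)


class TestLogisticCurve:
    spec = h.RegionSpec("toy", -1, change_time=-2.0, magnitude=0.2, steepness=0.8,
                        floor=0.1)

    def test_half_height_at_change_time(self):
        assert h.logistic_curve(-2.0, self.spec) == pytest.approx(0.1 - 0.1)

    def test_three_quarters_at_ln3_over_k(self):
        t = -2.0 + math.log(3) / 0.8
        assert h.logistic_curve(t, self.spec) == pytest.approx(0.1 - 0.75 * 0.2)

    def test_floor_asymptote(self):
        assert h.logistic_curve(-1e6, self.spec) == pytest.approx(0.1, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-30, 30), st.floats(-30, 30))
    def test_monotone_in_disease_direction(self, t1, t2):
        # direction -1: value decreases as disease time increases
        lo, hi = sorted([t1, t2])
        assert h.logistic_curve(hi, self.spec) <= h.logistic_curve(lo, self.spec) + 1e-12


class TestGenerateCohort:
    def test_row_and_truth_counts(self):
        cohort, truths = h.generate_cohort(small_config())
        assert len(cohort) == 30 * 3
        assert len(truths) == 30
        assert set(cohort["visit_index"]) == {0, 1, 2}

    def test_noiseless_values_lie_on_group_logistic(self):
        cfg = small_config(
            noise_sd=0.0, intercept_sd=0.0,
            pre_shift_range=(-3.0, -3.0), hd_shift_range=(2.0, 2.0),
            age_effect=0.0, sex_effect=0.0, tiv_effect=0.0,
            site_effects={"siteA": 0.0, "siteB": 0.0, "siteC": 0.0},
        )
        cohort, truths = h.generate_cohort(cfg)
        truth = {t.subject_id: t for t in truths}
        for _, row in cohort[cohort["group"] != "HC"].iterrows():
            t = truth[row["subject_id"]].time_shift + row["visit_index"] * 1.0
            for spec in cfg.regions:
                expected = spec.mean_volume * (1.0 + h.logistic_curve(t, spec))
                assert row[spec.name] == pytest.approx(expected, rel=1e-12)

    def test_hc_values_flat_without_noise(self):
        cfg = small_config(noise_sd=0.0, intercept_sd=0.0, age_effect=0.0)
        cohort, _ = h.generate_cohort(cfg)
        hc = cohort[cohort["group"] == "HC"]
        for name, g in hc.groupby("subject_id"):
            assert g["caudate"].nunique() == 1

    def test_seed_reproducibility_and_difference(self):
        c1, _ = h.generate_cohort(small_config(seed=1))
        c2, _ = h.generate_cohort(small_config(seed=1))
        c3, _ = h.generate_cohort(small_config(seed=2))
        pd.testing.assert_frame_equal(c1, c2)
        assert not c1["caudate"].equals(c3["caudate"])

    def test_noise_scale_recovered_from_repeat_residuals(self):
        # HC repeated visits scatter around a flat truth with the configured
        # noise SD (in raw units: scale * noise_sd); n large enough for 3 SE
        cfg = h.GeneratorConfig(
            n_per_group={"HC": 400, "PreHD": 0, "HD": 0}, seed=9,
            intercept_sd=0.0, age_effect=0.0,
        )
        cohort, _ = h.generate_cohort(cfg)
        spec = cfg.regions[0]
        scale = spec.mean_volume * spec.hc_cv / cfg.noise_sd  # sigma_tot = noise
        resid = cohort.groupby("subject_id")["caudate"].transform(
            lambda v: v - v.mean()
        )
        n = len(resid)
        sd = resid.std() * math.sqrt(n / (n - 400))  # within-subject dof correction
        se = sd / math.sqrt(2 * n)
        assert abs(sd - scale * cfg.noise_sd) < 3 * se + 1e-3

    def test_exactly_one_enlarging_region_by_default(self):
        dirs = [r.direction for r in h.DEFAULT_REGIONS]
        assert dirs.count(+1) == 1
        assert h.DEFAULT_REGIONS[[r.name for r in h.DEFAULT_REGIONS].index(
            "lateral_ventricles")].direction == +1

    def test_gauge_identity_shifted_change_times(self):
        # translating the whole timeline — the same constant added to every
        # shift and every change time — reproduces the table bit-for-bit
        # (the time origin is a pure gauge choice)
        c = 1.7
        cfg1 = small_config(pre_shift_range=(-4.0, -1.0), hd_shift_range=(0.5, 2.0))
        regions2 = tuple(
            dataclasses.replace(r, change_time=r.change_time + c) for r in cfg1.regions
        )
        cfg2 = small_config(
            regions=regions2,
            pre_shift_range=(-4.0 + c, -1.0 + c), hd_shift_range=(0.5 + c, 2.0 + c),
        )
        c1, _ = h.generate_cohort(cfg1)
        c2, _ = h.generate_cohort(cfg2)
        region_cols = [r.name for r in cfg1.regions]
        pd.testing.assert_frame_equal(c1[region_cols], c2[region_cols])


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw, field",
        [
            ({"noise_sd": -0.1}, "noise_sd"),
            ({"intercept_sd": -1.0}, "intercept_sd"),
            ({"regions": ()}, "regions"),
            ({"n_visits": 0}, "n_visits"),
            ({"missing_rate": 1.5}, "missing_rate"),
        ],
    )
    def test_invalid_config_names_field(self, kw, field):
        with pytest.raises(ConfigurationError, match=field):
            small_config(**kw)

    def test_invalid_region_spec(self):
        with pytest.raises(ConfigurationError, match="magnitude"):
            h.RegionSpec("x", -1, 0.0, -0.1, 1.0)
        with pytest.raises(ConfigurationError, match="steepness"):
            h.RegionSpec("x", -1, 0.0, 0.1, 0.0)


class TestOnsets:
    def test_onset_age_arithmetic(self):
        tr = h.SubjectTruth("s", "PreHD", time_shift=-3.0, random_intercept=0.0,
                            baseline_age=40.0, sex="F", site="a",
                            field_strength="3T", tiv=1400.0, cag=42)
        out = h.assign_onsets([tr], window=5.0)[0]
        assert out.onset_age == pytest.approx(43.0)

    def test_onset_at_baseline_when_shift_zero(self):
        tr = h.SubjectTruth("s", "HD", 0.0, 0.0, 55.0, "M", "a", "3T", 1500.0, 45)
        assert h.assign_onsets([tr], window=2.0)[0].onset_age == pytest.approx(55.0)

    def test_no_converters_when_window_too_short(self):
        trs = [
            h.SubjectTruth(f"s{i}", "PreHD", -12.0, 0.0, 40.0, "F", "a", "3T",
                           1400.0, 42)
            for i in range(3)
        ]
        assert all(t.onset_age is None for t in h.assign_onsets(trs, window=2.0))

    def test_censored_time_rounds_up_to_next_visit(self):
        tr = h.SubjectTruth("s", "PreHD", -2.3, 0.0, 40.0, "F", "a", "3T", 1400.0, 42)
        assert h.censored_time_to_onset(tr, 1.0, horizon=15.0) == pytest.approx(3.0)
        hd = h.SubjectTruth("s", "HD", 1.0, 0.0, 40.0, "F", "a", "3T", 1400.0, 42)
        assert h.censored_time_to_onset(hd, 1.0) == 0.0
        hc = h.SubjectTruth("s", "HC", 0.0, 0.0, 40.0, "F", "a", "3T", 1400.0, None)
        assert h.censored_time_to_onset(hc, 1.0) is None


class TestIO:
    def test_cohort_and_truth_roundtrip(self, tmp_path):
        cfg = small_config()
        cohort, truths = h.generate_cohort(cfg)
        h.simulate.write_cohort(cohort, tmp_path / "c.csv")
        h.simulate.write_truths(truths, tmp_path / "t.csv")
        c2 = h.simulate.read_cohort(tmp_path / "c.csv")
        t2 = h.simulate.read_truths(tmp_path / "t.csv")
        assert np.allclose(c2["caudate"], cohort["caudate"])
        assert [t.subject_id for t in t2] == [t.subject_id for t in truths]
        assert t2[0].cag == truths[0].cag

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = small_config(noise_sd=0.17)
        h.simulate.config_to_yaml(cfg, tmp_path / "cfg.yaml")
        cfg2 = h.simulate.config_from_yaml(tmp_path / "cfg.yaml")
        assert cfg2 == cfg
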