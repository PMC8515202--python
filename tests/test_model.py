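"""Progression-model fitting: recovery, monotonicity, sampling, CV, IO."""

import copy

import numpy as np
import pandas as pd
import pytest

import hdprogression as h
from hdprogression.exceptions import FitError
from hdprogression.model import MONOTONE_TOL


def small_gene_positive(seed=3, **gen_kw):
    gen_kw.setdefault("n_per_group", {"HC": 30, "PreHD": 30, "HD": 15})
    cfg = h.GeneratorConfig(seed=seed, **gen_kw)
    cohort, truths = h.generate_cohort(cfg)
    dirs = {r.name: r.direction for r in cfg.regions}
    adj = h.apply_adjustment(cohort, h.fit_adjustment(cohort), dirs)
    gp = adj.subset([t.subject_id for t in truths if t.group != "HC"])
    return gp, truths, cfg


class TestFit:
    def test_noiseless_zero_shift_cohort_recovers_near_zero_shifts(self):
        gp, truths, _ = small_gene_positive(
            seed=5, noise_sd=0.0, intercept_sd=0.0,
            pre_shift_range=(0.0, 0.0), hd_shift_range=(0.0, 0.0),
        )
        m = h.fit(gp, h.ModelConfig(seed=1, n_basis=10, n_outer=10))
        assert np.all(np.abs(m.shifts) < 0.25)

    def test_shift_recovery_on_noisy_cohort(self, fitted, true_shifts):
        true = np.array([true_shifts[s] for s in fitted.subject_ids])
        r = np.corrcoef(true, fitted.shifts)[0, 1]
        assert r > 0.9
        err = fitted.shifts - (true - true.mean())
        assert np.median(np.abs(err)) < 1.5

    def test_training_shifts_average_zero(self, fitted):
        assert abs(fitted.shifts.mean()) < 1e-9

    def test_noise_sd_recovered_within_20_percent(self, fitted, gen_config):
        truth = gen_config.noise_sd / np.hypot(
            gen_config.noise_sd, gen_config.intercept_sd
        )
        assert np.all(np.abs(fitted.sigma / truth - 1.0) < 0.2)

    def test_elbo_nondecreasing(self, fitted):
        assert np.all(np.diff(fitted.elbo_trace) >= -1e-6)

    def test_subject_relabeling_is_pure_renaming(self, gene_positive,
                                                 model_config, fitted):
        renamed = copy.deepcopy(gene_positive)
        mapping = {s: f"X{s}" for s in renamed.data["subject_id"].unique()}
        renamed.data["subject_id"] = renamed.data["subject_id"].map(mapping)
        m2 = h.fit(renamed, model_config)
        assert np.allclose(m2.weight_mean, fitted.weight_mean, atol=1e-10)
        assert np.allclose(m2.shifts, fitted.shifts, atol=1e-10)
        assert m2.subject_ids == [mapping[s] for s in fitted.subject_ids]

    def test_single_visit_data_rejected(self, gene_positive, model_config):
        single = copy.deepcopy(gene_positive)
        single.data = single.data[single.data["visit_index"] == 0].reset_index(
            drop=True
        )
        with pytest.raises(FitError, match="single visit"):
            h.fit(single, model_config)

    def test_hc_only_data_yields_flat_trajectories(self, adjusted, cohort_truths,
                                                   gen_config, model_config):
        _, truths = cohort_truths
        hc = adjusted.subset([t.subject_id for t in truths if t.group == "HC"])
        m = h.fit(hc, model_config)
        lo, hi = m.support
        grid = np.linspace(lo, hi, 50)
        noise_sd = gen_config.noise_sd / np.hypot(
            gen_config.noise_sd, gen_config.intercept_sd
        )
        for r in m.regions:
            curve = m.predict_mean(r, grid)
            assert curve.max() - curve.min() < 2 * noise_sd


class TestPrediction:
    def test_monotone_mean_curves(self, fitted):
        grid = fitted.support_grid(0.05)
        for r in fitted.regions:
            diffs = np.diff(fitted.predict_mean(r, grid))
            assert diffs.min() > -MONOTONE_TOL

    def test_grid_refinement_agrees_at_shared_points(self, fitted):
        lo, hi = fitted.support
        coarse = np.linspace(lo, hi, 51)
        fine = np.linspace(lo, hi, 101)
        c1 = fitted.predict_mean("caudate", coarse)
        c2 = fitted.predict_mean("caudate", fine)[::2]
        assert np.allclose(c1, c2, atol=1e-8)

    def test_unknown_region_raises(self, fitted):
        with pytest.raises(KeyError, match="unknown region"):
            fitted.predict_mean("amygdala", np.array([0.0]))

    def test_out_of_domain_grid_raises(self, fitted):
        lo, hi = fitted.domain
        with pytest.raises(ValueError, match="outside fitted domain"):
            fitted.predict_mean("caudate", np.array([hi + 5.0]))


class TestSampling:
    def test_seeded_samples_reproducible(self, fitted):
        grid = fitted.support_grid(0.1)
        s1 = h.sample_posterior(fitted, "caudate", grid, 20, seed=3)
        s2 = h.sample_posterior(fitted, "caudate", grid, 20, seed=3)
        s3 = h.sample_posterior(fitted, "caudate", grid, 20, seed=4)
        assert np.array_equal(s1.curves, s2.curves)
        assert not np.array_equal(s1.curves, s3.curves)

    def test_single_sample_is_monotone_within_tolerance(self, fitted):
        grid = fitted.support_grid(0.05)
        ss = h.sample_posterior(fitted, "putamen", grid, 1, seed=0)
        assert ss.curves.shape == (1, len(grid))
        assert np.diff(ss.curves[0]).min() > -MONOTONE_TOL

    def test_sample_mean_consistent_with_posterior_mean(self, fitted):
        grid = fitted.support_grid(0.25)
        ss = h.sample_posterior(fitted, "caudate", grid, 200, seed=9)
        mean_curve = fitted.predict_mean("caudate", grid)
        se = ss.curves.std(axis=0, ddof=1) / np.sqrt(200)
        # small positive slack covers the monotone-projection bias
        assert np.all(np.abs(ss.curves.mean(axis=0) - mean_curve) < 3 * se + 5e-3)

    def test_all_samples_monotone_within_tolerance(self, fitted):
        grid = fitted.support_grid(0.05)
        for r in fitted.regions:
            ss = h.sample_posterior(fitted, r, grid, 100, seed=11)
            assert np.diff(ss.curves, axis=1).min() > -MONOTONE_TOL


class TestSerialization:
    def test_yaml_roundtrip_is_exact(self, fitted, tmp_path):
        path = tmp_path / "model.yaml"
        h.save_model(fitted, path)
        loaded = h.load_model(path)
        assert np.array_equal(loaded.weight_mean, fitted.weight_mean)
        assert np.array_equal(loaded.weight_sd, fitted.weight_sd)
        assert np.array_equal(loaded.d_internal, fitted.d_internal)
        assert loaded.origin == fitted.origin
        assert loaded.config == fitted.config
        assert loaded.subject_ids == fitted.subject_ids
        grid = np.linspace(*fitted.support, 20)
        for r in fitted.regions:
            assert np.array_equal(loaded.predict_mean(r, grid),
                                  fitted.predict_mean(r, grid))


class TestCrossValidation:
    def test_leave_one_out_on_tiny_cohort(self):
        gp, _, _ = small_gene_positive(
            seed=8, n_per_group={"HC": 6, "PreHD": 6, "HD": 4}
        )
        cv = h.cross_validate(gp, h.ModelConfig(seed=1, n_basis=8, n_outer=6), k=10)
        assert np.isfinite(cv.rho) and cv.rho > 0

    def test_duplicated_subjects_split_across_two_folds(self):
        gp, _, _ = small_gene_positive(
            seed=9, n_per_group={"HC": 5, "PreHD": 12, "HD": 6}
        )
        dup = copy.deepcopy(gp)
        twin = gp.data.copy()
        twin["subject_id"] = "twin_" + twin["subject_id"]
        dup.data = pd.concat([gp.data, twin], ignore_index=True)
        originals = list(gp.data["subject_id"].unique())
        folds = [originals, [f"twin_{s}" for s in originals]]
        cv = h.cross_validate(
            dup, h.ModelConfig(seed=1, n_basis=8, n_outer=8), folds=folds
        )
        # each held-out subject has an exact twin in training
        assert cv.rho == pytest.approx(1.0, abs=0.15)

    def test_too_many_folds_raises(self, gene_positive, model_config):
        with pytest.raises(ValueError, match="exceeds"):
            h.cross_validate(gene_positive, model_config, k=10_000)
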