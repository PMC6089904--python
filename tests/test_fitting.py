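"""Least-squares calibration: recovery, counting rules, invariances."""

import numpy as np
import pandas as pd
import pytest

import resistmix as rm
from resistmix.datasets import DoseResponseDataset


def _flat_dataset(value=0.5):
    rows = [{"group": "a", "dose_uM": d, "replicate": r, "viability": value}
            for d in (0.0, 50.0, 100.0) for r in (1, 2)]
    return DoseResponseDataset(pd.DataFrame(rows))


class TestEstimateVmax:
    def test_mean_of_dose_zero_records(self):
        rows = [{"group": "a", "dose_uM": 0.0, "replicate": r, "viability": v}
                for r, v in enumerate([0.8, 1.0])]
        rows += [{"group": "a", "dose_uM": 50.0, "replicate": 1,
                  "viability": 0.4}]
        ds = DoseResponseDataset(pd.DataFrame(rows))
        assert rm.estimate_vmax(ds) == pytest.approx(0.9)

    def test_missing_dose_zero_is_an_error(self):
        rows = [{"group": "a", "dose_uM": d, "replicate": 1, "viability": 0.5}
                for d in (10.0, 50.0)]
        ds = DoseResponseDataset(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="v_max"):
            rm.estimate_vmax(ds)


class TestSingleStatic:
    def test_noiseless_recovery(self):
        design = rm.single_population_design(37.0, 0.055, 0.9)
        ds = rm.simulate_assay(design, rm.NoiseModel.constant(0.0))
        fit = rm.fit_single_static(ds, v_max=0.9)
        assert fit.converged
        assert fit.params.ld50 == pytest.approx(37.0, rel=1e-6)
        assert fit.params.slope == pytest.approx(0.055, rel=1e-6)
        assert fit.k == 2

    def test_flat_data_does_not_converge(self):
        fit = rm.fit_single_static(_flat_dataset(), v_max=0.5)
        assert not fit.converged
        assert "dose effect" in fit.message

    def test_too_few_doses_rejected(self):
        rows = [{"group": "a", "dose_uM": d, "replicate": 1, "viability": v}
                for d, v in [(0.0, 0.9), (50.0, 0.4)]]
        ds = DoseResponseDataset(pd.DataFrame(rows))
        with pytest.raises(ValueError):
            rm.fit_single_static(ds, v_max=0.9)


class TestSingleDynamic:
    def test_parameter_count_scales_with_groups(self, noisy_time_course):
        fit = rm.fit_single_dynamic(noisy_time_course, v_max=0.9)
        assert fit.k == 16  # slope and LD50 at each of the 8 weeks

    def test_single_group_reduces_to_static(self):
        design = rm.single_population_design(37.0, 0.055, 0.9)
        ds = rm.simulate_assay(design, rm.NoiseModel.constant(0.03, seed=2))
        static = rm.fit_single_static(ds, v_max=0.9)
        dynamic = rm.fit_single_dynamic(ds, v_max=0.9)
        assert dynamic.rss == pytest.approx(static.rss, rel=1e-8)
        assert dynamic.params.ld50[0] == pytest.approx(static.params.ld50,
                                                       rel=1e-6)

    def test_noiseless_per_group_recovery(self):
        truth = {1: (30.0, 0.05), 2: (60.0, 0.04), 3: (90.0, 0.03)}
        curves = {
            g: (lambda d, c=c, m=m: rm.logistic_viability(d, c, m, 0.9))
            for g, (c, m) in truth.items()
        }
        design = rm.AssayDesign(doses=rm.reference.DOSE_PANEL, replicates=3,
                                curves=curves)
        ds = rm.simulate_assay(design, rm.NoiseModel.constant(0.0))
        fit = rm.fit_single_dynamic(ds, v_max=0.9)
        for g, (c, m) in truth.items():
            assert fit.params.curve(g).ld50 == pytest.approx(c, rel=1e-6)
            assert fit.params.curve(g).slope == pytest.approx(m, rel=1e-6)


class TestTwoPopulation:
    def test_parameter_count_four_plus_one_per_group(self, noisy_time_course):
        fit = rm.fit_two_population(noisy_time_course, v_max=0.9)
        assert fit.k == 12  # 4 shared state parameters + 8 weekly fractions

    def test_noiseless_joint_recovery(self, noiseless_time_course,
                                      two_pop_truth):
        fit = rm.fit_two_population(noiseless_time_course, v_max=0.9)
        assert fit.converged
        assert fit.params.sensitive.ld50 == pytest.approx(22.4, rel=1e-4)
        assert fit.params.resistant.ld50 == pytest.approx(79.7, rel=1e-4)
        assert fit.params.sensitive.slope == pytest.approx(0.060, rel=1e-4)
        assert fit.params.resistant.slope == pytest.approx(0.028, rel=1e-4)
        for g, f_true in zip(two_pop_truth.groups, two_pop_truth.f_sens):
            assert fit.per_group_fractions[g] == pytest.approx(f_true,
                                                               abs=1e-4)

    def test_fractions_respect_unit_interval(self, noisy_time_course):
        fit = rm.fit_two_population(noisy_time_course, v_max=0.9)
        assert all(0.0 <= f <= 1.0 for f in fit.params.f_sens)

    def test_pure_sensitive_data_recovers_pure_curve(self, two_pop_truth):
        design = rm.make_time_course_design([1.0] * 4, two_pop_truth)
        ds = rm.simulate_assay(design, rm.NoiseModel.constant(0.0))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = rm.fit_two_population(ds, v_max=0.9)
        # the resistant state is unidentifiable here: either the fitted
        # sensitive fraction pins to 1 or the two states collapse; in both
        # cases the fitted curve must equal the pure sensitive curve
        doses = np.asarray(design.doses)
        expected = rm.logistic_viability(doses,
                                         two_pop_truth.sensitive.ld50,
                                         two_pop_truth.sensitive.slope, 0.9)
        for g in fit.groups:
            fitted = rm.evaluate_two_population(fit.params, doses, g)
            assert np.allclose(fitted, expected, atol=1e-3)
        separation = (fit.params.resistant.ld50 - fit.params.sensitive.ld50)
        assert (min(fit.params.f_sens) > 0.95) or (separation < 2.0) \
            or (max(1 - f for f in fit.params.f_sens) *
                separation < 1.0)

    def test_too_few_doses_rejected(self, two_pop_truth):
        design = rm.make_time_course_design([0.5], two_pop_truth,
                                            doses=(0.0, 50.0, 100.0, 150.0))
        ds = rm.simulate_assay(design, rm.NoiseModel.constant(0.0))
        with pytest.raises(ValueError):
            rm.fit_two_population(ds, v_max=0.9)


class TestInvariances:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dynamic_never_fits_worse_than_static(self, time_course_design,
                                                  seed):
        ds = rm.simulate_assay(time_course_design,
                               rm.NoiseModel.constant(0.05, seed=seed))
        static = rm.fit_single_static(ds, v_max=0.9)
        dynamic = rm.fit_single_dynamic(ds, v_max=0.9)
        assert dynamic.rss <= static.rss + 1e-12

    def test_record_shuffling_leaves_fit_unchanged(self, noisy_time_course):
        fit = rm.fit_two_population(noisy_time_course, v_max=0.9)
        shuffled = DoseResponseDataset(
            noisy_time_course.frame.sample(frac=1.0, random_state=99)
            .reset_index(drop=True))
        fit_shuffled = rm.fit_two_population(shuffled, v_max=0.9)
        # identical up to solver termination tolerance: the cost is a sum
        # whose floating-point value depends on record order
        assert fit_shuffled.params.sensitive.ld50 == pytest.approx(
            fit.params.sensitive.ld50, rel=1e-4)
        assert fit_shuffled.params.resistant.ld50 == pytest.approx(
            fit.params.resistant.ld50, rel=1e-4)
        assert fit_shuffled.per_group_fractions == pytest.approx(
            fit.per_group_fractions, abs=1e-3)

    def test_model_dispatch(self, noisy_time_course):
        fit = rm.fit_model(noisy_time_course, "single_static", v_max=0.9)
        assert fit.model_kind == "single_static"
        with pytest.raises(ValueError):
            rm.fit_model(noisy_time_course, "three_population", v_max=0.9)
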