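"""Growth-rate and subpopulation-trajectory bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from resistmix.dynamics import (growth_rates_from_counts, per_capita_growth,
                                project_totals, subpopulation_counts)


def _counts(weeks, values):
    rows = []
    for w, reps in zip(weeks, values):
        for r, c in enumerate(reps, start=1):
            rows.append({"week": w, "replicate": r, "count": c})
    return pd.DataFrame(rows)


def _totals(weeks, values, lo=None, hi=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({
        "n_total": values,
        "lower": values if lo is None else lo,
        "upper": values if hi is None else hi,
    }, index=pd.Index(weeks, name="week"))


def _fractions(weeks, values, lo=None, hi=None):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame({
        "f_res": values,
        "lower": values if lo is None else lo,
        "upper": values if hi is None else hi,
    }, index=pd.Index(weeks, name="week"))


class TestPerCapitaGrowth:
    @pytest.mark.parametrize("n0, n1, days, expected", [
        (1000, 1000, 7, 0.0),
        (1000, 2000, 7, 0.099021),   # doubling: ln(2)/7
        (2000, 1000, 7, -0.099021),  # halving is the mirror image
    ])
    def test_log_ratio_rate(self, n0, n1, days, expected):
        assert per_capita_growth(n0, n1, days) == pytest.approx(expected,
                                                                abs=1e-6)

    @pytest.mark.parametrize("n0, n1, days", [
        (0, 100, 7), (100, -5, 7), (100, 100, 0),
    ])
    def test_domain_errors(self, n0, n1, days):
        with pytest.raises(ValueError):
            per_capita_growth(n0, n1, days)


class TestGrowthRates:
    def test_exact_doubling_has_zero_width(self):
        counts = _counts([1, 2], [(1000, 1000, 1000), (2000, 2000, 2000)])
        rates = growth_rates_from_counts(counts)
        assert rates.loc[1, "rate"] == pytest.approx(math.log(2) / 7)
        assert rates.loc[1, "lower"] == pytest.approx(rates.loc[1, "upper"])
        assert rates.loc[1, "n_replicates"] == 3

    def test_t_interval_matches_closed_form(self):
        from scipy import stats

        counts = _counts([1, 2], [(1000, 1000, 1000), (1800, 2000, 2200)])
        rates = growth_rates_from_counts(counts)
        per_rep = np.log(np.array([1800, 2000, 2200]) / 1000.0) / 7.0
        half = stats.t.ppf(0.975, 2) * per_rep.std(ddof=1) / math.sqrt(3)
        assert rates.loc[1, "upper"] - rates.loc[1, "rate"] \
            == pytest.approx(half)

    def test_positive_counts_required(self):
        counts = _counts([1, 2], [(1000,), (0,)])
        with pytest.raises(ValueError):
            growth_rates_from_counts(counts)


class TestProjectTotals:
    def test_zero_rates_keep_population_constant(self):
        rates = pd.DataFrame({"rate": [0.0, 0.0], "lower": [0.0, 0.0],
                              "upper": [0.0, 0.0]},
                             index=pd.Index([1, 2], name="week"))
        totals = project_totals(1000.0, rates)
        assert np.allclose(totals["n_total"], 1000.0)

    def test_constant_doubling_rate(self):
        r = math.log(2) / 7
        rates = pd.DataFrame({"rate": [r] * 3, "lower": [r] * 3,
                              "upper": [r] * 3},
                             index=pd.Index([1, 2, 3], name="week"))
        totals = project_totals(1000.0, rates)
        assert np.allclose(totals["n_total"], [1000, 2000, 4000, 8000])

    def test_one_week_at_known_rate(self):
        rates = pd.DataFrame({"rate": [0.0990], "lower": [0.0990],
                              "upper": [0.0990]},
                             index=pd.Index([1], name="week"))
        totals = project_totals(1000.0, rates)
        assert totals.loc[2, "n_total"] == pytest.approx(2000.0, rel=1e-3)

    def test_missing_week_is_an_error(self):
        rates = pd.DataFrame({"rate": [0.1, 0.1], "lower": [0.1, 0.1],
                              "upper": [0.1, 0.1]},
                             index=pd.Index([1, 3], name="week"))
        with pytest.raises(ValueError, match="missing"):
            project_totals(1000.0, rates)


class TestSubpopulationCounts:
    def test_quarter_resistant_split(self):
        out = subpopulation_counts(_totals([1], [1000.0]),
                                   _fractions([1], [0.25]))
        assert out.loc[1, "n_res"] == pytest.approx(250.0)
        assert out.loc[1, "n_sens"] == pytest.approx(750.0)

    def test_zero_fraction_gives_empty_resistant_trajectory(self):
        out = subpopulation_counts(_totals([1, 2], [1000.0, 2000.0]),
                                   _fractions([1, 2], [0.0, 0.0]))
        assert np.allclose(out["n_res"], 0.0)
        assert np.allclose(out["n_sens"], out["n_total"])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6),
           st.floats(1.0, 1e6))
    def test_counts_conserve_total_exactly(self, fracs, n0):
        weeks = list(range(1, len(fracs) + 1))
        totals = _totals(weeks, [n0 * (1.2 ** i) for i in range(len(fracs))])
        out = subpopulation_counts(totals, _fractions(weeks, fracs))
        assert np.array_equal(out["n_res"] + out["n_sens"], out["n_total"])

    def test_misaligned_weeks_rejected(self):
        with pytest.raises(ValueError, match="weeks"):
            subpopulation_counts(_totals([1, 2], [1.0, 2.0]),
                                 _fractions([1, 3], [0.5, 0.5]))

    def test_unit_rescaling_scales_trajectories(self):
        totals = _totals([1, 2], [1000.0, 1500.0],
                         lo=[900.0, 1300.0], hi=[1100.0, 1700.0])
        fr = _fractions([1, 2], [0.3, 0.6], lo=[0.2, 0.5], hi=[0.4, 0.7])
        a = subpopulation_counts(totals, fr)
        b = subpopulation_counts(totals * 10.0, fr)
        # every output column is a cell count, so all scale by the factor
        assert np.allclose(b, a * 10.0)

    def test_compounded_interval_at_least_as_wide_as_inputs(self):
        totals = _totals([1], [1000.0], lo=[800.0], hi=[1200.0])
        fr = _fractions([1], [0.5], lo=[0.4], hi=[0.6])
        out = subpopulation_counts(totals, fr)
        rel_n = (1200 - 800) / 1000
        rel_f = (0.6 - 0.4) / 0.5
        rel_res = (out.loc[1, "n_res_upper"] - out.loc[1, "n_res_lower"]) \
            / out.loc[1, "n_res"]
        assert rel_res >= max(rel_n, rel_f) - 1e-12

    def test_montecarlo_within_interval_bounds(self):
        totals = _totals([1], [1000.0], lo=[800.0], hi=[1200.0])
        fr = _fractions([1], [0.5], lo=[0.4], hi=[0.6])
        ia = subpopulation_counts(totals, fr, method="interval")
        mc = subpopulation_counts(totals, fr, method="montecarlo", seed=1)
        assert ia.loc[1, "n_res_lower"] <= mc.loc[1, "n_res_lower"]
        assert mc.loc[1, "n_res_upper"] <= ia.loc[1, "n_res_upper"]
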