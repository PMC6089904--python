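"""Mixture validation and parameter-identifiability studies.

Two ways of checking that the two-population fit recovers real
subpopulation structure:

* **mixture validation** — fit the joint model to assays of *known*
  sensitive/resistant mixtures (groups = mixture compositions instead of
  weeks) and compare estimated to measured resistant fractions via the
  coefficient of determination,
* **identifiability study** — repeatedly simulate mixture assays from a
  known truth under realistic dose-dependent noise, refit each, and
  examine the spread of the estimate distributions, whether the truth
  lies inside their central 95% bands, and whether neighbouring mixture
  fractions remain statistically distinguishable (pairwise Welch
  t-tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import DoseResponseDataset
from .fitting import FitResult, fit_two_population
from .models import TwoPopulationParams
from .selection import bootstrap_ci
from .simulate import NoiseModel, make_mixture_design, simulate_assay

__all__ = [
    "MixtureValidationResult",
    "IdentifiabilityReport",
    "fit_mixture_fractions",
    "r_squared",
    "validate_mixtures",
    "run_identifiability_study",
    "pairwise_fraction_tests",
]


def fit_mixture_fractions(dataset: DoseResponseDataset,
                          v_max: Optional[float] = None,
                          n_starts: int = 10) -> FitResult:
    """Joint two-population fit with groups interpreted as mixtures.

    The estimated resistant fraction of each mixture is
    ``1 - f_sens[group]`` on the returned fit.  With a single group the
    fractions are not identifiable jointly with free LD50s; that case is
    allowed but warned about.
    """
    if len(dataset.groups) < 2:
        warnings.warn(
            "a single mixture group cannot pin down both states and its "
            "fraction; estimates will be unreliable", stacklevel=2,
        )
    return fit_two_population(dataset, v_max=v_max, n_starts=n_starts)


def r_squared(measured, estimated, convention: str = "unity") -> float:
    """Coefficient of determination between measured and estimated values.

    ``convention="unity"`` (default) takes residuals about the line of
    unity — the estimates are judged against the measurements as truth:
    ``R² = 1 − Σ(est−meas)² / Σ(meas−mean(meas))²``.
    ``convention="regression"`` instead reports the squared Pearson
    correlation.
    """
    meas = np.asarray(measured, dtype=float)
    est = np.asarray(estimated, dtype=float)
    if meas.shape != est.shape or meas.ndim != 1 or len(meas) < 2:
        raise ValueError("measured and estimated must be equal-length "
                         "vectors with n >= 2")
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("measured values have zero variance; R² undefined")
    if convention == "unity":
        return 1.0 - float(np.sum((est - meas) ** 2)) / ss_tot
    if convention == "regression":
        return float(np.corrcoef(meas, est)[0, 1] ** 2)
    raise ValueError(f"unknown R² convention {convention!r}")


@dataclass
class MixtureValidationResult:
    """Per-mixture measured vs estimated resistant fractions and the
    overall coefficient of determination."""

    table: pd.DataFrame  # index: group; measured, estimated, lower, upper
    r2: float
    fit: FitResult


def validate_mixtures(dataset: DoseResponseDataset, measured: dict,
                      v_max: Optional[float] = None, n_boot: int = 500,
                      seed: int = 0, n_starts: int = 10) -> MixtureValidationResult:
    """Full mixture validation: joint fit, bootstrap CIs on the
    fractions, and R² of estimated vs measured resistant fractions.

    ``measured`` maps each mixture group label to its measured resistant
    fraction.
    """
    fit = fit_mixture_fractions(dataset, v_max=v_max, n_starts=n_starts)
    missing = [g for g in dataset.groups if g not in measured]
    if missing:
        raise ValueError(f"measured fractions missing for group(s) {missing}")
    boot = bootstrap_ci(dataset, "two_population", v_max=fit.v_max,
                        n_boot=n_boot, seed=seed, fit=fit)
    rows = []
    for g in dataset.groups:
        est = 1.0 - fit.per_group_fractions[g]
        lo_s, hi_s = boot.interval(f"f_sens[{g}]")
        rows.append({
            "group": g,
            "measured": float(measured[g]),
            "estimated": est,
            "lower": 1.0 - hi_s,
            "upper": 1.0 - lo_s,
        })
    table = pd.DataFrame(rows).set_index("group")
    r2 = r_squared(table["measured"], table["estimated"])
    return MixtureValidationResult(table=table, r2=r2, fit=fit)


@dataclass
class IdentifiabilityReport:
    """Estimate distributions from a simulate-and-refit study.

    ``estimates`` holds one row per converged simulated dataset with the
    natural-space parameters; ``bands`` the central 95% band and truth
    coverage per parameter; ``fraction_estimates`` the resistant-fraction
    estimate distribution per mixture group.
    """

    estimates: pd.DataFrame
    bands: pd.DataFrame  # index: parameter; lower, upper, truth, covered
    truth: dict
    n_sim: int
    n_failed: int

    @property
    def fraction_estimates(self) -> dict:
        out = {}
        for col in self.estimates.columns:
            if col.startswith("f_res["):
                out[col[len("f_res["):-1]] = self.estimates[col].to_numpy()
        return out


def run_identifiability_study(truth: TwoPopulationParams,
                              mixture_fractions=None,
                              noise: Optional[NoiseModel] = None,
                              doses=None, replicates: int = 4,
                              n_sim: int = 100, seed: int = 0,
                              band_level: float = 0.95,
                              n_starts: int = 10) -> IdentifiabilityReport:
    """Simulate ``n_sim`` mixture assays from ``truth`` and refit each.

    ``mixture_fractions`` are the resistant fractions of the simulated
    mixtures; when omitted they are read off ``truth`` (``1 - f_sens``
    per group).  Non-converged refits are counted and excluded from the
    bands.
    """
    from . import reference

    if mixture_fractions is None:
        if not truth.groups:
            raise ValueError("truth has no groups and no mixture_fractions "
                             "were given")
        mixture_fractions = tuple(1.0 - f for f in truth.f_sens)
    if noise is None:
        noise = NoiseModel.constant(reference.DEFAULT_NOISE_SD)
    if doses is None:
        doses = reference.DOSE_PANEL
    design = make_mixture_design(mixture_fractions, truth, doses=doses,
                                 replicates=replicates)
    truth_params = {
        "ld50_sens": truth.sensitive.ld50,
        "ld50_res": truth.resistant.ld50,
        "slope_sens": truth.sensitive.slope,
        "slope_res": truth.resistant.slope,
    }
    for g, frac in zip(design.groups, mixture_fractions):
        truth_params[f"f_res[{g}]"] = float(frac)

    seed_root = np.random.SeedSequence(seed)
    rows = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_sim):
            sim_seed = int(seed_root.spawn(1)[0].generate_state(1)[0] % (2**31))
            sim_noise = NoiseModel(sd_at_dose=noise.sd_at_dose,
                                   scale=noise.scale, seed=sim_seed)
            ds = simulate_assay(design, sim_noise)
            fit = fit_two_population(ds, v_max=truth.v_max, n_starts=n_starts)
            if not fit.converged:
                n_failed += 1
                continue
            row = {
                "ld50_sens": fit.params.sensitive.ld50,
                "ld50_res": fit.params.resistant.ld50,
                "slope_sens": fit.params.sensitive.slope,
                "slope_res": fit.params.resistant.slope,
            }
            for g, f in fit.per_group_fractions.items():
                row[f"f_res[{g}]"] = 1.0 - f
            rows.append(row)
    estimates = pd.DataFrame(rows)
    alpha = (1.0 - band_level) / 2.0
    band_rows = []
    for name, true_val in truth_params.items():
        if estimates.empty:
            lo = hi = float("nan")
            covered = False
        else:
            lo = float(estimates[name].quantile(alpha))
            hi = float(estimates[name].quantile(1.0 - alpha))
            # float tolerance: truths at a parameter bound (fraction 0 or
            # 1) would otherwise fall an epsilon outside the band
            tol = 1e-9
            covered = bool(lo - tol <= true_val <= hi + tol)
        band_rows.append({"parameter": name, "lower": lo, "upper": hi,
                          "truth": true_val, "covered": covered})
    bands = pd.DataFrame(band_rows).set_index("parameter")
    return IdentifiabilityReport(estimates=estimates, bands=bands,
                                 truth=truth_params, n_sim=n_sim,
                                 n_failed=n_failed)


def pairwise_fraction_tests(fractions_by_group: dict,
                            bonferroni: bool = False) -> pd.DataFrame:
    """Welch t-test p-value matrix over mixture-fraction distributions.

    ``fractions_by_group`` maps a mixture label to the array of its
    fraction estimates across simulated datasets (e.g.
    ``IdentifiabilityReport.fraction_estimates``).  Zero-variance pairs
    short-circuit: p = 1 when the means coincide, p = 0 otherwise.  With
    ``bonferroni=True`` p-values are multiplied by the number of pairs
    (capped at 1).
    """
    labels = list(fractions_by_group)
    if len(labels) < 2:
        raise ValueError("at least two mixture distributions are required")
    arrays = {}
    for lab in labels:
        a = np.asarray(fractions_by_group[lab], dtype=float)
        if len(a) < 2:
            raise ValueError(f"distribution {lab!r} has fewer than 2 estimates")
        arrays[lab] = a
    n_pairs = len(labels) * (len(labels) - 1) // 2
    mat = pd.DataFrame(np.ones((len(labels), len(labels))),
                       index=labels, columns=labels)
    for a_lab, b_lab in combinations(labels, 2):
        a, b = arrays[a_lab], arrays[b_lab]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if bonferroni:
            p = min(1.0, p * n_pairs)
        mat.loc[a_lab, b_lab] = p
        mat.loc[b_lab, a_lab] = p
    return mat
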