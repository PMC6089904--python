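"""Model comparison (AIC, MSE) and bootstrap confidence intervals.

AIC uses the Gaussian least-squares form ``n ln(rss/n) + 2k`` with the
free-parameter counts of the fitting module (V_max excluded).  The
small-sample corrected variant (AICc) is available behind a flag.

Confidence intervals are percentile intervals from a stratified case
bootstrap: records are resampled with replacement *within* each
(group, dose) cell, which preserves the assay's design balance, and
each resampled dataset is refit warm-started from the original
solution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .datasets import DoseResponseDataset
from .fitting import (MODEL_KINDS, FitResult, _natural_params, _refit_warm,
                      _resolve_vmax, fit_model)

__all__ = ["ModelComparison", "BootstrapSummary", "compute_aic",
           "compare_models", "bootstrap_ci"]


def compute_aic(n_obs: int, rss: float, k: int, corrected: bool = False) -> float:
    """Least-squares AIC: ``n ln(rss/n) + 2k`` (lower is better).

    With ``corrected=True`` the small-sample AICc penalty
    ``2k(k+1)/(n-k-1)`` is added.  A zero rss is a degenerate
    (interpolating) fit: −inf is returned with a warning rather than an
    exception so callers can still rank the alternatives.
    """
    if n_obs <= k:
        raise ValueError(
            f"AIC requires more observations than parameters (n={n_obs}, k={k})"
        )
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0:
        warnings.warn("rss is zero: AIC is degenerate (-inf)", stacklevel=2)
        return -math.inf
    aic = n_obs * math.log(rss / n_obs) + 2 * k
    if corrected:
        if n_obs - k - 1 <= 0:
            raise ValueError("AICc undefined for n <= k + 1")
        aic += 2 * k * (k + 1) / (n_obs - k - 1)
    return aic


@dataclass
class ModelComparison:
    """AIC/MSE table over the fitted models and the lowest-AIC winner."""

    table: pd.DataFrame  # index: model kind; columns: k, n_obs, rss, mse, aic, converged
    winner: str
    fits: dict

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.table}\nwinner: {self.winner}"


def compare_models(dataset: DoseResponseDataset,
                   v_max: Optional[float] = None,
                   models=MODEL_KINDS,
                   n_starts: int = 10,
                   aic_corrected: bool = False) -> ModelComparison:
    """Fit each candidate model and rank them by AIC.

    Non-converged fits are reported in the table but excluded from
    winner selection (with a warning).
    """
    v_max = _resolve_vmax(dataset, v_max)
    fits: dict[str, FitResult] = {}
    rows = []
    for kind in models:
        fit = fit_model(dataset, kind, v_max=v_max, n_starts=n_starts)
        fits[kind] = fit
        rows.append({
            "model": kind,
            "k": fit.k,
            "n_obs": fit.n_obs,
            "rss": fit.rss,
            "mse": fit.mse,
            "aic": compute_aic(fit.n_obs, fit.rss, fit.k,
                               corrected=aic_corrected),
            "converged": fit.converged,
        })
    table = pd.DataFrame(rows).set_index("model")
    eligible = table[table["converged"]]
    if eligible.empty:
        warnings.warn("no model converged; winner chosen among all fits",
                      stacklevel=2)
        eligible = table
    elif len(eligible) < len(table):
        dropped = sorted(set(table.index) - set(eligible.index))
        warnings.warn(
            f"non-converged fit(s) excluded from winner selection: {dropped}",
            stacklevel=2,
        )
    winner = str(eligible["aic"].idxmin())
    return ModelComparison(table=table, winner=winner, fits=fits)


@dataclass
class BootstrapSummary:
    """Percentile confidence intervals per parameter.

    ``table`` has one row per parameter with columns
    ``estimate, lower, upper``; ``reliable`` is False when more than 10%
    of the bootstrap refits failed to converge.
    """

    table: pd.DataFrame
    n_boot: int
    level: float
    n_failed: int
    reliable: bool
    samples: pd.DataFrame  # one row per successful replicate

    def interval(self, name: str) -> tuple:
        row = self.table.loc[name]
        return float(row["lower"]), float(row["upper"])


def bootstrap_ci(dataset: DoseResponseDataset, model_kind: str,
                 v_max: Optional[float] = None, n_boot: int = 500,
                 level: float = 0.95, seed: int = 0,
                 n_starts: int = 10,
                 fit: Optional[FitResult] = None) -> BootstrapSummary:
    """Stratified case bootstrap of a model fit.

    Each of ``n_boot`` surrogate datasets resamples the records with
    replacement within every (group, dose) cell and is refit from the
    original solution.  Percentile intervals at ``level`` are reported
    for every natural-space parameter.  A pre-computed ``fit`` of the
    same model may be supplied to skip the initial multistart fit.
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    v_max = _resolve_vmax(dataset, v_max)
    if fit is None:
        fit = fit_model(dataset, model_kind, v_max=v_max, n_starts=n_starts)
    elif fit.model_kind != model_kind:
        raise ValueError("supplied fit is for a different model kind")
    dose, y, codes, groups = dataset.arrays()
    n_groups = len(groups)

    # index the (group, dose) strata once
    strata: list[np.ndarray] = []
    keys = {}
    for i, key in enumerate(zip(codes.tolist(), dose.tolist())):
        keys.setdefault(key, []).append(i)
    strata = [np.asarray(v, dtype=np.intp) for v in keys.values()]

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    records = []
    n_failed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # refit-level warnings are summarised
        for _ in range(n_boot):
            idx = np.concatenate([
                s[rng.integers(0, len(s), size=len(s))] for s in strata
            ])
            x, rss, ok = _refit_warm(model_kind, fit.x, dose[idx], y[idx],
                                     codes[idx], n_groups, v_max)
            if not ok:
                n_failed += 1
                continue
            records.append(_natural_params(model_kind, x, groups))
    samples = pd.DataFrame.from_records(records)
    estimate = pd.Series(fit.parameter_dict())
    alpha = (1.0 - level) / 2.0
    if samples.empty:
        lower = upper = estimate * np.nan
    else:
        lower = samples.quantile(alpha)
        upper = samples.quantile(1.0 - alpha)
    table = pd.DataFrame({
        "estimate": estimate,
        "lower": lower.reindex(estimate.index),
        "upper": upper.reindex(estimate.index),
    })
    reliable = n_failed <= 0.10 * n_boot
    if not reliable:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap refits failed to converge; "
            "intervals are unreliable", stacklevel=2,
        )
    return BootstrapSummary(table=table, n_boot=n_boot, level=level,
                            n_failed=n_failed, reliable=reliable,
                            samples=samples)
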