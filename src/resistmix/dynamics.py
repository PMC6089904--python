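"""Cell-count bookkeeping: growth rates and subpopulation trajectories.

Weekly bulk cell counts give a per-capita growth rate per interval
(births minus deaths per cell per day, ``ln(N1/N0)/Δt``); projecting an
initial count through those rates gives the total population size per
week; multiplying by the fitted resistant fraction splits the total
into resistant and sensitive cell numbers.  The split is purely
empirical — no birth/death/transition mechanism is assumed.

Uncertainty: growth-rate intervals are t-intervals across replicates;
the subpopulation count interval compounds the total-count interval
with the bootstrap fraction interval by interval arithmetic
([lo·lo, hi·hi] for positive quantities), with a Monte-Carlo
propagation alternative behind ``method="montecarlo"``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "per_capita_growth",
    "growth_rates_from_counts",
    "project_totals",
    "subpopulation_counts",
]

DAYS_PER_WEEK = 7.0


def per_capita_growth(counts_t0: float, counts_t1: float,
                      delta_days: float = DAYS_PER_WEEK) -> float:
    """Per-capita growth rate (1/day): ``ln(counts_t1/counts_t0)/Δt``."""
    if counts_t0 <= 0 or counts_t1 <= 0:
        raise ValueError("cell counts must be positive")
    if delta_days <= 0:
        raise ValueError("delta_days must be positive")
    return math.log(counts_t1 / counts_t0) / delta_days


def growth_rates_from_counts(counts: pd.DataFrame,
                             delta_days: float = DAYS_PER_WEEK,
                             level: float = 0.95) -> pd.DataFrame:
    """Per-interval growth rates with t-intervals across replicates.

    ``counts`` is a long table with columns ``week, replicate, count``.
    Returns one row per consecutive week pair, indexed by the starting
    week, with columns ``rate, lower, upper, n_replicates``.  Replicates
    present in both weeks are paired; a week pair with a single shared
    replicate gets a degenerate (point) interval.
    """
    for col in ("week", "replicate", "count"):
        if col not in counts.columns:
            raise ValueError(f"counts table is missing column {col!r}")
    if (counts["count"] <= 0).any():
        raise ValueError("cell counts must be positive")
    weeks = sorted(counts["week"].unique())
    rows = []
    for w0, w1 in zip(weeks, weeks[1:]):
        a = counts[counts["week"] == w0].set_index("replicate")["count"]
        b = counts[counts["week"] == w1].set_index("replicate")["count"]
        shared = a.index.intersection(b.index)
        if shared.empty:
            raise ValueError(
                f"no shared replicates between weeks {w0} and {w1}"
            )
        rates = np.array([
            per_capita_growth(a[r], b[r], delta_days) for r in shared
        ])
        mean = float(rates.mean())
        if len(rates) >= 2 and rates.std(ddof=1) > 0:
            half = float(stats.t.ppf(0.5 + level / 2, len(rates) - 1)
                         * rates.std(ddof=1) / math.sqrt(len(rates)))
        else:
            half = 0.0
        rows.append({"week": w0, "rate": mean, "lower": mean - half,
                     "upper": mean + half, "n_replicates": len(rates)})
    return pd.DataFrame(rows).set_index("week")


def project_totals(n0: float, rates: pd.DataFrame,
                   delta_days: float = DAYS_PER_WEEK) -> pd.DataFrame:
    """Project total cell numbers week by week from an initial count.

    ``rates`` is the output of :func:`growth_rates_from_counts` (or any
    frame indexed by starting week with columns ``rate, lower, upper``).
    Week w+1 count is ``N(w) · exp(rate_w · Δt)``; interval bounds
    compound the per-interval rate bounds the same way.  Weeks must be
    consecutive — a gap in the rate series is an error, not an
    interpolation.
    """
    if n0 <= 0:
        raise ValueError("initial cell count must be positive")
    weeks = list(rates.index)
    if any(w1 != w0 + 1 for w0, w1 in zip(weeks, weeks[1:])):
        missing = [w0 + 1 for w0, w1 in zip(weeks, weeks[1:]) if w1 != w0 + 1]
        raise ValueError(f"missing growth rate for week(s) {missing}")
    lower_col = rates["lower"] if "lower" in rates else rates["rate"]
    upper_col = rates["upper"] if "upper" in rates else rates["rate"]
    rows = [{"week": weeks[0], "n_total": float(n0),
             "lower": float(n0), "upper": float(n0)}]
    n = lo = hi = float(n0)
    for w in weeks:
        n *= math.exp(float(rates.loc[w, "rate"]) * delta_days)
        lo *= math.exp(float(lower_col.loc[w]) * delta_days)
        hi *= math.exp(float(upper_col.loc[w]) * delta_days)
        rows.append({"week": w + 1, "n_total": n, "lower": lo, "upper": hi})
    return pd.DataFrame(rows).set_index("week")


def _interval_product(lo1, hi1, lo2, hi2):
    # both intervals non-negative here, so the product interval is
    # simply [lo·lo, hi·hi]
    return lo1 * lo2, hi1 * hi2


def subpopulation_counts(totals: pd.DataFrame, fractions: pd.DataFrame,
                         method: str = "interval", n_draws: int = 10000,
                         seed: int = 0) -> pd.DataFrame:
    """Split total cell numbers into resistant and sensitive counts.

    ``totals``: frame indexed by week with columns
    ``n_total, lower, upper`` (see :func:`project_totals`).
    ``fractions``: frame indexed by week with columns
    ``f_res, lower, upper`` — the resistant fraction with its bootstrap
    interval.  Indices must align exactly.

    Point estimates satisfy ``n_res + n_sens = n_total`` exactly.  The
    compounded interval is the interval-arithmetic product by default;
    ``method="montecarlo"`` instead samples both inputs uniformly over
    their intervals and reports the central interval of the products.
    """
    if not totals.index.equals(fractions.index):
        raise ValueError("totals and fractions must share the same weeks")
    f = fractions["f_res"].to_numpy(dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("resistant fractions must lie in [0, 1]")
    n = totals["n_total"].to_numpy(dtype=float)
    n_lo = totals["lower"].to_numpy(dtype=float)
    n_hi = totals["upper"].to_numpy(dtype=float)
    f_lo = np.clip(fractions["lower"].to_numpy(dtype=float), 0.0, 1.0)
    f_hi = np.clip(fractions["upper"].to_numpy(dtype=float), 0.0, 1.0)

    n_res = f * n
    n_sens = n - n_res
    # report the total as the sum of its parts so the conservation
    # identity n_res + n_sens == n_total holds bit-exactly (the sum can
    # differ from the input total by one ulp)
    n = n_res + n_sens
    if method == "interval":
        res_lo, res_hi = _interval_product(n_lo, n_hi, f_lo, f_hi)
        sens_lo, sens_hi = _interval_product(n_lo, n_hi, 1 - f_hi, 1 - f_lo)
    elif method == "montecarlo":
        rng = np.random.default_rng(seed)
        draws_n = rng.uniform(n_lo, n_hi, size=(n_draws, len(n)))
        draws_f = rng.uniform(f_lo, f_hi, size=(n_draws, len(n)))
        res = draws_n * draws_f
        sens = draws_n * (1 - draws_f)
        res_lo, res_hi = np.percentile(res, [2.5, 97.5], axis=0)
        sens_lo, sens_hi = np.percentile(sens, [2.5, 97.5], axis=0)
    else:
        raise ValueError(f"unknown compounding method {method!r}")
    return pd.DataFrame({
        "n_total": n, "n_total_lower": n_lo, "n_total_upper": n_hi,
        "n_res": n_res, "n_res_lower": res_lo, "n_res_upper": res_hi,
        "n_sens": n_sens, "n_sens_lower": sens_lo, "n_sens_upper": sens_hi,
    }, index=totals.index)
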