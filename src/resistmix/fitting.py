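"""Nonlinear least-squares calibration of the three structural models.

All fits minimise the sum of squared viability residuals with bounded
trust-region least squares (``scipy.optimize.least_squares``, method
``trf``) from multiple starting points: a data-driven heuristic start
plus Latin-hypercube draws over the parameter box.  The baseline
viability ``V_max`` is a fixed normalisation, supplied by the caller or
taken as the mean of the dose-0 records — it is never a free parameter,
so the free-parameter counts are 2 (single static), 2 per group (single
dynamic) and 4 + 1 per group (two population).

The two-population fit is a single joint minimisation: the sensitive
and resistant LD50s and slopes are shared by every group while each
group's sensitive fraction floats in [0, 1].  The canonical state
ordering is imposed by reparameterising the resistant LD50 as
``c_res = c_sens + δ`` with δ > 0, which removes the label-switching
symmetry without any constraint machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import qmc

from .datasets import DoseResponseDataset
from .models import (SigmoidState, SingleDynamicParams, SingleStaticParams,
                     TwoPopulationParams)

__all__ = [
    "FitResult",
    "estimate_vmax",
    "fit_single_static",
    "fit_single_dynamic",
    "fit_two_population",
    "fit_model",
    "MODEL_KINDS",
]

MODEL_KINDS = ("single_static", "single_dynamic", "two_population")

#: solver tolerances: tight, these are cheap problems
_FTOL, _XTOL, _GTOL = 1e-10, 1e-8, 1e-10

#: resistant-minus-sensitive LD50 separation (µM) below which the two
#: states are considered collapsed and the mixture unidentifiable
_SEPARATION_FLAG_UM = 2.0

_EPS = 1e-6


class UnidentifiableMixtureWarning(UserWarning):
    """The two fitted states have nearly identical LD50s; the mixture
    fractions are not separately identifiable."""


@dataclass
class FitResult:
    """Outcome of one model calibration.

    ``x`` is the solver-space vector (kept for warm-started refits, e.g.
    during bootstrap); ``params`` is the natural-space parameter object.
    """

    model_kind: str
    params: object
    rss: float
    n_obs: int
    k: int
    converged: bool
    v_max: float
    groups: tuple = ()
    message: str = ""
    x: np.ndarray = field(default=None, repr=False)

    @property
    def mse(self) -> float:
        return self.rss / self.n_obs

    @property
    def per_group_fractions(self) -> dict:
        """Sensitive fraction per group (two-population model only)."""
        if self.model_kind != "two_population":
            raise AttributeError(
                "per-group fractions exist only for the two-population model"
            )
        return dict(zip(self.params.groups, self.params.f_sens))

    def parameter_dict(self) -> dict:
        """Named natural-space parameters, in a stable order."""
        return _natural_params(self.model_kind, self.x, self.groups)


# ---------------------------------------------------------------------------
# V_max

def estimate_vmax(dataset: DoseResponseDataset) -> float:
    """Baseline viability: the mean of all dose-0 records.

    Fixed thereafter — the models treat V_max as a measured
    normalisation for drug-independent death, not a fitted quantity.
    """
    zero = dataset.frame.loc[dataset.frame["dose_uM"] == 0.0, "viability"]
    if zero.empty:
        raise ValueError(
            "dataset has no dose-0 records; pass an explicit v_max"
        )
    return float(zero.mean())


def _resolve_vmax(dataset, v_max) -> float:
    if v_max is None:
        return estimate_vmax(dataset)
    v_max = float(v_max)
    if not 0 < v_max <= 1:
        raise ValueError(f"v_max must lie in (0, 1], got {v_max}")
    return v_max


# ---------------------------------------------------------------------------
# residuals

def _single_residual(x, dose, y, v_max):
    c, m = x
    return y - v_max * expit(-m * (dose - c))


def _twopop_residual(x, dose, y, codes, v_max):
    c_sens, delta, m_sens, m_res = x[:4]
    f = x[4:][codes]
    vs = expit(-m_sens * (dose - c_sens))
    vr = expit(-m_res * (dose - (c_sens + delta)))
    return y - v_max * (f * vs + (1.0 - f) * vr)


# ---------------------------------------------------------------------------
# multistart machinery

def _solve(fun, starts, lo, hi, args=()):
    """Run bounded trf least squares from each start; keep the best."""
    best = None
    for x0 in starts:
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            res = least_squares(fun, x0, bounds=(lo, hi), args=args,
                                method="trf", ftol=_FTOL, xtol=_XTOL,
                                gtol=_GTOL)
        except Exception:  # singular jacobian etc. — try the next start
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def _lhs(n, ranges, log_mask, seed=1234):
    """n Latin-hypercube points over per-dimension ranges.

    Dimensions flagged in ``log_mask`` are sampled log-uniformly.  The
    sampler seed is fixed: starts depend only on the parameter box, so
    fits are invariant to record order in the data.
    """
    if n <= 0:
        return np.empty((0, len(ranges)))
    sampler = qmc.LatinHypercube(d=len(ranges), seed=seed)
    u = sampler.random(n)
    out = np.empty_like(u)
    for j, ((a, b), is_log) in enumerate(zip(ranges, log_mask)):
        if is_log:
            out[:, j] = np.exp(np.log(a) + u[:, j] * (np.log(b) - np.log(a)))
        else:
            out[:, j] = a + u[:, j] * (b - a)
    return out


def _dose_profile(dose, y):
    """Per-dose mean viability, sorted by dose."""
    order = np.argsort(dose, kind="stable")
    d_sorted, y_sorted = dose[order], y[order]
    uniq, start = np.unique(d_sorted, return_index=True)
    means = np.array([s.mean() for s in np.split(y_sorted, start[1:])])
    return uniq, means


def _half_max_dose(dose, y, v_max):
    uniq, means = _dose_profile(dose, y)
    return float(uniq[np.argmin(np.abs(means - 0.5 * v_max))])


def _is_flat(dose, y) -> bool:
    _, means = _dose_profile(dose, y)
    return float(np.ptp(means)) < 1e-10


# ---------------------------------------------------------------------------
# single static

def _static_bounds(dose):
    dmax = float(dose.max())
    lo = np.array([_EPS, _EPS])
    hi = np.array([2.0 * dmax, 10.0])
    return lo, hi


def _static_starts(dose, y, v_max, n_starts):
    dmax, dmin = float(dose.max()), float(dose.min())
    c0 = max(_half_max_dose(dose, y, v_max), 1.0)
    m0 = 4.0 / max(dmax - dmin, 1.0)
    starts = [np.array([c0, m0])]
    extra = _lhs(n_starts - 1, [(1.0, 2.0 * dmax), (1e-3, 1.0)],
                 [False, True])
    starts.extend(extra)
    return starts


def _fit_static_arrays(dose, y, v_max, n_starts, extra_starts=()):
    lo, hi = _static_bounds(dose)
    starts = _static_starts(dose, y, v_max, n_starts) + list(extra_starts)
    best = _solve(_single_residual, starts, lo, hi, args=(dose, y, v_max))
    return best


def fit_single_static(dataset: DoseResponseDataset, v_max: Optional[float] = None,
                      n_starts: int = 10) -> FitResult:
    """Fit one logistic curve to all records pooled across groups."""
    v_max = _resolve_vmax(dataset, v_max)
    dose, y, codes, groups = dataset.arrays()
    if len(np.unique(dose)) < 3:
        raise ValueError("at least 3 distinct doses are required")
    n = len(y)
    if _is_flat(dose, y):
        c0 = max(float(dose.max()), 1.0)
        x = np.array([c0, _EPS])
        rss = float(np.sum(_single_residual(x, dose, y, v_max) ** 2))
        return FitResult("single_static",
                         SingleStaticParams(c0, _EPS, v_max), rss, n, 2,
                         converged=False, v_max=v_max, groups=groups,
                         message="no dose effect in the data", x=x)
    best = _fit_static_arrays(dose, y, v_max, n_starts)
    if best is None:
        raise RuntimeError("single-static optimisation failed from all starts")
    c, m = best.x
    return FitResult("single_static", SingleStaticParams(c, m, v_max),
                     float(2 * best.cost), n, 2, bool(best.success),
                     v_max=v_max, groups=groups,
                     message=best.message, x=best.x.copy())


# ---------------------------------------------------------------------------
# single dynamic

def fit_single_dynamic(dataset: DoseResponseDataset,
                       v_max: Optional[float] = None,
                       n_starts: int = 10) -> FitResult:
    """Fit an independent logistic curve per group, sharing ``v_max``.

    Equivalent to fitting a dose-response curve to each group on its
    own; the pooled rss is the sum over groups.  The pooled static
    solution is added as an extra start in every group, so the dynamic
    model can never fit worse than its static special case.
    """
    v_max = _resolve_vmax(dataset, v_max)
    dose, y, codes, groups = dataset.arrays()
    static = fit_single_static(dataset, v_max, n_starts=n_starts)
    ld50s, slopes, xs = [], [], []
    rss = 0.0
    all_ok = True
    messages = []
    for gi, group in enumerate(groups):
        sel = codes == gi
        d_g, y_g = dose[sel], y[sel]
        if len(np.unique(d_g)) < 3:
            raise ValueError(
                f"group {group!r} needs at least 3 distinct doses"
            )
        if _is_flat(d_g, y_g):
            all_ok = False
            messages.append(f"group {group!r}: no dose effect")
            c, m = max(float(d_g.max()), 1.0), _EPS
            rss += float(np.sum(
                _single_residual((c, m), d_g, y_g, v_max) ** 2))
        else:
            best = _fit_static_arrays(d_g, y_g, v_max, n_starts,
                                      extra_starts=[static.x])
            if best is None:
                all_ok = False
                messages.append(f"group {group!r}: optimisation failed")
                c, m = static.x
                rss += float(np.sum(
                    _single_residual((c, m), d_g, y_g, v_max) ** 2))
            else:
                if not best.success:
                    all_ok = False
                    messages.append(f"group {group!r}: {best.message}")
                c, m = best.x
                rss += float(2 * best.cost)
        ld50s.append(float(c))
        slopes.append(float(m))
        xs.extend([float(c), float(m)])
    params = SingleDynamicParams(groups, tuple(ld50s), tuple(slopes), v_max)
    return FitResult("single_dynamic", params, rss, len(y), 2 * len(groups),
                     converged=all_ok, v_max=v_max, groups=groups,
                     message="; ".join(messages), x=np.array(xs))


# ---------------------------------------------------------------------------
# two population

def _twopop_bounds(dose, n_groups):
    dmax = float(dose.max())
    lo = np.concatenate([[_EPS, _EPS, _EPS, _EPS], np.zeros(n_groups)])
    hi = np.concatenate([[2.0 * dmax, 2.0 * dmax, 10.0, 10.0],
                         np.ones(n_groups)])
    return lo, hi


def _twopop_starts(dose, y, v_max, n_groups, n_starts):
    dmax, dmin = float(dose.max()), float(dose.min())
    c50 = max(_half_max_dose(dose, y, v_max), 2.0)
    m0 = 4.0 / max(dmax - dmin, 1.0)
    heuristic = np.concatenate([
        [max(0.6 * c50, 1.0), max(0.8 * c50, 5.0), m0, m0],
        np.full(n_groups, 0.5),
    ])
    ranges = ([(1.0, dmax), (2.0, dmax), (3e-3, 0.5), (3e-3, 0.5)]
              + [(0.05, 0.95)] * n_groups)
    log_mask = [False, False, True, True] + [False] * n_groups
    return [heuristic] + list(_lhs(n_starts - 1, ranges, log_mask))


def fit_two_population(dataset: DoseResponseDataset,
                       v_max: Optional[float] = None,
                       n_starts: int = 10) -> FitResult:
    """Joint two-state mixture fit with shared-state constraints.

    One minimisation over (c_sens, δ, m_sens, m_res, f_sens per group),
    with c_res = c_sens + δ; the free-parameter count is 4 + the number
    of groups.  A fit whose states end up closer than ~2 µM apart is
    flagged with :class:`UnidentifiableMixtureWarning`: the data do not
    support two distinct states, and the fractions are arbitrary.
    """
    v_max = _resolve_vmax(dataset, v_max)
    dose, y, codes, groups = dataset.arrays()
    if len(np.unique(dose)) < 5:
        raise ValueError("at least 5 distinct doses are required")
    n_groups = len(groups)
    lo, hi = _twopop_bounds(dose, n_groups)
    starts = _twopop_starts(dose, y, v_max, n_groups, n_starts)
    best = _solve(_twopop_residual, starts, lo, hi,
                  args=(dose, y, codes, v_max))
    if best is None:
        raise RuntimeError(
            "two-population optimisation failed from all starts"
        )
    c_sens, delta, m_sens, m_res = best.x[:4]
    fractions = tuple(float(f) for f in best.x[4:])
    params = TwoPopulationParams(
        sensitive=SigmoidState(c_sens, m_sens),
        resistant=SigmoidState(c_sens + delta, m_res),
        groups=groups, f_sens=fractions, v_max=v_max,
    )
    message = best.message
    if delta < _SEPARATION_FLAG_UM:
        message = (f"states separated by only {delta:.3g} µM; "
                   "mixture fractions are not identifiable")
        warnings.warn(message, UnidentifiableMixtureWarning, stacklevel=2)
    return FitResult("two_population", params, float(2 * best.cost), len(y),
                     4 + n_groups, bool(best.success), v_max=v_max,
                     groups=groups, message=message, x=best.x.copy())


def fit_model(dataset: DoseResponseDataset, model_kind: str,
              v_max: Optional[float] = None, n_starts: int = 10) -> FitResult:
    """Dispatch a fit by model kind."""
    if model_kind == "single_static":
        return fit_single_static(dataset, v_max, n_starts)
    if model_kind == "single_dynamic":
        return fit_single_dynamic(dataset, v_max, n_starts)
    if model_kind == "two_population":
        return fit_two_population(dataset, v_max, n_starts)
    raise ValueError(f"unknown model kind {model_kind!r}; "
                     f"expected one of {MODEL_KINDS}")


# ---------------------------------------------------------------------------
# warm refits (bootstrap internals)

def _refit_warm(model_kind, x0, dose, y, codes, n_groups, v_max):
    """Single-start refit from a previous solution; used by the
    bootstrap, where the resampled problem is near the original one.

    Returns (x, rss, success).
    """
    if model_kind == "single_static":
        lo, hi = _static_bounds(dose)
        best = _solve(_single_residual, [x0], lo, hi, args=(dose, y, v_max))
        if best is None:
            return x0, np.inf, False
        return best.x, float(2 * best.cost), bool(best.success)
    if model_kind == "single_dynamic":
        xs, rss, ok = [], 0.0, True
        for gi in range(n_groups):
            sel = codes == gi
            d_g, y_g = dose[sel], y[sel]
            lo, hi = _static_bounds(d_g)
            best = _solve(_single_residual, [x0[2 * gi:2 * gi + 2]], lo, hi,
                          args=(d_g, y_g, v_max))
            if best is None:
                ok = False
                xs.extend(x0[2 * gi:2 * gi + 2])
                continue
            ok = ok and bool(best.success)
            xs.extend(best.x)
            rss += float(2 * best.cost)
        return np.array(xs), rss, ok
    if model_kind == "two_population":
        lo, hi = _twopop_bounds(dose, n_groups)
        best = _solve(_twopop_residual, [x0], lo, hi,
                      args=(dose, y, codes, v_max))
        if best is None:
            return x0, np.inf, False
        return best.x, float(2 * best.cost), bool(best.success)
    raise ValueError(f"unknown model kind {model_kind!r}")


def _natural_params(model_kind, x, groups) -> dict:
    """Map a solver vector to named natural-space parameters."""
    if model_kind == "single_static":
        return {"ld50": float(x[0]), "slope": float(x[1])}
    if model_kind == "single_dynamic":
        out = {}
        for gi, g in enumerate(groups):
            out[f"ld50[{g}]"] = float(x[2 * gi])
            out[f"slope[{g}]"] = float(x[2 * gi + 1])
        return out
    if model_kind == "two_population":
        out = {
            "ld50_sens": float(x[0]),
            "ld50_res": float(x[0] + x[1]),
            "slope_sens": float(x[2]),
            "slope_res": float(x[3]),
        }
        for gi, g in enumerate(groups):
            out[f"f_sens[{g}]"] = float(x[4 + gi])
        return out
    raise ValueError(f"unknown model kind {model_kind!r}")
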