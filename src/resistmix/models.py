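"""Sigmoidal viability models for drug dose-response data.

Three nested structural models describe the fraction of cells viable,
``V(d)``, after exposure to a cytotoxic drug at dose ``d`` (µM):

* **single static** — one logistic curve shared by every assay group;
  the null model in which drug sensitivity does not change over time,
* **single dynamic** — an independent logistic curve per group (week),
* **two population** — a weighted sum of two *fixed* logistic states, a
  sensitive and a resistant one, whose mixing fraction varies by group.

Every curve has the form ``V(d) = V_max / (1 + exp(m * (d - c)))`` where
``c`` is the LD50 (dose of half-maximal viability, µM), ``m`` is the
slope of viability loss (1/µM; the reciprocal of the spread σ of the
underlying lethal-dose distribution), and ``V_max`` is the baseline
viability of the population in the absence of drug, normalising for
drug-independent cell death.

These are pure functions and frozen parameter containers; fitting lives
in :mod:`resistmix.fitting`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "SigmoidState",
    "SingleStaticParams",
    "SingleDynamicParams",
    "TwoPopulationParams",
    "logistic_viability",
    "mixture_viability",
    "evaluate_single",
    "evaluate_two_population",
    "sigma_from_slope",
]


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class SigmoidState:
    """One logistic drug-sensitivity state: LD50 ``ld50`` (µM) and slope
    ``slope`` (1/µM)."""

    ld50: float
    slope: float

    def __post_init__(self) -> None:
        _require_finite("ld50", self.ld50)
        _require_finite("slope", self.slope)
        if self.ld50 <= 0:
            raise ValueError(f"ld50 must be positive, got {self.ld50}")
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")


@dataclass(frozen=True)
class SingleStaticParams:
    """Parameters of the single static model: one curve for all groups."""

    ld50: float
    slope: float
    v_max: float = 1.0

    def __post_init__(self) -> None:
        _require_finite("ld50", self.ld50)
        _require_finite("slope", self.slope)
        _require_finite("v_max", self.v_max)
        if self.ld50 <= 0:
            raise ValueError(f"ld50 must be positive, got {self.ld50}")
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if not 0 < self.v_max <= 1:
            raise ValueError(f"v_max must lie in (0, 1], got {self.v_max}")

    @property
    def state(self) -> SigmoidState:
        return SigmoidState(self.ld50, self.slope)


@dataclass(frozen=True)
class SingleDynamicParams:
    """Parameters of the single dynamic model: one independent curve per
    assay group (week), all sharing ``v_max``.

    ``groups``, ``ld50`` and ``slope`` are aligned tuples.
    """

    groups: tuple
    ld50: tuple
    slope: tuple
    v_max: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "ld50", tuple(float(c) for c in self.ld50))
        object.__setattr__(self, "slope", tuple(float(m) for m in self.slope))
        if not self.groups:
            raise ValueError("at least one group is required")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        if not (len(self.groups) == len(self.ld50) == len(self.slope)):
            raise ValueError("groups, ld50 and slope must be aligned")
        for c, m in zip(self.ld50, self.slope):
            SigmoidState(c, m)  # validates positivity/finiteness
        if not 0 < self.v_max <= 1:
            raise ValueError(f"v_max must lie in (0, 1], got {self.v_max}")

    def curve(self, group) -> SingleStaticParams:
        """The per-group logistic curve, as a static parameter set."""
        try:
            i = self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None
        return SingleStaticParams(self.ld50[i], self.slope[i], self.v_max)


@dataclass(frozen=True)
class TwoPopulationParams:
    """Parameters of the two-population model.

    A sensitive and a resistant logistic state are fixed across groups;
    each group mixes them with sensitive fraction ``f_sens`` (the
    resistant fraction is ``1 - f_sens`` by construction).  The canonical
    state labelling ``sensitive.ld50 < resistant.ld50`` is enforced at
    construction so that state identities cannot silently switch.
    """

    sensitive: SigmoidState
    resistant: SigmoidState
    groups: tuple = ()
    f_sens: tuple = ()
    v_max: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "f_sens", tuple(float(f) for f in self.f_sens))
        if self.sensitive.ld50 >= self.resistant.ld50:
            raise ValueError(
                "canonical ordering requires sensitive.ld50 < resistant.ld50 "
                f"(got {self.sensitive.ld50} >= {self.resistant.ld50})"
            )
        if len(self.groups) != len(self.f_sens):
            raise ValueError("groups and f_sens must be aligned")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("group labels must be unique")
        for f in self.f_sens:
            if not (0.0 <= f <= 1.0) or not math.isfinite(f):
                raise ValueError(f"f_sens values must lie in [0, 1], got {f}")
        if not 0 < self.v_max <= 1:
            raise ValueError(f"v_max must lie in (0, 1], got {self.v_max}")

    def fraction_sensitive(self, group) -> float:
        try:
            i = self.groups.index(group)
        except ValueError:
            raise KeyError(f"unknown group {group!r}") from None
        return self.f_sens[i]

    def fraction_resistant(self, group) -> float:
        return 1.0 - self.fraction_sensitive(group)


def logistic_viability(dose, ld50: float, slope: float, v_max: float = 1.0):
    """Evaluate ``V_max / (1 + exp(slope * (dose - ld50)))``.

    Computed through the numerically stable logistic ``expit``, so doses
    arbitrarily far from the LD50 never overflow.  ``dose`` may be a
    scalar or array; doses must be non-negative and finite.
    """
    d = np.asarray(dose, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("doses must be finite")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    _require_finite("ld50", ld50)
    _require_finite("slope", slope)
    _require_finite("v_max", v_max)
    out = v_max * expit(-slope * (d - ld50))
    return float(out) if np.isscalar(dose) else out


def mixture_viability(dose, f_sens: float, sensitive: SigmoidState,
                      resistant: SigmoidState, v_max: float = 1.0):
    """Two-state mixture viability: a direct sum of the viability of each
    subpopulation weighted by its fraction.

    Unlike :class:`TwoPopulationParams` this functional form does not
    require the canonical LD50 ordering, which makes the symmetric
    degenerate cases (identical states, boundary fractions) expressible.
    """
    if not (0.0 <= f_sens <= 1.0):
        raise ValueError(f"f_sens must lie in [0, 1], got {f_sens}")
    vs = logistic_viability(dose, sensitive.ld50, sensitive.slope, 1.0)
    vr = logistic_viability(dose, resistant.ld50, resistant.slope, 1.0)
    out = v_max * (f_sens * np.asarray(vs) + (1.0 - f_sens) * np.asarray(vr))
    return float(out) if np.isscalar(dose) else out


def evaluate_single(params, dose, group=None):
    """Viability of a single-population model at ``dose``.

    ``params`` is a :class:`SingleStaticParams`, or a
    :class:`SingleDynamicParams` together with the ``group`` whose curve
    should be evaluated.
    """
    if isinstance(params, SingleDynamicParams):
        if group is None:
            raise ValueError("a group label is required for the dynamic model")
        params = params.curve(group)
    return logistic_viability(dose, params.ld50, params.slope, params.v_max)


def evaluate_two_population(params: TwoPopulationParams, dose, group):
    """Viability of the two-population model at ``dose`` for ``group``."""
    f = params.fraction_sensitive(group)
    return mixture_viability(dose, f, params.sensitive, params.resistant,
                             params.v_max)


def sigma_from_slope(m: float) -> float:
    """Spread σ (µM) of the lethal-dose distribution from the slope: σ = 1/m."""
    m = _require_finite("slope", m)
    if m <= 0:
        raise ValueError(f"slope must be positive, got {m}")
    return 1.0 / m
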