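"""Synthetic dose-response assay generation.

The experimental data this pipeline was designed for are not publicly
deposited, so this module generates datasets with the same structure: a
fixed dose panel, several assay groups (weeks after a drug pulse, or
known sensitive/resistant mixtures), a few replicates per (group, dose)
cell, and measurement noise whose spread depends on dose.

Noise model: each record is the generative model viability plus
zero-mean Gaussian noise with a per-dose standard deviation, truncated
to [0, 1] (the range of a viability fraction).  Randomness flows from a
single root seed; every (group, dose) cell draws from its own
deterministically derived stream, so a dataset is reproducible
bit-for-bit from the seed alone and is unchanged by adding groups after
it in the design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import reference
from .datasets import DoseResponseDataset
from .models import SigmoidState, TwoPopulationParams, logistic_viability, \
    mixture_viability

__all__ = [
    "NoiseModel",
    "AssayDesign",
    "simulate_assay",
    "estimate_noise_from_data",
    "make_mixture_design",
    "make_time_course_design",
]


@dataclass(frozen=True)
class NoiseModel:
    """Per-dose measurement noise for viability readings.

    ``sd_at_dose`` maps dose (µM) to the standard deviation of the
    viability reading; doses not in the table are linearly interpolated
    (constant extrapolation at the ends).  ``scale`` is used instead when
    the table is empty — a flat noise profile.
    """

    sd_at_dose: Mapping[float, float] = field(default_factory=dict)
    scale: float = reference.DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sd_at_dose",
            {float(d): float(s) for d, s in dict(self.sd_at_dose).items()},
        )
        if any(s < 0 or not math.isfinite(s) for s in self.sd_at_dose.values()):
            raise ValueError("noise standard deviations must be >= 0")
        if self.scale < 0 or not math.isfinite(self.scale):
            raise ValueError("noise scale must be >= 0")

    @classmethod
    def constant(cls, sd: float, seed: int = 0) -> "NoiseModel":
        return cls(sd_at_dose={}, scale=sd, seed=seed)

    def sd(self, dose) -> np.ndarray:
        d = np.atleast_1d(np.asarray(dose, dtype=float))
        if not self.sd_at_dose:
            return np.full(d.shape, self.scale)
        known = np.array(sorted(self.sd_at_dose))
        sds = np.array([self.sd_at_dose[k] for k in known])
        return np.interp(d, known, sds)


@dataclass(frozen=True)
class AssayDesign:
    """Dose panel, replicate count, and one generative curve per group.

    ``curves`` is an ordered mapping from group label to a callable
    returning the noise-free model viability at an array of doses.
    """

    doses: tuple
    replicates: int
    curves: "dict[object, Callable[[np.ndarray], np.ndarray]]"

    def __post_init__(self) -> None:
        doses = tuple(float(d) for d in self.doses)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "curves", dict(self.curves))
        if len(doses) < 2 or any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if doses[0] != 0.0 or any(d < 0 for d in doses):
            raise ValueError("dose panel must start at 0 and be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.curves:
            raise ValueError("at least one group is required")

    @property
    def groups(self) -> tuple:
        return tuple(self.curves)

    @property
    def n_records(self) -> int:
        return len(self.doses) * self.replicates * len(self.curves)


def simulate_assay(design: AssayDesign, noise: NoiseModel) -> DoseResponseDataset:
    """Draw one synthetic dataset from ``design`` under ``noise``.

    Identical (design, noise) including the seed yields an identical
    dataset.
    """
    doses = np.asarray(design.doses)
    rows = []
    for gi, (group, curve) in enumerate(design.curves.items()):
        mean = np.asarray(curve(doses), dtype=float)
        sd = noise.sd(doses)
        for di, d in enumerate(doses):
            stream = np.random.default_rng(
                np.random.SeedSequence(noise.seed, spawn_key=(gi, di))
            )
            draws = mean[di] + sd[di] * stream.standard_normal(design.replicates)
            draws = np.clip(draws, 0.0, 1.0)
            for r, v in enumerate(draws, start=1):
                rows.append((group, float(d), r, float(v)))
    return DoseResponseDataset(
        pd.DataFrame(rows, columns=["group", "dose_uM", "replicate", "viability"])
    )


def estimate_noise_from_data(dataset: DoseResponseDataset,
                             seed: int = 0) -> NoiseModel:
    """Per-dose noise sd estimated from replicate scatter.

    At each dose the within-(group, dose) sample variances are pooled
    across groups (weighted by degrees of freedom).  Doses where every
    cell is a singleton carry no information; their sd is interpolated
    from neighbouring doses.
    """
    frame = dataset.frame
    sd_at_dose: dict[float, float] = {}
    singletons: list[float] = []
    for dose, sub in frame.groupby("dose_uM"):
        num = 0.0
        dof = 0
        for _, cell in sub.groupby("group"):
            n = len(cell)
            if n >= 2:
                num += (n - 1) * float(cell["viability"].var(ddof=1))
                dof += n - 1
        if dof > 0:
            sd_at_dose[float(dose)] = math.sqrt(num / dof)
        else:
            singletons.append(float(dose))
    if not sd_at_dose:
        raise ValueError(
            "no dose has replicated measurements; noise is not estimable"
        )
    if singletons:
        known = np.array(sorted(sd_at_dose))
        sds = np.array([sd_at_dose[k] for k in known])
        for d in singletons:
            sd_at_dose[d] = float(np.interp(d, known, sds))
    return NoiseModel(sd_at_dose=sd_at_dose, seed=seed)


def _mixture_curve(f_sens: float, sensitive: SigmoidState,
                   resistant: SigmoidState, v_max: float):
    def curve(doses: np.ndarray) -> np.ndarray:
        return np.asarray(
            mixture_viability(doses, f_sens, sensitive, resistant, v_max)
        )
    return curve


def make_mixture_design(
    resistant_fractions,
    params: TwoPopulationParams,
    doses=reference.DOSE_PANEL,
    replicates: int = reference.DEFAULT_REPLICATES,
) -> AssayDesign:
    """Design with one group per known sensitive/resistant mixture.

    ``resistant_fractions`` are the mixed-in resistant proportions (the
    canonical validation series is 0, 0.25, 0.5, 0.75, 1); each group's
    generative curve is the two-state mixture with sensitive fraction
    ``1 - fraction``.  Group labels carry the fraction, e.g. ``res_0.25``.
    """
    fractions = [float(f) for f in resistant_fractions]
    if not fractions:
        raise ValueError("at least one mixture fraction is required")
    if any(not 0 <= f <= 1 for f in fractions):
        raise ValueError("resistant fractions must lie in [0, 1]")
    curves = {
        f"res_{f:g}": _mixture_curve(1.0 - f, params.sensitive,
                                     params.resistant, params.v_max)
        for f in fractions
    }
    return AssayDesign(doses=tuple(doses), replicates=replicates, curves=curves)


def make_time_course_design(
    f_sens_trajectory,
    params: TwoPopulationParams,
    doses=reference.DOSE_PANEL,
    replicates: int = reference.DEFAULT_REPLICATES,
) -> AssayDesign:
    """Design emulating the weekly assay course: one group per week,
    weeks labelled 1..n, with the given sensitive fraction per week."""
    traj = [float(f) for f in f_sens_trajectory]
    if not traj:
        raise ValueError("trajectory must contain at least one week")
    if any(not 0 <= f <= 1 for f in traj):
        raise ValueError("sensitive fractions must lie in [0, 1]")
    curves = {
        week: _mixture_curve(f, params.sensitive, params.resistant, params.v_max)
        for week, f in enumerate(traj, start=1)
    }
    return AssayDesign(doses=tuple(doses), replicates=replicates, curves=curves)


def single_population_design(
    ld50: float,
    slope: float,
    v_max: float = 1.0,
    doses=reference.DOSE_PANEL,
    replicates: int = reference.DEFAULT_REPLICATES,
    group="pooled",
) -> AssayDesign:
    """One-group design generated from a single logistic curve."""
    def curve(d: np.ndarray) -> np.ndarray:
        return np.asarray(logistic_viability(d, ld50, slope, v_max))
    return AssayDesign(doses=tuple(doses), replicates=replicates,
                       curves={group: curve})
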