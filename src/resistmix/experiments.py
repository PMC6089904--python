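"""Parameter-recovery experiments on synthetic assays.

Each experiment simulates dose-response data from published point
estimates for the MCF-7 / MCF-7-ADR doxorubicin system
(:mod:`resistmix.reference`), refits the matching model, and averages
the recovered LD50s over independent noise realisations.  They are the
computational backbone of the acceptance checks and are runnable on
their own.
"""

from __future__ import annotations

import numpy as np

from . import reference
from .fitting import fit_single_static, fit_two_population
from .models import TwoPopulationParams
from .simulate import NoiseModel, make_time_course_design, \
    single_population_design, simulate_assay

__all__ = [
    "recover_two_population_ld50s",
    "recover_wildtype_ld50",
    "recover_resistant_line_ld50",
]


def _derived_seed(root: int, stream: int, i: int) -> int:
    ss = np.random.SeedSequence(root, spawn_key=(stream, i))
    return int(ss.generate_state(1)[0] % (2**31))


def recover_two_population_ld50s(seed: int = 0, n_seeds: int = 25,
                                 noise_sd: float = 0.03,
                                 replicates: int = reference.DEFAULT_REPLICATES,
                                 v_max: float = 0.9) -> dict:
    """Joint two-population recovery over an 8-week course.

    Truth: sensitive/resistant LD50s 22.4 / 79.7 µM, slopes
    0.060 / 0.028 1/µM, sensitive fraction varying per week over the
    default trajectory.  Returns the mean recovered LD50s over
    ``n_seeds`` simulated datasets.
    """
    traj = reference.DEFAULT_FSENS_TRAJECTORY
    truth = TwoPopulationParams(
        sensitive=reference.SENSITIVE_STATE,
        resistant=reference.RESISTANT_STATE,
        groups=tuple(range(1, len(traj) + 1)),
        f_sens=traj, v_max=v_max,
    )
    design = make_time_course_design(traj, truth,
                                     doses=reference.DOSE_PANEL,
                                     replicates=replicates)
    res, sens = [], []
    for i in range(n_seeds):
        noise = NoiseModel.constant(noise_sd,
                                    seed=_derived_seed(seed, 1, i))
        ds = simulate_assay(design, noise)
        fit = fit_two_population(ds, v_max=v_max)
        res.append(fit.params.resistant.ld50)
        sens.append(fit.params.sensitive.ld50)
    return {
        "ld50_res": float(np.mean(res)),
        "ld50_sens": float(np.mean(sens)),
        "ld50_res_estimates": res,
        "ld50_sens_estimates": sens,
        "truth": {"ld50_res": truth.resistant.ld50,
                  "ld50_sens": truth.sensitive.ld50},
        "n_records": design.n_records,
        "n_seeds": n_seeds,
    }


def _recover_single(ld50, slope, v_max, doses, noise_sd, seed, stream,
                    n_seeds, replicates):
    design = single_population_design(ld50, slope, v_max, doses=doses,
                                      replicates=replicates)
    estimates = []
    for i in range(n_seeds):
        noise = NoiseModel.constant(noise_sd,
                                    seed=_derived_seed(seed, stream, i))
        ds = simulate_assay(design, noise)
        fit = fit_single_static(ds, v_max=v_max)
        estimates.append(fit.params.ld50)
    return {
        "ld50": float(np.mean(estimates)),
        "ld50_estimates": estimates,
        "truth": {"ld50": ld50},
        "n_records": design.n_records,
        "n_seeds": n_seeds,
    }


def recover_wildtype_ld50(seed: int = 0, n_seeds: int = 25,
                          noise_sd: float = 0.05,
                          replicates: int = reference.DEFAULT_REPLICATES) -> dict:
    """Single-static recovery at the untreated wild-type MCF-7 truth
    (LD50 37.0 µM, slope 0.055 1/µM, V_max 0.9) on the standard panel."""
    return _recover_single(reference.MCF7_LD50, reference.MCF7_SLOPE, 0.9,
                           reference.DOSE_PANEL, noise_sd, seed, 2,
                           n_seeds, replicates)


def recover_resistant_line_ld50(seed: int = 0, n_seeds: int = 25,
                                noise_sd: float = 0.03,
                                replicates: int = reference.DEFAULT_REPLICATES) -> dict:
    """Single-static recovery at the pure MCF-7/ADR truth (LD50
    187.5 µM, slope 0.034 1/µM, V_max 0.95) on the extended dose panel —
    the standard panel tops out at 144 µM, below this line's LD50, so
    higher doses are required to see the downslope."""
    doses = reference.DOSE_PANEL + reference.EXTENDED_DOSES
    return _recover_single(reference.ADR_LD50, reference.ADR_SLOPE, 0.95,
                           doses, noise_sd, seed, 3, n_seeds, replicates)
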