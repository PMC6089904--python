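"""End-to-end analysis pipeline: fit → compare → bootstrap → dynamics.

A :class:`RunConfig` (built directly or loaded from YAML) names the
input tables and the statistical settings; :func:`run_pipeline` executes
the stages and writes CSV reports plus a deterministic JSON run log
(seed, library versions, configuration, winner).  Identical config and
seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .datasets import DoseResponseDataset
from .dynamics import growth_rates_from_counts, project_totals, \
    subpopulation_counts
from .fitting import MODEL_KINDS, estimate_vmax
from .selection import bootstrap_ci, compare_models

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Inputs and settings of one pipeline run."""

    assay_csv: str
    output_dir: str
    counts_csv: Optional[str] = None
    models: tuple = MODEL_KINDS
    v_max: Optional[float] = None
    n_boot: int = 500
    ci_level: float = 0.95
    seed: int = 0
    delta_days: float = 7.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["models"] = list(self.models)
        return out


def _stage(name):
    def decorate(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
        return wrapper
    return decorate


@_stage("read")
def _read_inputs(config):
    dataset = DoseResponseDataset.read_csv(config.assay_csv)
    counts = None
    if config.counts_csv is not None:
        counts = pd.read_csv(config.counts_csv)
    return dataset, counts


@_stage("fit/compare")
def _fit_and_compare(dataset, config, v_max):
    return compare_models(dataset, v_max=v_max, models=config.models)


@_stage("bootstrap")
def _bootstrap_winner(dataset, comparison, config, v_max):
    winner = comparison.winner
    return bootstrap_ci(dataset, winner, v_max=v_max, n_boot=config.n_boot,
                        level=config.ci_level, seed=config.seed,
                        fit=comparison.fits[winner])


@_stage("dynamics")
def _dynamics(counts, comparison, boot, config, dataset, v_max):
    if "two_population" not in comparison.fits:
        raise ValueError(
            "dynamics requires the two-population model in 'models'"
        )
    fit = comparison.fits["two_population"]
    rates = growth_rates_from_counts(counts, delta_days=config.delta_days,
                                     level=config.ci_level)
    first_week = counts["week"].min()
    n0 = float(counts.loc[counts["week"] == first_week, "count"].mean())
    totals = project_totals(n0, rates, delta_days=config.delta_days)

    if comparison.winner == "two_population":
        ci = boot
    else:
        ci = bootstrap_ci(dataset, "two_population", v_max=v_max,
                          n_boot=config.n_boot, level=config.ci_level,
                          seed=config.seed, fit=fit)
    rows = []
    for g, f_sens in fit.per_group_fractions.items():
        week = int(float(g))
        row = {"week": week, "f_res": 1.0 - f_sens}
        name = f"f_sens[{g}]"
        if name in ci.table.index:
            lo_s, hi_s = ci.interval(name)
            row["lower"], row["upper"] = 1.0 - hi_s, 1.0 - lo_s
        else:
            row["lower"] = row["upper"] = row["f_res"]
        rows.append(row)
    fractions = pd.DataFrame(rows).set_index("week").sort_index()
    shared = totals.index.intersection(fractions.index)
    if shared.empty:
        raise ValueError(
            "no shared weeks between the counts table and the fitted groups"
        )
    return subpopulation_counts(totals.loc[shared], fractions.loc[shared])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the pipeline and write the report bundle.

    Writes ``comparison.csv``, ``parameters.csv``, ``ci.csv``,
    optionally ``trajectory.csv``, and ``run_log.json`` to
    ``config.output_dir``.  Returns the output paths keyed by stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset, counts = _read_inputs(config)
    try:
        v_max = config.v_max if config.v_max is not None \
            else estimate_vmax(dataset)
    except ValueError as err:
        raise PipelineError(f"stage 'v_max' failed: {err}") from err

    comparison = _fit_and_compare(dataset, config, v_max)
    boot = _bootstrap_winner(dataset, comparison, config, v_max)

    paths = {}
    comparison.table.to_csv(outdir / "comparison.csv")
    paths["comparison"] = str(outdir / "comparison.csv")

    param_rows = []
    for kind, fit in comparison.fits.items():
        for name, value in fit.parameter_dict().items():
            param_rows.append({"model": kind, "parameter": name,
                               "value": value})
    pd.DataFrame(param_rows).to_csv(outdir / "parameters.csv", index=False)
    paths["parameters"] = str(outdir / "parameters.csv")

    boot.table.to_csv(outdir / "ci.csv", index_label="parameter")
    paths["ci"] = str(outdir / "ci.csv")

    if counts is not None:
        trajectory = _dynamics(counts, comparison, boot, config, dataset,
                               v_max)
        trajectory.to_csv(outdir / "trajectory.csv", index_label="week")
        paths["trajectory"] = str(outdir / "trajectory.csv")

    from . import __version__
    import numpy
    import scipy

    log = {
        "config": config.to_dict(),
        "seed": config.seed,
        "v_max": v_max,
        "winner": comparison.winner,
        "bootstrap_failed": boot.n_failed,
        "versions": {
            "resistmix": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    paths["run_log"] = str(outdir / "run_log.json")
    return paths
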