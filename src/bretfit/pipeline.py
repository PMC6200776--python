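"""Validated run configuration and the end-to-end analysis pipeline.

``run_pipeline`` ties the stages together — optional simulation, ratio
computation, baseline correction, the mode-appropriate fit, aggregation —
and returns a JSON-serializable result bundle with a provenance block
(config hash, seed, library versions) sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from contextlib import contextmanager
from pathlib import Path
from typing import Literal, Optional

import lmfit
import numpy as np
import pandas as pd
import scipy
import statsmodels
from pydantic import BaseModel, ConfigDict, field_validator

from . import __version__, fitting, simulate
from .plate_io import ConfigurationError, read_plate_csv, write_plate_csv

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "format_report"]

NM = 1e-9


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run.

    Unknown keys are rejected.  Either ``input`` (an existing plate CSV)
    must be given, or ``simulate=True`` to generate the default design for
    ``mode`` with the noise/seed block below.
    """

    model_config = ConfigDict(extra="forbid")

    mode: Literal["saturation", "association", "competition", "concentration_response"]
    input: Optional[Path] = None
    output: Optional[Path] = None
    simulate: bool = False
    simulated_csv: Optional[Path] = None
    seed: int = 0
    noise_sd: Optional[float] = None
    n_experiments: int = 5
    replicates: int = 2
    probe_kd_nM: Optional[float] = None
    free_hill: bool = False
    verbosity: Literal["debug", "info", "warning"] = "info"

    @field_validator("probe_kd_nM")
    @classmethod
    def _positive_kd(cls, v):
        if v is not None and v <= 0:
            raise ValueError("probe_kd_nM must be > 0")
        return v


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


def provenance(config: RunConfig) -> dict:
    return {
        "config": config.model_dump(mode="json"),
        "config_sha256": _config_hash(config),
        "seed": config.seed,
        "versions": {
            "bretfit": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "lmfit": lmfit.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    logger.info("stage %s: done", name)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run and return the result bundle.

    Stages: ``simulate``/``load`` -> ``ratio`` -> ``baseline`` (association
    only) -> ``fit`` -> ``aggregate``/serialize.  A failure in any stage
    raises :class:`PipelineError` naming that stage.
    """
    logging.basicConfig(level=config.verbosity.upper())
    bundle: dict = {"provenance": provenance(config)}

    if config.simulate:
        with _stage("simulate"):
            design = simulate.default_design(
                config.mode,
                seed=config.seed,
                noise_sd=config.noise_sd,
                n_experiments=config.n_experiments,
                replicates=config.replicates,
            )
            table = simulate.simulate_plate(design)
            if config.simulated_csv is not None:
                write_plate_csv(table, config.simulated_csv)
    elif config.input is not None:
        with _stage("load"):
            table = read_plate_csv(config.input)
    else:
        raise ConfigurationError("RunConfig needs either input= or simulate=True")

    with _stage("ratio"):
        table = fitting.compute_bret_ratio(table)

    if config.mode == "association":
        with _stage("baseline"):
            table = fitting.baseline_correct(table)

    with _stage("fit"):
        if config.mode == "saturation":
            summary = fitting.fit_saturation(table)
            bundle["results"] = summary.to_dict()
        elif config.mode == "association":
            summary = fitting.fit_association_global(table)
            bundle["results"] = summary.to_dict()
        elif config.mode == "competition":
            if config.probe_kd_nM is None:
                raise ConfigurationError(
                    "competition analysis requires probe_kd_nM (probe Kd from "
                    "a saturation experiment)"
                )
            per_exp, summary = fitting.fit_competition(
                table, config.probe_kd_nM * NM, free_hill=config.free_hill
            )
            bundle["results"] = summary.to_dict()
            bundle["results"]["per_experiment_detail"] = [r.to_dict() for r in per_exp]
        else:
            summary = fitting.fit_concentration_response(
                table, free_hill=config.free_hill
            )
            bundle["results"] = summary.to_dict()

    bundle["mode"] = config.mode
    if config.output is not None:
        with _stage("write"):
            Path(config.output).write_text(json.dumps(bundle, indent=2) + "\n")
    return bundle


def format_report(bundle: dict) -> str:
    """Human-readable summary of a result bundle."""
    lines = [f"bretfit report — mode: {bundle.get('mode', '?')}"]
    prov = bundle.get("provenance", {})
    lines.append(f"seed: {prov.get('seed')}  config: {prov.get('config_sha256', '')[:12]}")
    results = bundle.get("results", {})
    n = results.get("n_experiments")
    lines.append(f"experiments aggregated: {n}")
    mean, sem = results.get("mean", {}), results.get("sem", {})
    for key, value in mean.items():
        s = sem.get(key)
        sem_txt = "n/a" if s is None else f"{s:.4g}"
        lines.append(f"  {key:>16s} = {value:.6g} ± {sem_txt} (SEM)")
    for fit in results.get("per_experiment", []):
        if not fit.get("converged", True):
            lines.append(
                f"  [!] experiment {fit.get('experiment_id')} flagged: "
                f"{'; '.join(fit.get('messages', [])) or 'not converged'}"
            )
    return "\n".join(lines)
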