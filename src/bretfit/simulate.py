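"""Synthetic plate-data generator for the four NanoBRET assay designs.

Each generator emulates the layout of a live-cell plate-reader binding
experiment and draws well-level noise on the BRET-ratio scale:

* ``saturation`` — endpoint reads over a probe dilution series, each
  concentration paired with a non-specific-binding (NSB) well containing
  100 nM unlabeled ligand; duplicate wells; 5 independent experiments.
* ``association`` — time courses sampled every 30 s for 20 min at ~5 probe
  concentrations (1-20 nM), plus ligand-free vehicle wells for baseline
  correction.
* ``competition`` — endpoint reads of a competitor dilution series against
  several fixed probe concentrations.
* ``concentration_response`` — endpoint functional responses following a
  logistic curve.

Noise is additive iid Gaussian on the ratio (or response) scale, the
simplest model consistent with mean +/- SEM summaries of ratio data.  The
per-experiment random streams are split with ``numpy.random.SeedSequence``
so increasing ``n_experiments`` never perturbs earlier experiments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import models
from .plate_io import MODES, PLATE_COLUMNS, ConfigurationError, validate_plate

__all__ = [
    "DEFAULT_BASELINE",
    "DEFAULT_BMAX",
    "AssociationTruth",
    "CompetitionTruth",
    "SimulationDesign",
    "default_design",
    "simulate_plate",
    "simulate_saturation_plate",
    "simulate_association_plate",
    "simulate_competition_plate",
    "simulate_cr_plate",
    "emit_channels",
]

# Raw BRET ratio magnitudes are instrument-dependent; these arbitrary but
# fixed defaults put the specific window at 0.02 ratio units over a 0.05
# baseline.  Every fitted affinity/rate is invariant to them.
DEFAULT_BASELINE = 0.05
DEFAULT_BMAX = 0.02
#: default noise standard deviation: 5% of the specific window
DEFAULT_NOISE_SD = 0.05 * DEFAULT_BMAX


@dataclass(frozen=True)
class AssociationTruth:
    """Ground truth for kinetic simulations: rate constants plus a single
    shared signal amplitude and a vehicle baseline."""

    rates: models.KineticRateParams
    bmax: float = DEFAULT_BMAX
    baseline: float = DEFAULT_BASELINE


@dataclass(frozen=True)
class CompetitionTruth:
    """Ground truth for competition simulations: the probe's equilibrium
    binding parameters and the competitor's affinity ``ki`` (M)."""

    probe: models.EquilibriumBindingParams
    ki: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.ki) and self.ki > 0):
            raise ConfigurationError(f"ki must be > 0, got {self.ki!r}")


@dataclass(frozen=True)
class SimulationDesign:
    """Full specification of one simulated multi-experiment assay.

    Concentrations and ``ki`` are molar; times are minutes.  ``seed``
    fixes the entire output: identical designs produce byte-identical
    CSV files.
    """

    mode: str
    ground_truth: object
    probe_concs: tuple = ()
    competitor_concs: Optional[tuple] = None
    timepoints: Optional[tuple] = None
    replicates: int = 2
    n_experiments: int = 5
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    include_nsb: bool = True
    include_vehicle: bool = True

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigurationError(
                f"unknown mode {self.mode!r}; valid modes: {', '.join(MODES)}"
            )
        object.__setattr__(self, "probe_concs", tuple(float(c) for c in self.probe_concs))
        if not self.probe_concs:
            raise ConfigurationError("probe_concs must be nonempty")
        min_allowed = 0.0 if self.mode == "concentration_response" else None
        for c in self.probe_concs:
            if not math.isfinite(c) or c < 0 or (min_allowed is None and c == 0):
                raise ConfigurationError(f"invalid probe concentration {c!r}")
        if self.competitor_concs is not None:
            object.__setattr__(
                self, "competitor_concs", tuple(float(c) for c in self.competitor_concs)
            )
            if any(not math.isfinite(c) or c < 0 for c in self.competitor_concs):
                raise ConfigurationError("competitor concentrations must be >= 0")
        if self.timepoints is not None:
            object.__setattr__(
                self, "timepoints", tuple(float(t) for t in self.timepoints)
            )
            if any(t < 0 for t in self.timepoints):
                raise ConfigurationError("timepoints must be >= 0")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.n_experiments < 1:
            raise ConfigurationError("n_experiments must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.mode == "association" and len(self.probe_concs) < 2:
            warnings.warn(
                "association design with a single probe concentration: "
                "kon and koff will not be separately identifiable downstream",
                stacklevel=2,
            )


# --- ground truths used as the study conditions for the default designs ---

_NRP1_RATES = models.KineticRateParams(kon=7.11e7, koff=0.26)
_NRP1_SATURATION = models.EquilibriumBindingParams(
    kd=4.41e-9, bmax=DEFAULT_BMAX, ns_slope=1.0e5, baseline=DEFAULT_BASELINE
)
_NRP1_COMPETITOR_KI = 10 ** -9.54
_CR_TRUTH = models.ConcentrationResponseParams(
    ec50=10 ** -8.16, emax=100.0, basal=0.0, hill=1.0
)


def default_design(
    mode: str,
    *,
    seed: int = 0,
    noise_sd: Optional[float] = None,
    n_experiments: int = 5,
    replicates: int = 2,
) -> SimulationDesign:
    """A ready-to-run design for each assay mode.

    The defaults mirror the study layouts the generator emulates: 8-point
    saturation series (0.1-30 nM) with paired NSB wells; association at
    1, 2.5, 5, 10 and 20 nM sampled every 30 s for 20 min; competition at
    probe concentrations 0.5-5 nM against an 11-point competitor series;
    a 9-point concentration-response series.  Ground truths are the NRP1
    parameter set (Kd 4.41 nM; kon 7.11e7 M^-1 min^-1; koff 0.26 min^-1;
    competitor pKi 9.54; pEC50 8.16).
    """
    if mode == "saturation":
        return SimulationDesign(
            mode=mode,
            ground_truth=_NRP1_SATURATION,
            probe_concs=tuple(np.geomspace(0.1e-9, 30e-9, 8)),
            replicates=replicates,
            n_experiments=n_experiments,
            noise_sd=DEFAULT_NOISE_SD if noise_sd is None else noise_sd,
            seed=seed,
        )
    if mode == "association":
        return SimulationDesign(
            mode=mode,
            ground_truth=AssociationTruth(rates=_NRP1_RATES),
            probe_concs=(1e-9, 2.5e-9, 5e-9, 10e-9, 20e-9),
            timepoints=tuple(np.arange(0.0, 20.0 + 1e-9, 0.5)),
            replicates=1,
            n_experiments=n_experiments,
            noise_sd=DEFAULT_NOISE_SD if noise_sd is None else noise_sd,
            seed=seed,
        )
    if mode == "competition":
        return SimulationDesign(
            mode=mode,
            ground_truth=CompetitionTruth(
                probe=_NRP1_SATURATION, ki=_NRP1_COMPETITOR_KI
            ),
            probe_concs=(0.5e-9, 1e-9, 2e-9, 3e-9, 5e-9),
            competitor_concs=(0.0,) + tuple(np.geomspace(1e-11, 1e-7, 11)),
            replicates=replicates,
            n_experiments=n_experiments,
            noise_sd=DEFAULT_NOISE_SD if noise_sd is None else noise_sd,
            seed=seed,
        )
    if mode == "concentration_response":
        return SimulationDesign(
            mode=mode,
            ground_truth=_CR_TRUTH,
            probe_concs=(0.0,) + tuple(np.geomspace(1e-11, 1e-6, 9)),
            replicates=replicates,
            n_experiments=n_experiments,
            noise_sd=(0.05 * _CR_TRUTH.emax) if noise_sd is None else noise_sd,
            seed=seed,
        )
    raise ConfigurationError(f"unknown mode {mode!r}")


def _experiment_rngs(design: SimulationDesign):
    children = np.random.SeedSequence(design.seed).spawn(design.n_experiments)
    return [np.random.default_rng(c) for c in children]


def _record(exp_id, mode, well_id, well_type, probe_M, value, *, competitor_M=None, t=None):
    return {
        "experiment_id": exp_id,
        "mode": mode,
        "well_id": well_id,
        "well_type": well_type,
        "probe_conc_nM": probe_M * 1e9,
        "competitor_conc_nM": np.nan if competitor_M is None else competitor_M * 1e9,
        "time_min": np.nan if t is None else t,
        "donor_em": np.nan,
        "acceptor_em": np.nan,
        "bret_ratio": value,
    }


def _to_table(rows) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=PLATE_COLUMNS)
    return validate_plate(table)


def _require_truth(design: SimulationDesign, kind, mode: str):
    if design.mode != mode:
        raise ConfigurationError(
            f"design mode is {design.mode!r}; this generator needs {mode!r}"
        )
    if not isinstance(design.ground_truth, kind):
        raise ConfigurationError(
            f"{mode} simulation needs a {kind.__name__} ground truth, "
            f"got {type(design.ground_truth).__name__}"
        )
    return design.ground_truth


def simulate_saturation_plate(design: SimulationDesign) -> pd.DataFrame:
    """Endpoint saturation plate with paired total/NSB wells."""
    gt = _require_truth(design, models.EquilibriumBindingParams, "saturation")
    well_types = ("total", "nsb") if design.include_nsb else ("total",)
    rows = []
    for e, rng in enumerate(_experiment_rngs(design), start=1):
        exp, widx = f"E{e:02d}", 0
        for L in design.probe_concs:
            for _rep in range(design.replicates):
                for wt in well_types:
                    mean = (
                        models.total_signal_eq(L, gt)
                        if wt == "total"
                        else gt.baseline + gt.ns_slope * L
                    )
                    widx += 1
                    rows.append(
                        _record(
                            exp, "saturation", f"{exp}-W{widx:04d}", wt, L,
                            mean + rng.normal(0.0, design.noise_sd),
                        )
                    )
    return _to_table(rows)


def simulate_association_plate(design: SimulationDesign) -> pd.DataFrame:
    """Kinetic association plate: time series per concentration plus
    ligand-free vehicle wells carrying only baseline + noise."""
    gt = _require_truth(design, AssociationTruth, "association")
    timepoints = design.timepoints
    if timepoints is None:
        timepoints = tuple(np.arange(0.0, 20.0 + 1e-9, 0.5))
    rows = []
    for e, rng in enumerate(_experiment_rngs(design), start=1):
        exp, widx = f"E{e:02d}", 0
        for L in design.probe_concs:
            for _rep in range(design.replicates):
                widx += 1
                wid = f"{exp}-W{widx:04d}"
                for t in timepoints:
                    mean = gt.baseline + models.association_signal(t, L, gt.rates, gt.bmax)
                    rows.append(
                        _record(exp, "association", wid, "total", L,
                                mean + rng.normal(0.0, design.noise_sd), t=t)
                    )
        if design.include_vehicle:
            for _rep in range(design.replicates):
                widx += 1
                wid = f"{exp}-W{widx:04d}"
                for t in timepoints:
                    rows.append(
                        _record(exp, "association", wid, "vehicle", 0.0,
                                gt.baseline + rng.normal(0.0, design.noise_sd), t=t)
                    )
    return _to_table(rows)


def simulate_competition_plate(design: SimulationDesign) -> pd.DataFrame:
    """Endpoint competition plate at fixed probe concentrations.

    The expected curve at probe concentration L has top equal to the
    probe-only equilibrium signal, bottom equal to the non-specific level,
    and IC50 = Ki (1 + L/Kd).
    """
    gt = _require_truth(design, CompetitionTruth, "competition")
    if not design.competitor_concs:
        raise ConfigurationError("competition design requires competitor_concs")
    rows = []
    for e, rng in enumerate(_experiment_rngs(design), start=1):
        exp, widx = f"E{e:02d}", 0
        for L in design.probe_concs:
            curve = models.CompetitionCurveParams(
                ic50=models.ic50_from_ki(gt.ki, L, gt.probe.kd),
                top=models.total_signal_eq(L, gt.probe),
                bottom=gt.probe.baseline + gt.probe.ns_slope * L,
                hill=1.0,
            )
            for I in design.competitor_concs:
                for _rep in range(design.replicates):
                    widx += 1
                    rows.append(
                        _record(exp, "competition", f"{exp}-W{widx:04d}", "total", L,
                                models.competition_signal(I, curve)
                                + rng.normal(0.0, design.noise_sd),
                                competitor_M=I)
                    )
    return _to_table(rows)


def simulate_cr_plate(design: SimulationDesign) -> pd.DataFrame:
    """Endpoint concentration-response plate following a logistic curve."""
    gt = _require_truth(design, models.ConcentrationResponseParams, "concentration_response")
    rows = []
    for e, rng in enumerate(_experiment_rngs(design), start=1):
        exp, widx = f"E{e:02d}", 0
        for conc in design.probe_concs:
            for _rep in range(design.replicates):
                widx += 1
                rows.append(
                    _record(exp, "concentration_response", f"{exp}-W{widx:04d}",
                            "total", conc,
                            models.logistic_response(conc, gt)
                            + rng.normal(0.0, design.noise_sd))
                )
    return _to_table(rows)


_GENERATORS = {
    "saturation": simulate_saturation_plate,
    "association": simulate_association_plate,
    "competition": simulate_competition_plate,
    "concentration_response": simulate_cr_plate,
}


def simulate_plate(design: SimulationDesign) -> pd.DataFrame:
    """Dispatch to the generator for ``design.mode``."""
    return _GENERATORS[design.mode](design)


def emit_channels(
    table: pd.DataFrame,
    donor_level: float = 1e6,
    seed: int = 0,
    donor_cv: float = 0.0,
) -> pd.DataFrame:
    """Fill donor/acceptor emission counts consistent with each ratio.

    Donor counts are drawn around ``donor_level`` (coefficient of
    variation ``donor_cv``); acceptor counts are ``bret_ratio * donor_em``
    so recomputing acceptor/donor reproduces the stored ratio exactly.
    """
    if not (np.isfinite(donor_level) and donor_level > 0):
        raise ConfigurationError(f"donor_level must be > 0, got {donor_level!r}")
    if donor_cv < 0:
        raise ConfigurationError("donor_cv must be >= 0")
    validate_plate(table)
    if table["bret_ratio"].isna().any():
        raise ConfigurationError("emit_channels requires bret_ratio on every row")
    out = table.copy()
    rng = np.random.default_rng(seed)
    donor = donor_level * (1.0 + donor_cv * rng.standard_normal(len(out)))
    donor = np.clip(donor, donor_level * 1e-3, None)
    out["donor_em"] = donor
    out["acceptor_em"] = out["bret_ratio"].to_numpy() * donor
    return out
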