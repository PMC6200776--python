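import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bretfit as bf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# NRP1 parameter set used as ground truth throughout
NRP1_RATES = bf.KineticRateParams(kon=7.11e7, koff=0.26)
VEGFR2_RATES = bf.KineticRateParams(kon=1.54e7, koff=0.06)
NRP1_SATURATION = bf.EquilibriumBindingParams(
    kd=4.41e-9, bmax=0.02, ns_slope=1.0e5, baseline=0.05
)
NRP1_KI = 10 ** -9.54


@pytest.fixture
def nrp1_rates():
    return NRP1_RATES


@pytest.fixture
def vegfr2_rates():
    return VEGFR2_RATES


@pytest.fixture
def nrp1_saturation():
    return NRP1_SATURATION


def saturation_design(noise_sd=0.0, n_experiments=2, seed=0, ground_truth=None, **kw):
    return bf.SimulationDesign(
        mode="saturation",
        ground_truth=ground_truth or NRP1_SATURATION,
        probe_concs=tuple(np.geomspace(0.1e-9, 30e-9, 8)),
        replicates=2,
        n_experiments=n_experiments,
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )


def association_design(noise_sd=0.0, n_experiments=2, seed=0, rates=NRP1_RATES, **kw):
    return bf.SimulationDesign(
        mode="association",
        ground_truth=bf.AssociationTruth(rates=rates),
        probe_concs=(1e-9, 2.5e-9, 5e-9, 10e-9, 20e-9),
        timepoints=tuple(np.arange(0.0, 20.0 + 1e-9, 0.5)),
        replicates=1,
        n_experiments=n_experiments,
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )


def competition_design(noise_sd=0.0, n_experiments=2, seed=0, ki=NRP1_KI, **kw):
    return bf.SimulationDesign(
        mode="competition",
        ground_truth=bf.CompetitionTruth(probe=NRP1_SATURATION, ki=ki),
        probe_concs=(0.5e-9, 1e-9, 2e-9, 3e-9, 5e-9),
        competitor_concs=(0.0,) + tuple(np.geomspace(1e-11, 1e-7, 11)),
        replicates=2,
        n_experiments=n_experiments,
        noise_sd=noise_sd,
        seed=seed,
        **kw,
    )
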