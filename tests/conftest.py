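"""Shared fixtures: reference parameter sets, spaces and virtual enzymes."""
import numpy as np
import pytest

from autoassay import (Axis, DiproticParams, GroundTruth, ModulatorEffect,
                       ParameterSpace)

#: reference diprotic parameter set of the yeast pyruvate-kinase fit
TABLE_PARAMS = dict(Vmax=1.1e4, KM=0.53, K1E=1.9e-6, K2E=4.4e-9,
                    K1ES=2.2e-6, K2ES=9.6e-9, alpha=0.16, beta=0.0)

#: the dedicated pH-dependence experiment grid: 8 pH x 6 PEP levels
PH_LEVELS = [4.75, 5.39, 6.02, 6.66, 7.29, 7.93, 8.56, 9.2]
PEP_LEVELS = [0.25, 0.5, 1.0, 2.0, 4.0, 8.0]


@pytest.fixture
def table_params() -> DiproticParams:
    return DiproticParams(**TABLE_PARAMS)


@pytest.fixture
def space3d() -> ParameterSpace:
    """The buffer-optimization space: pH x KCl x fructose 1,6-bisphosphate."""
    return ParameterSpace((Axis("pH", 4.75, 9.2),
                           Axis("KCl", 0.0, 266.6),
                           Axis("Fru", 0.0, 10.0)))


@pytest.fixture
def space2d() -> ParameterSpace:
    return ParameterSpace((Axis("a", 0.0, 1.0), Axis("b", 0.0, 1.0)))


def make_noise_free_truth(**overrides) -> GroundTruth:
    """Virtual enzyme with effector bumps peaking at known concentrations."""
    kw = dict(
        modulators=[ModulatorEffect("KCl", c_opt=90.6, width=1.2, floor=0.05),
                    ModulatorEffect("Fru", c_opt=4.1, width=0.9, floor=0.05)],
        pipetting_cv=0.0, photometric_sd=0.0,
    )
    kw.update(overrides)
    return GroundTruth(**kw)


@pytest.fixture
def noise_free_truth() -> GroundTruth:
    return make_noise_free_truth()
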