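"""Shared fixtures: synthetic membrane configurations and calibrated CV
parameters, built once per session."""
from dataclasses import replace

import numpy as np
import pytest

from porecv.cv_fullpath import CVParams, calibrate_cv_eq
from porecv.membranes import (GeometrySpec, build_flat_bilayer,
                              build_pore_bilayer, build_stripe)


@pytest.fixture(scope="session")
def flat_bilayer():
    return build_flat_bilayer(GeometrySpec(n_lipids=200, seed=1))


@pytest.fixture(scope="session")
def pore_bilayer():
    return build_pore_bilayer(GeometrySpec(n_lipids=200, pore_radius=1.5, seed=1))


@pytest.fixture(scope="session")
def stripe():
    return build_stripe(GeometrySpec(n_lipids=60, stripe=True, seed=1,
                                     water_density=0.0))


@pytest.fixture(scope="session")
def calibrated_params(flat_bilayer):
    params = CVParams()
    cal = calibrate_cv_eq([flat_bilayer], params)
    return replace(params, cv_eq=cal.cv_eq)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
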