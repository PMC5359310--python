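"""Shared fixtures: reference configuration, forcing, and one stand run.

Everything is generated programmatically; there are no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from meristree import (
    ModelParameters,
    TreeState,
    generate_forcing,
    simulate,
)
from meristree.synthetic import reference_parameters


@pytest.fixture(scope="session")
def table_params() -> ModelParameters:
    """The tabulated reference constants (package defaults)."""
    return ModelParameters()


@pytest.fixture(scope="session")
def ref_params() -> ModelParameters:
    """The partial-fit reference configuration with a mid-range
    meristem-activity ratio."""
    return reference_parameters().replace(alpha2=0.37)


@pytest.fixture(scope="session")
def stand_forcing():
    """Forcing over the emulated stand ages 48-188 (CO2 ramp)."""
    return generate_forcing(np.arange(48, 189), seed=11)


@pytest.fixture(scope="session")
def constant_forcing():
    """Noise-free constant-climate forcing over ages 0-400."""
    return generate_forcing(
        np.arange(0, 401), t_sd=0.0, co2_scenario="constant", co2_start=390.0, seed=0
    )


@pytest.fixture(scope="session")
def stand_trajectory(ref_params, stand_forcing):
    """Reference stand run: (r0, h0) = (0.075 m, 15 m), ages 48-188."""
    return simulate(
        TreeState(0.075, 15.0, ref_params.S1), ref_params, stand_forcing, (48.0, 188.0)
    )
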