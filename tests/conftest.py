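"""Shared fixtures: simulator configs and one full synthetic study.

The synthetic study fixture runs the whole pipeline once per session
(simulate -> landmarks with 0.05 cm noise -> stroke table -> fits) at the
study's standard conditions and is reused by the integration and
acceptance tests.
"""

import time

import numpy as np
import pytest

from sideslip import RunConfig, run_pipeline
from sideslip.simulate import SimConfig, WingCommand, trim_hover


@pytest.fixture(scope="session")
def cfg():
    return SimConfig()


@pytest.fixture(scope="session")
def trimmed_cmd(cfg):
    return trim_hover(cfg)


@pytest.fixture(scope="session")
def fast_cfg():
    """Coarser but still-valid integration settings for cheap tests."""
    return SimConfig(n_blade_elements=6, timestep=1.0 / (52.0 * 26.0))


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Full synthetic study: 4 moths x 3 trials of commanded sideslips."""
    out = tmp_path_factory.mktemp("study")
    run = RunConfig(seed=11, out_dir=str(out))
    t0 = time.time()
    result = run_pipeline(run)
    result["elapsed_s"] = time.time() - t0
    result["run_config"] = run
    return result


@pytest.fixture(scope="session")
def study_table(study):
    return study["stroke_table"]
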