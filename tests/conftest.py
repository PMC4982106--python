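"""Shared fixtures: toy networks and the scaled multi-instance fleets.

The fleets emulate the study design at desk scale (6 network instances,
250 trials per word for the main condition; smaller fleets for the
deprivation and mask-off controls) and are trained once per session.
"""

import sys
from fractions import Fraction
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import semground as sg
from semground.connectivity import KernelParams
from semground.experiment import Condition, run_condition, run_instance

SCALED = dict(n_instances=6, reps_per_word=200)
CONTROL = dict(n_instances=3, reps_per_word=100)


@pytest.fixture(scope="session")
def scaled_config():
    return sg.ExperimentConfig(seed=20_16).scaled(**SCALED)


@pytest.fixture(scope="session")
def toy_network():
    """Full 12-area graph on tiny 5x5 sheets, for oracle comparisons."""
    kernel = KernelParams(within_extent=3, between_extent=3, inhib_extent=3,
                          amplitude=0.5, between_amplitude=0.4, sigma=1.5)
    return sg.build_network(kernel=kernel, side=5, seed=123)


@pytest.fixture(scope="session")
def main_fleet(scaled_config):
    """Six instances trained on the full-semantic, masked condition."""
    return run_condition(scaled_config, Condition(Fraction(1), True),
                         keep_networks=True)


@pytest.fixture(scope="session")
def deprivation_fleets(scaled_config):
    """Small fleets for the 75% and 50% semantic-fraction conditions."""
    cfg = sg.ExperimentConfig(seed=scaled_config.seed).scaled(
        n_instances=CONTROL["n_instances"],
        reps_per_word=CONTROL["reps_per_word"])
    return {frac: run_condition(cfg, Condition(frac, True))
            for frac in (Fraction(3, 4), Fraction(2, 3),
                         Fraction(1, 2))}


@pytest.fixture(scope="session")
def maskoff_fleet(scaled_config):
    cfg = sg.ExperimentConfig(seed=scaled_config.seed).scaled(
        n_instances=CONTROL["n_instances"],
        reps_per_word=CONTROL["reps_per_word"])
    return run_condition(cfg, Condition(Fraction(1), False))


@pytest.fixture(scope="session")
def maskon_control_fleet(scaled_config):
    """Mask-on twin of the mask-off fleet (same size, for paired contrast)."""
    cfg = sg.ExperimentConfig(seed=scaled_config.seed).scaled(
        n_instances=CONTROL["n_instances"],
        reps_per_word=CONTROL["reps_per_word"])
    return run_condition(cfg, Condition(Fraction(1), True))
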