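"""Shared fixtures: one small simulated experiment reused across test modules.

The session fixtures mirror the smallest imaged volume of the study
conditions (a few hundred mono-contrast cells, 1500 sparse-noise
presentations) so estimation-quality checks run on realistic data without
re-simulating per test.
"""

import numpy as np
import pandas as pd
import pytest

from onoffmap import kernels as ker
from onoffmap import synthetic as syn


@pytest.fixture(scope="session")
def small_population():
    bias = syn.make_bias_field(amplitude=0.8, seed=11)
    ret = syn.default_retinotopy()
    return syn.sample_population(bias, ret, n_on=60, n_off=100,
                                 n_simple=25, n_complex=20, seed=12)


@pytest.fixture(scope="session")
def stimulus_1500():
    return syn.make_stimulus(n_stimuli=1500, seed=13)


@pytest.fixture(scope="session")
def classified(small_population, stimulus_1500):
    """(population, stimulus, classified cell table, kernel set)."""
    resp = syn.simulate_responses(small_population, stimulus_1500, seed=14)
    cells, kset = ker.classify_population(resp, stimulus_1500)
    cells = cells.merge(
        small_population.cells[["cell_id", "true_class", "x1", "x2", "x3"]],
        on="cell_id")
    return small_population, stimulus_1500, cells, kset


@pytest.fixture()
def mono_table(small_population):
    """Ground-truth mono-contrast cells labelled as a classified table."""
    cells = small_population.cells
    mono = cells[cells.true_class.isin(["ON", "OFF"])].copy()
    return mono.rename(columns={"true_class": "cell_class"})
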