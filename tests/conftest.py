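"""Shared synthetic fixtures: one small multi-pool panel with planted
truth, reused across test modules (module-scoped where heavy)."""

import numpy as np
import pandas as pd
import pytest

from maizearray import clustering, simulate


@pytest.fixture(scope="session")
def genome():
    return simulate.simulate_genome(simulate.GenomeConfig(), seed=11)


@pytest.fixture(scope="session")
def panel_config():
    return simulate.default_panel()


@pytest.fixture(scope="session")
def truth(genome, panel_config):
    return simulate.simulate_panel(genome, panel_config, n_variants=600, seed=11)


@pytest.fixture(scope="session")
def seq_calls(truth):
    return simulate.simulate_sequencing_calls(truth, paralog_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def intensities(truth):
    return simulate.simulate_intensities(truth, seed=11)


@pytest.fixture(scope="session")
def sample_sheet(panel_config):
    return simulate.sample_sheet(panel_config)


@pytest.fixture(scope="session")
def panel_calls(intensities, sample_sheet):
    """Genotype calls without inbred correction (planted-geometry view)."""
    return clustering.genotype_panel(intensities, sample_sheet, inbred_correction=False)


@pytest.fixture(scope="session")
def panel_calls_corrected(intensities, sample_sheet):
    return clustering.genotype_panel(intensities, sample_sheet, inbred_correction=True)
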