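"""Shared fixtures: a down-scaled genome, a reference panel, binning schemes.

Everything is generated at test time from the synthetic module; session
scope keeps the suite fast since the panel and binning are reused
read-only across tests.
"""

import numpy as np
import pytest

from methyldx.array_model import build_reference
from methyldx.cnv import BinConfig, build_bins, load_highlight_genes
from methyldx.scores import load_schema
from methyldx.synthetic import simulate_reference_panel, test_scale_manifest


@pytest.fixture(scope="session")
def manifest():
    return test_scale_manifest(seed=11)


@pytest.fixture(scope="session")
def panel(manifest):
    return build_reference(simulate_reference_panel(5, manifest, noise_sd=0.1, seed=12))


@pytest.fixture(scope="session")
def scheme(panel):
    """Test-profile binning: 800 genome-wide bins."""
    return build_bins(panel.manifest, BinConfig(target_bins=800, min_probes=10))


@pytest.fixture(scope="session")
def scheme_fine(panel):
    """Finer binning (1600 bins) for short focal-event fixtures."""
    return build_bins(panel.manifest, BinConfig(target_bins=1600, min_probes=10))


@pytest.fixture(scope="session")
def schema():
    return load_schema()


@pytest.fixture(scope="session")
def highlight_genes():
    return load_highlight_genes()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
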