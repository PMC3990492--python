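import numpy as np
import pandas as pd
import pytest

from lanccsv.panel import HaplotypePanel
from lanccsv.simulate import PopulationSpec, SyntheticPanelSpec


@pytest.fixture
def toy_panel():
    """Hand-built 3-group panel with known CSV structure.

    site 0: alt private to A (2 carriers)
    site 1: alt shared by A and B        -> no CSV
    site 2: A fixed ref, B and C fixed alt -> ref is a CSV of A
    site 3: monomorphic ref              -> no CSV
    site 4: alt private to C (1 carrier)
    """
    sites = pd.DataFrame({
        "chrom": "1",
        "pos": [100, 200, 300, 400, 500],
        "ref": ["A", "C", "A", "C", "A"],
        "alt": ["G", "T", "G", "T", "C"],
    })
    hap = np.array([
        [1, 1, 0, 0, 0, 0],
        [1, 0, 1, 0, 0, 0],
        [0, 0, 1, 1, 1, 1],
        [0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 1, 0],
    ], dtype=np.uint8)
    labels = np.array(["a1", "a1", "b1", "b1", "c1", "c1"])
    return HaplotypePanel(sites, hap, labels,
                          {"a1": "A", "b1": "B", "c1": "C"})


@pytest.fixture
def small_spec():
    """Small 3-group synthetic panel spec (2 Mb, modest densities)."""
    return SyntheticPanelSpec(
        populations=[PopulationSpec("EUR", 30, 150.0),
                     PopulationSpec("NAM", 30, 100.0),
                     PopulationSpec("AFR", 30, 800.0)],
        length_bp=2_000_000, shared_density=50.0)


@pytest.fixture
def two_group_spec():
    return SyntheticPanelSpec(
        populations=[PopulationSpec("EUR", 20, 200.0),
                     PopulationSpec("AFR", 20, 600.0)],
        length_bp=2_000_000, shared_density=50.0)
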