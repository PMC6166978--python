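import numpy as np
import pandas as pd
import pytest

from mendelbalance import simdata
from mendelbalance.core_io import MarkerMap, PhasedPanel


@pytest.fixture(scope="session")
def bundle():
    """Default-scale synthetic bundle (~19k animals), shared across tests."""
    return simdata.generate_population(simdata.SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced bundle for tests that refit models repeatedly."""
    cfg = simdata.SimConfig(seed=5, n_founders=200, n_generations=2,
                            n_dams=150, n_sires=20, tnb_mean=12.0)
    return simdata.generate_population(cfg)


def make_panel(hap1, hap2, animals=None, chrom="1"):
    """Small phased panel from int8-able nested lists (one row per animal)."""
    h1 = np.asarray(hap1, dtype=np.int8)
    h2 = np.asarray(hap2, dtype=np.int8)
    n, m = h1.shape
    markers = MarkerMap(pd.DataFrame({
        "marker_id": [f"M{j}" for j in range(m)],
        "chrom": chrom,
        "pos_bp": np.arange(1, m + 1) * 1000,
        "allele_a": "A",
        "allele_b": "B",
    }))
    if animals is None:
        animals = [f"S{i}" for i in range(n)]
    return PhasedPanel(markers, animals, h1, h2)
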