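import numpy as np
import pandas as pd
import pytest

from uroquant import ihc, simulate as sim


@pytest.fixture(scope="session")
def small_core():
    """A 20-tumour-cell + 5-lymphocyte noiseless core with truth table."""
    spec = sim.ImageSpec(n_cells=20, n_lymphocytes=5, seed=1)
    image, truth = sim.gen_ihc_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def quant_config():
    return ihc.QuantConfig()


def match_cells(cells: pd.DataFrame, truth: pd.DataFrame, max_dist: float = 3.0):
    """Pair measured cells with truth rows by nearest centroid.

    Returns a list of (truth_row, measured_row_or_None).
    """
    pairs = []
    for _, tr in truth.iterrows():
        if len(cells) == 0:
            pairs.append((tr, None))
            continue
        d = np.hypot(cells["x"] - tr["x"], cells["y"] - tr["y"])
        i = d.idxmin()
        pairs.append((tr, cells.loc[i] if d[i] < max_dist else None))
    return pairs
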