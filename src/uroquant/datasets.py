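"""Bundled reference tables."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd


@lru_cache(maxsize=1)
def load_induced_gene_table() -> pd.DataFrame:
    """The 54-gene differential-expression table for channel-dead (T134A)
    versus wild-type Cx32 overexpression in differentiated urothelial
    cultures: columns ``gene``, ``q`` (likelihood-ratio-test q-value) and
    ``log2fc`` (log2 fold change on the TPM+1 scale), at two-decimal
    reporting precision.
    """
    with resources.files("uroquant.data").joinpath("cx32_t134a_deg.csv").open() as fh:
        return pd.read_csv(fh)
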