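"""File-format helpers: multi-page TIFF images, expression/clinical TSV."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .regulon import ExpressionCohort


def save_ihc_tiff(path, image: np.ndarray) -> None:
    """Write a (2, H, W) image as a two-page TIFF (counterstain, chromogen)."""
    tifffile.imwrite(path, np.asarray(image))


def load_ihc_tiff(path) -> np.ndarray:
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        raise ValueError("expected a two-page TIFF (counterstain, chromogen)")
    return np.asarray(pages[:2])


def save_cohort(cohort: ExpressionCohort, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.abundance.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
    if cohort.clinical is not None:
        cohort.clinical.to_csv(out / "clinical.tsv", sep="\t")


def load_cohort(expr_path, clinical_path=None, kind: str = "au") -> ExpressionCohort:
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    clinical = (
        pd.read_csv(clinical_path, sep="\t", index_col=0)
        if clinical_path is not None
        else None
    )
    return ExpressionCohort(expr, kind=kind, clinical=clinical)


def read_table(path) -> pd.DataFrame:
    """CSV/TSV sniffing reader for small analysis tables."""
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".txt", ".rnk")) else ","
    return pd.read_csv(path, sep=sep)
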