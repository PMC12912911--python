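"""Differential-expression post-processing: donor-matched fold changes,
significance/fold-change selection, and pi-value pre-ranked lists.

The pi-value combines effect size and significance into one signed
ranking score, ``pi = log2FC(TPM+1) x -log10(q)``, used to order genes
for pre-ranked gene-set enrichment; genes with pi = 0 carry no ranking
information and are removed before export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import load_induced_gene_table

__all__ = [
    "SelectionThresholds",
    "donor_matched_log2fc",
    "pi_value",
    "floor_q",
    "compute_pi",
    "build_rnk",
    "select_deg",
    "load_induced_gene_table",
]


def donor_matched_log2fc(
    tpm_treated: pd.DataFrame, tpm_control: pd.DataFrame
) -> pd.Series:
    """Per-gene mean over donors of log2((treated+1)/(control+1)).

    Both tables are gene x donor with identical donor columns; the +1
    offset damps the influence of low-abundance transcripts.
    """
    unmatched = set(tpm_treated.columns) ^ set(tpm_control.columns)
    if unmatched:
        raise ValueError(f"donor mismatch between conditions: {sorted(unmatched)}")
    if (np.asarray(tpm_treated) < 0).any() or (np.asarray(tpm_control) < 0).any():
        raise ValueError("TPM values must be non-negative")
    ctrl = tpm_control[tpm_treated.columns]
    lfc = np.log2(tpm_treated + 1.0) - np.log2(ctrl + 1.0)
    return lfc.mean(axis=1).rename("log2fc")


def pi_value(log2fc, q):
    """Signed ranking score log2fc x -log10(q) for q in (0, 1]."""
    log2fc = np.asarray(log2fc, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q = 0 gives an infinite pi; floor q first (floor_q)")
    if np.any(q > 1):
        raise ValueError("q-values must lie in (0, 1]")
    out = log2fc * (-np.log10(q))
    return float(out) if out.ndim == 0 else out


def floor_q(q, min_q: float = 1e-300):
    """Replace q = 0 by ``min_q`` (with a warning) so pi stays finite."""
    q = np.asarray(q, dtype=float)
    if np.any(q == 0):
        warnings.warn(f"flooring {int((q == 0).sum())} zero q-value(s) to {min_q}")
    out = np.where(q == 0, min_q, q)
    return float(out) if out.ndim == 0 else out


def compute_pi(records: pd.DataFrame, q_floor: float | None = None) -> pd.DataFrame:
    """Add a ``pi`` column to a (gene, log2fc, q) table."""
    out = records.copy()
    q = out["q"].to_numpy(dtype=float)
    if q_floor is not None:
        q = floor_q(q, q_floor)
    out["pi"] = pi_value(out["log2fc"].to_numpy(dtype=float), q)
    return out


def build_rnk(records: pd.DataFrame) -> pd.DataFrame:
    """Pre-ranked two-column list (gene, pi), pi descending.

    Genes with pi = 0 are removed as unranked data; ties are broken by
    gene id so the output is deterministic under input shuffling.
    """
    if "pi" not in records.columns:
        records = compute_pi(records)
    ranked = records.loc[records["pi"] != 0, ["gene", "pi"]]
    if ranked.empty:
        raise ValueError("all pi-values are zero; nothing to rank")
    return ranked.sort_values(
        ["pi", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def write_rnk(ranked: pd.DataFrame, path) -> None:
    ranked.to_csv(path, sep="\t", header=False, index=False)


def read_rnk(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=["gene", "pi"])


@dataclass
class SelectionThresholds:
    """Significance and fold-change cut-offs for calling regulated genes.

    With ``strict=False`` (default) comparisons happen at the printed
    precision: values are rounded (half-even) to ``boundary_tolerance``
    decimals and the boundaries are inclusive, so a gene printed as
    q = 0.050, log2FC = 1.00 passes a "q < 0.05, >twofold" selection the
    way published tables treat it.  ``strict=True`` applies literal
    strict inequalities on the unrounded values.
    """

    q_max: float = 0.05
    min_abs_log2fc: float = 1.0
    boundary_tolerance: int = 2
    strict: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be non-negative")


def select_deg(
    records: pd.DataFrame, thresholds: SelectionThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a (gene, log2fc, q) table into up- and down-regulated calls."""
    thresholds = thresholds or SelectionThresholds()
    q = records["q"].to_numpy(dtype=float)
    fc = records["log2fc"].to_numpy(dtype=float)
    if thresholds.strict:
        sig = q < thresholds.q_max
        up = sig & (fc > thresholds.min_abs_log2fc)
        down = sig & (fc < -thresholds.min_abs_log2fc)
    else:
        tol = thresholds.boundary_tolerance
        qr = np.round(q, tol)
        fr = np.round(fc, tol)
        sig = qr <= thresholds.q_max
        up = sig & (fr >= thresholds.min_abs_log2fc)
        down = sig & (fr <= -thresholds.min_abs_log2fc)
    return records[up].copy(), records[down].copy()
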