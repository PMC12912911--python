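"""Functional-readout statistics: wound-closure kinetics (WC50),
scrape-load dye-transfer index, TEER barrier metrics and qPCR relative
expression (2^-ddCt)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "percent_closure",
    "wc50",
    "WC50Result",
    "sldt_index",
    "teer_metrics",
    "TEERResult",
    "relative_expression",
]


def percent_closure(area_t: float, area_0: float) -> tuple[float, bool]:
    """Percent of the original wound area healed, clamped to [0, 100].

    Returns ``(percent, clamped)`` where the flag marks values that fell
    outside [0, 100] before clamping (e.g. the wound transiently opening
    wider than at t = 0).
    """
    if area_0 <= 0:
        raise ValueError("original wound area must be positive")
    if area_t < 0:
        raise ValueError("wound area must be non-negative")
    raw = 100.0 * (1.0 - area_t / area_0)
    clamped = not 0.0 <= raw <= 100.0
    return float(np.clip(raw, 0.0, 100.0)), clamped


@dataclass
class WC50Result:
    per_replicate: pd.Series  # hours; NaN = never reached 50%
    mean_h: float
    flags: dict[str, str]


def _first_crossing(time: np.ndarray, value: np.ndarray, level: float) -> float:
    """Time of first crossing of ``level`` by linear interpolation; NaN if
    never reached; 0.0 (by convention) if already past at the first
    sample."""
    if value[0] >= level:
        return 0.0
    idx = np.nonzero(value >= level)[0]
    if idx.size == 0:
        return float("nan")
    i = idx[0]
    t0, t1 = time[i - 1], time[i]
    v0, v1 = value[i - 1], value[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (level - v0) * (t1 - t0) / (v1 - v0))


def wc50(series: pd.DataFrame, level: float = 50.0) -> WC50Result:
    """Time to 50% wound closure, per replicate then averaged.

    ``series`` is long-format with columns ``replicate``, ``time_h`` and
    ``value`` (percent closed).  The crossing is located by linear
    interpolation between the bracketing timepoints; replicates that
    never reach the level are excluded from the mean with a warning, and
    replicates already past the level at their first sample report 0.0 h
    with a quality flag.
    """
    out = {}
    flags = {}
    for rep, grp in series.groupby("replicate", sort=True):
        grp = grp.sort_values("time_h")
        if len(grp) < 2:
            raise ValueError(f"replicate {rep!r} has fewer than 2 timepoints")
        t = grp["time_h"].to_numpy(dtype=float)
        v = grp["value"].to_numpy(dtype=float)
        c = _first_crossing(t, v, level)
        if np.isnan(c):
            flags[str(rep)] = "not reached"
            warnings.warn(f"replicate {rep!r} never reached {level}% closure")
        elif c == 0.0 and v[0] >= level:
            flags[str(rep)] = "already closed at first sample"
        out[str(rep)] = c
    per_rep = pd.Series(out, name="wc50_h")
    mean = float(per_rep.dropna().mean()) if per_rep.notna().any() else float("nan")
    return WC50Result(per_replicate=per_rep, mean_h=mean, flags=flags)


def sldt_index(fields: pd.DataFrame) -> float:
    """Mean dye-transfer index: LY-positive count normalised to the RhoD
    (initially loaded) count, averaged over fields of view.

    Fields with no RhoD cells are excluded with a warning; an error is
    raised if no field is usable.
    """
    if len(fields) == 0:
        raise ValueError("at least one field is required")
    n_ly = fields["n_ly"].to_numpy(dtype=float)
    n_rhod = fields["n_rhod"].to_numpy(dtype=float)
    usable = n_rhod > 0
    if (~usable).any():
        warnings.warn(f"excluding {int((~usable).sum())} field(s) with no RhoD cells")
    if not usable.any():
        raise ValueError("no field has RhoD-positive cells")
    return float((n_ly[usable] / n_rhod[usable]).mean())


@dataclass
class TEERResult:
    flags: pd.DataFrame  # per replicate/timepoint tight/leaky
    recovery_h: pd.Series  # per replicate, NaN if barrier never recovers


def teer_metrics(
    series: pd.DataFrame,
    tight_threshold: float = 500.0,
    wound_time_h: float = 0.0,
) -> TEERResult:
    """Barrier flags and recovery time from a TEER time course.

    A timepoint is ``tight`` when resistance strictly exceeds
    ``tight_threshold`` (Ohm.cm^2).  Recovery time is the first, linearly
    interpolated, return above the threshold after ``wound_time_h``.
    """
    if len(series) == 0:
        raise ValueError("empty TEER series")
    if (series["value"] <= 0).any():
        raise ValueError("TEER values must be strictly positive")
    flags = series.copy()
    flags["tight"] = flags["value"] > tight_threshold
    rec = {}
    for rep, grp in flags.groupby("replicate", sort=True):
        grp = grp.sort_values("time_h")
        post = grp[grp["time_h"] > wound_time_h]
        t = post["time_h"].to_numpy(dtype=float)
        v = post["value"].to_numpy(dtype=float)
        if t.size == 0:
            rec[str(rep)] = float("nan")
            continue
        # first upward crossing of the threshold after wounding
        above = v > tight_threshold
        if above[0]:
            rec[str(rep)] = float(t[0])
            continue
        idx = np.nonzero(above)[0]
        if idx.size == 0:
            rec[str(rep)] = float("nan")
            continue
        i = idx[0]
        t0, t1, v0, v1 = t[i - 1], t[i], v[i - 1], v[i]
        rec[str(rep)] = float(t0 + (tight_threshold - v0) * (t1 - t0) / (v1 - v0))
    return TEERResult(flags=flags, recovery_h=pd.Series(rec, name="recovery_h"))


def relative_expression(
    ct_target,
    ct_reference,
    ct_target_cal,
    ct_reference_cal,
) -> float:
    """qPCR fold change by the 2^-ddCt method.

    Each argument is a scalar or an iterable of technical-replicate Ct
    values (means are taken first); the calibrator pair defines the
    reference condition (fold change 1).
    """
    vals = []
    for name, ct in (
        ("ct_target", ct_target),
        ("ct_reference", ct_reference),
        ("ct_target_cal", ct_target_cal),
        ("ct_reference_cal", ct_reference_cal),
    ):
        arr = np.atleast_1d(np.asarray(ct, dtype=float))
        if arr.size == 0 or not np.isfinite(arr).all():
            raise ValueError(f"{name} must be finite and non-empty")
        vals.append(float(arr.mean()))
    tgt, ref, tgt_cal, ref_cal = vals
    ddct = (tgt - ref) - (tgt_cal - ref_cal)
    return float(2.0**-ddct)
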