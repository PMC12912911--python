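"""Seeded ground-truthed generators for every downstream analysis stage.

Four generators are provided:

* :func:`gen_ihc_image` -- two-channel (haematoxylin counterstain + DAB
  chromogen) rasters of a tumour core with elliptical nuclei, annular
  cytoplasmic staining, thin membrane arcs and sub-30 um^2 lymphocyte
  contaminants, plus a per-cell truth table.
* :func:`gen_cohort` -- a gene x sample expression cohort in which a
  regulon block is given a target within-block Spearman correlation via
  a Gaussian copula (decoys stay independent), consensus-subtype labels
  are mixed in, and exponential survival times carry a configurable
  hazard ratio between regulon-high and regulon-low samples.
* :func:`gen_de_experiment` -- donor-matched control/treated TPM tables
  with planted log2 fold changes.
* :func:`gen_assay_series` -- logistic wound-closure curves with a known
  50%-closure time, TEER recovery series, and Poisson dye-transfer
  counts.

Fixing ``seed`` fixes every output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import load_induced_gene_table
from .regulon import ExpressionCohort

__all__ = [
    "ImageSpec",
    "CohortSpec",
    "AssaySpec",
    "PlacementError",
    "gen_ihc_image",
    "gen_cohort",
    "gen_survival",
    "gen_de_experiment",
    "gen_assay_series",
    "spearman_to_pearson",
]

IHC_CLASSES = ("membrane", "cytoplasmic", "absent")

#: Default consensus-subtype mixture (luminal-skewed, with a stroma-rich
#: fraction to exercise reclassification).
DEFAULT_SUBTYPE_MIX = {
    "Ba/Sq": 0.25,
    "LumP": 0.30,
    "LumNS": 0.10,
    "LumU": 0.15,
    "NE-like": 0.05,
    "Stroma-rich": 0.15,
}


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap."""


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose Spearman rho is
    ``rho_s`` (inverse of rho_s = (6/pi) arcsin(r/2))."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


# ---------------------------------------------------------------------------
# IHC images
# ---------------------------------------------------------------------------

@dataclass
class ImageSpec:
    """Geometry and staining truth for one synthetic tumour core.

    ``class_truth``, ``membrane_arc_deg`` and ``cyto_intensity_au`` may be
    given per cell (length ``n_cells``) or left ``None`` to be sampled:
    classes from ``class_probs``, arcs uniform on [90, 270] degrees and
    cytoplasmic intensities uniform on [30, 80] AU (absent cells get
    < 10 AU residual background staining).
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 0.5
    n_cells: int = 25
    class_truth: list[str] | None = None
    class_probs: tuple[float, float, float] = (0.44, 0.38, 0.18)
    membrane_arc_deg: list[float] | None = None
    cyto_intensity_au: list[float] | None = None
    n_lymphocytes: int = 0
    noise_sd: float = 0.0
    seed: int = 0
    tumour_area_um2: tuple[float, float] = (45.0, 90.0)
    lymphocyte_area_um2: tuple[float, float] = (12.0, 25.0)
    membrane_intensity_au: float = 180.0
    nucleus_value: int = 60
    background_value: int = 230

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0 or self.n_lymphocytes < 0:
            raise ValueError("cell counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.class_truth is not None:
            if len(self.class_truth) != self.n_cells:
                raise ValueError("class_truth length must equal n_cells")
            bad = set(self.class_truth) - set(IHC_CLASSES)
            if bad:
                raise ValueError(f"unknown classes {bad}")
        if self.lymphocyte_area_um2[1] >= 30.0:
            raise ValueError("lymphocyte areas must stay below 30 um^2")
        if self.tumour_area_um2[0] < 30.0:
            raise ValueError("tumour nuclear areas must be >= 30 um^2")


def _ellipse_mask(a: float, b: float, theta: float, target_px: int) -> np.ndarray:
    """Boolean crop of an ellipse, trimmed/grown to exactly ``target_px``
    pixels (pixels ranked by normalised elliptical radius)."""
    r = int(np.ceil(max(a, b))) + 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = np.cos(theta), np.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    d = (u / a) ** 2 + (v / b) ** 2
    order = np.argsort(d, axis=None, kind="stable")
    mask = np.zeros(d.size, dtype=bool)
    mask[order[:target_px]] = True
    return mask.reshape(d.shape)


def gen_ihc_image(spec: ImageSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a two-channel core image and its per-cell truth table.

    Returns ``(image, truth)`` where ``image`` has shape ``(2, H, W)``
    uint8 (page 0 counterstain with dark nuclei on a bright background,
    page 1 chromogen where higher value means more DAB) and ``truth`` has
    one row per nucleus (tumour cells first, then lymphocytes).
    """
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size_um
    h, w = spec.height_px, spec.width_px

    n = spec.n_cells
    classes = (
        list(spec.class_truth)
        if spec.class_truth is not None
        else list(rng.choice(IHC_CLASSES, size=n, p=spec.class_probs))
    )
    arcs = (
        np.asarray(spec.membrane_arc_deg, dtype=float)
        if spec.membrane_arc_deg is not None
        else rng.uniform(90.0, 270.0, size=n)
    )
    cyto = (
        np.asarray(spec.cyto_intensity_au, dtype=float)
        if spec.cyto_intensity_au is not None
        else np.where(
            [c == "absent" for c in classes],
            rng.uniform(0.0, 5.0, size=n),
            rng.uniform(60.0, 120.0, size=n),
        )
    )

    areas_um2 = np.concatenate(
        [
            rng.uniform(*spec.tumour_area_um2, size=n),
            rng.uniform(*spec.lymphocyte_area_um2, size=spec.n_lymphocytes),
        ]
    )
    ratios = rng.uniform(1.0, 2.0, size=areas_um2.size)
    thetas = rng.uniform(0.0, np.pi, size=areas_um2.size)
    arc_starts = rng.uniform(0.0, 360.0, size=n)

    counter = np.full((h, w), spec.background_value, dtype=float)
    chromo = np.zeros((h, w), dtype=float)

    # place cells by rejection sampling on bounding circles
    margin_extra = 9.0  # membrane band offset + thickness, px
    centres: list[tuple[float, float]] = []
    radii: list[float] = []
    rows = []
    ntot = areas_um2.size
    for i in range(ntot):
        area_px = max(int(round(areas_um2[i] / ps**2)), 4)
        a = np.sqrt(area_px * ratios[i] / np.pi)
        b = area_px / (np.pi * a)
        bound = a + (margin_extra if i < n else 4.0)
        placed = False
        for _ in range(400):
            cx = rng.uniform(bound + 1, w - bound - 1)
            cy = rng.uniform(bound + 1, h - bound - 1)
            if all(
                np.hypot(cx - px, cy - py) > bound + pr + 1
                for (px, py), pr in zip(centres, radii)
            ):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {i} after 400 attempts; "
                "reduce n_cells or enlarge the image"
            )
        centres.append((cx, cy))
        radii.append(bound)

        mask = _ellipse_mask(a, b, thetas[i], area_px)
        r = mask.shape[0] // 2
        icx, icy = int(round(cx)), int(round(cy))
        ys = slice(icy - r, icy + r + 1)
        xs = slice(icx - r, icx + r + 1)
        counter[ys, xs][mask] = spec.nucleus_value

        is_lymph = i >= n
        if not is_lymph:
            cls = classes[i]
            r2 = r + 10
            # clip the paste window at the image edges and trim the grids
            y0, y1 = max(icy - r2, 0), min(icy + r2 + 1, h)
            x0, x1 = max(icx - r2, 0), min(icx + r2 + 1, w)
            yy, xx = np.mgrid[y0 - icy : y1 - icy, x0 - icx : x1 - icx]
            ct, st = np.cos(thetas[i]), np.sin(thetas[i])
            u = xx * ct + yy * st
            v = -xx * st + yy * ct
            ys2 = slice(y0, y1)
            xs2 = slice(x0, x1)
            nuc2 = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if cyto[i] > 0:
                inner = (u / (a + 5)) ** 2 + (v / (b + 5)) ** 2 <= 1.0
                band = inner & ~nuc2
                region = chromo[ys2, xs2]
                region[band] = np.maximum(region[band], cyto[i])
            if cls == "membrane":
                # one-pixel membrane curve on the (a+6, b+6) ellipse,
                # restricted to the requested angular extent
                am, bm = a + 6.0, b + 6.0
                tpar = np.linspace(0.0, 2 * np.pi, int(np.ceil(8 * np.pi * am)))
                mx = am * np.cos(tpar) * ct - bm * np.sin(tpar) * st
                my = am * np.cos(tpar) * st + bm * np.sin(tpar) * ct
                ang = (np.degrees(np.arctan2(my, mx)) - arc_starts[i]) % 360.0
                sel = ang <= arcs[i]
                pxs = np.round(mx[sel] + cx).astype(int)
                pys = np.round(my[sel] + cy).astype(int)
                ok = (pxs >= 0) & (pxs < w) & (pys >= 0) & (pys < h)
                chromo[pys[ok], pxs[ok]] = np.maximum(
                    chromo[pys[ok], pxs[ok]], spec.membrane_intensity_au
                )

        rows.append(
            {
                "cell_id": i,
                "x": cx,
                "y": cy,
                "nuclear_area_um2": area_px * ps**2,
                "nuclear_area_px": area_px,
                "requested_area_um2": areas_um2[i],
                "class_truth": "lymphocyte" if is_lymph else classes[i],
                "membrane_arc_deg": 0.0 if is_lymph or classes[i] != "membrane" else arcs[i],
                "cyto_intensity_au": 0.0 if is_lymph else cyto[i],
                "is_lymphocyte": is_lymph,
            }
        )

    if spec.noise_sd > 0:
        counter += rng.normal(0.0, spec.noise_sd, size=counter.shape)
        chromo += rng.normal(0.0, spec.noise_sd, size=chromo.shape)
    image = np.stack(
        [
            np.clip(np.round(counter), 0, 255).astype(np.uint8),
            np.clip(np.round(chromo), 0, 255).astype(np.uint8),
        ]
    )
    truth = pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "x",
            "y",
            "nuclear_area_um2",
            "nuclear_area_px",
            "requested_area_um2",
            "class_truth",
            "membrane_arc_deg",
            "cyto_intensity_au",
            "is_lymphocyte",
        ],
    )
    return image, truth


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------

def _default_regulon_genes() -> list[str]:
    tab = load_induced_gene_table()
    up = tab[tab["log2fc"] > 0].sort_values("log2fc", ascending=False)
    return list(up["gene"].head(25))


def _default_decoy_genes() -> list[str]:
    tab = load_induced_gene_table()
    up = tab[tab["log2fc"] > 0].sort_values("log2fc", ascending=False)
    return list(up["gene"].iloc[25:50])


@dataclass
class CohortSpec:
    """Statistical structure of a synthetic tumour expression cohort.

    ``block_rho`` is the target *Spearman* correlation inside the regulon
    block, induced through a Gaussian copula so each gene keeps a
    log-normal marginal regardless of the dependence.  ``true_hr`` is the
    hazard ratio of regulon-high over regulon-low samples (exponential
    survival, administrative censoring at the quantile matching
    ``censor_frac``).  Default gene lists are the top/bottom halves of
    the bundled 50-gene induced set.
    """

    n_samples: int = 300
    regulon_genes: list[str] = field(default_factory=_default_regulon_genes)
    decoy_genes: list[str] = field(default_factory=_default_decoy_genes)
    n_marker_genes: int = 30
    block_rho: float = 0.7
    subtype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX)
    )
    marker_shift: float = 2.0
    true_hr: float = 1.8
    median_survival_months: float = 30.0
    censor_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.block_rho < 1:
            raise ValueError("block_rho must be in [0, 1)")
        if set(self.regulon_genes) & set(self.decoy_genes):
            raise ValueError("regulon and decoy gene lists must be disjoint")
        if not np.isclose(sum(self.subtype_mix.values()), 1.0):
            raise ValueError("subtype proportions must sum to 1")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")


def gen_survival(
    n: int,
    true_hr: float,
    censor_frac: float = 0.3,
    median_months: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Fast survival-only draw: a 50/50 high/low split with exponential
    times (rate scaled by ``true_hr`` for the high group) and
    administrative censoring.  Used for null/recovery simulations where
    the expression matrix is irrelevant."""
    rng = np.random.default_rng(seed)
    lam0 = np.log(2.0) / median_months
    high = np.arange(n) < n // 2
    rng.shuffle(high)
    lam = np.where(high, lam0 * true_hr, lam0)
    t = rng.exponential(1.0 / lam)
    if censor_frac > 0:
        cutoff = np.quantile(t, 1.0 - censor_frac)
        event = (t <= cutoff).astype(int)
        t = np.minimum(t, cutoff)
    else:
        event = np.ones(n, dtype=int)
    return pd.DataFrame(
        {"time": t, "event": event, "group": np.where(high, "high", "low")}
    )


def gen_cohort(spec: CohortSpec) -> tuple[ExpressionCohort, dict]:
    """Generate an :class:`ExpressionCohort` plus ground-truth tables.

    The truth dict holds ``samples`` (per-sample hidden regulon group and,
    for stroma-rich samples, the latent urothelial class), ``genes``
    (role of every gene) and ``centroids`` (class x marker-gene table for
    reclassification).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    samples = [f"S{i:04d}" for i in range(n)]
    markers = [f"MK{i:03d}" for i in range(spec.n_marker_genes)]
    genes = list(spec.regulon_genes) + list(spec.decoy_genes) + markers
    nb, nd, nm = len(spec.regulon_genes), len(spec.decoy_genes), len(markers)

    # log2-scale marginal parameters, independent of the copula
    mu = rng.uniform(3.0, 8.0, size=len(genes))
    sigma = rng.uniform(0.5, 1.5, size=len(genes))

    rp = spearman_to_pearson(spec.block_rho)
    cov = np.full((nb, nb), rp)
    np.fill_diagonal(cov, 1.0)
    z_block = (
        rng.multivariate_normal(np.zeros(nb), cov, size=n, method="cholesky").T
        if nb
        else np.empty((0, n))
    )
    z_rest = rng.standard_normal((nd + nm, n))
    z = np.vstack([z_block, z_rest])

    # consensus subtype labels; stroma-rich samples carry a latent class
    labels = list(spec.subtype_mix)
    probs = np.array([spec.subtype_mix[c] for c in labels])
    subtype = rng.choice(labels, size=n, p=probs)
    urothelial = [c for c in labels if c != "Stroma-rich"]
    if not urothelial:
        urothelial = ["LumP"]
    latent = np.array(
        [
            rng.choice(urothelial) if s == "Stroma-rich" else s
            for s in subtype
        ]
    )

    # class signal on marker genes only (keeps regulon/decoy structure clean)
    class_list = sorted(set(latent))
    shifts = {
        c: rng.normal(0.0, spec.marker_shift, size=nm) for c in sorted(set(urothelial))
    }
    for c in class_list:
        if c not in shifts:
            shifts[c] = rng.normal(0.0, spec.marker_shift, size=nm)
    log2_expr = mu[:, None] + sigma[:, None] * z
    for j, s in enumerate(samples):
        log2_expr[nb + nd :, j] += shifts[latent[j]]
    abundance = pd.DataFrame(2.0**log2_expr, index=genes, columns=samples)

    # survival keyed to the regulon score (median split)
    if nb:
        score = ((log2_expr[:nb] - mu[:nb, None]) / sigma[:nb, None]).mean(axis=0)
    else:
        score = rng.standard_normal(n)
    high = score > np.median(score)
    lam0 = np.log(2.0) / spec.median_survival_months
    lam = np.where(high, lam0 * spec.true_hr, lam0)
    t = rng.exponential(1.0 / lam)
    if spec.censor_frac > 0:
        cutoff = np.quantile(t, 1.0 - spec.censor_frac)
        event = (t <= cutoff).astype(int)
        t = np.minimum(t, cutoff)
    else:
        event = np.ones(n, dtype=int)

    clinical = pd.DataFrame(
        {"time": t, "event": event, "subtype": subtype}, index=pd.Index(samples, name="sample_id")
    )
    cohort = ExpressionCohort(abundance, kind="au", clinical=clinical)

    centroids = pd.DataFrame(
        {g: [mu[nb + nd + i] + shifts[c][i] for c in sorted(shifts)] for i, g in enumerate(markers)},
        index=sorted(shifts),
    )
    truth = {
        "samples": pd.DataFrame(
            {
                "group": np.where(high, "high", "low"),
                "subtype": subtype,
                "latent_class": latent,
            },
            index=clinical.index,
        ),
        "genes": pd.DataFrame(
            {
                "gene": genes,
                "role": ["regulon"] * nb + ["decoy"] * nd + ["marker"] * nm,
            }
        ),
        "centroids": centroids,
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# Donor-matched differential expression
# ---------------------------------------------------------------------------

def gen_de_experiment(
    n_donors: int,
    effect_table: pd.Series | dict[str, float],
    seed: int = 0,
    noise_sd: float = 0.1,
    base_log2_tpm: tuple[float, float] = (6.0, 9.0),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Paired control/treated TPM tables with planted per-gene log2FC.

    Returns ``(treated, control, true_log2fc)``; both tables are gene x
    donor with matching donor columns.  Noise is log-normal (sd
    ``noise_sd`` on the log2 scale) on top of a shared per-donor offset.
    """
    if n_donors < 2:
        raise ValueError("n_donors must be >= 2")
    effects = pd.Series(effect_table, dtype=float)
    if base_log2_tpm[0] <= 0:
        raise ValueError("base TPM must be positive")
    rng = np.random.default_rng(seed)
    donors = [f"D{i+1:02d}" for i in range(n_donors)]
    mu = rng.uniform(*base_log2_tpm, size=len(effects))
    donor_off = rng.normal(0.0, 0.3, size=n_donors)
    noise_c = rng.normal(0.0, noise_sd, size=(len(effects), n_donors))
    noise_t = rng.normal(0.0, noise_sd, size=(len(effects), n_donors))
    base = mu[:, None] + donor_off[None, :]
    control = pd.DataFrame(
        2.0 ** (base + noise_c), index=effects.index, columns=donors
    )
    treated = pd.DataFrame(
        2.0 ** (base + effects.to_numpy()[:, None] + noise_t),
        index=effects.index,
        columns=donors,
    )
    return treated, control, effects


# ---------------------------------------------------------------------------
# Functional assays
# ---------------------------------------------------------------------------

@dataclass
class AssaySpec:
    """Wound-closure, TEER and dye-transfer generation parameters.

    Defaults mirror a standard experiment: 2-h imaging over 36 h, six
    replicate scratches, a 2,500 Ohm.cm^2 differentiated baseline and ten
    dye-transfer fields per scratch.
    """

    wc50_true: float = 13.0
    closure_rate: float = 0.35
    sample_interval: float = 2.0
    duration: float = 36.0
    n_replicates: int = 6
    noise_sd: float = 0.0
    teer_baseline: float = 2500.0
    teer_wound_drop: float = 300.0
    teer_recovery_tau: float = 10.0
    dye_mean_index: float = 3.0
    dye_rhod_mean: float = 25.0
    n_fields: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.wc50_true < self.duration:
            raise ValueError("wc50_true must lie within the assay duration")
        if self.teer_baseline <= 0:
            raise ValueError("teer_baseline must be positive")
        if self.sample_interval <= 0 or self.duration <= 0:
            raise ValueError("time parameters must be positive")
        if self.dye_mean_index < 0 or self.dye_rhod_mean <= 0:
            raise ValueError("dye parameters must be positive")


def gen_assay_series(spec: AssaySpec) -> dict[str, pd.DataFrame]:
    """Generate ``wound``, ``teer`` and ``dye`` tables.

    The noiseless wound curve is logistic and crosses 50% exactly at
    ``wc50_true``.  TEER starts at the differentiated baseline (t = 0,
    pre-scratch), drops to ``teer_wound_drop`` and recovers exponentially
    with time constant ``teer_recovery_tau``.  Dye counts are Poisson:
    RhoD with mean ``dye_rhod_mean`` (at least one loaded cell per field)
    and LY conditionally Poisson with mean ``dye_mean_index`` x the
    field's RhoD count.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.arange(0.0, spec.duration + 1e-9, spec.sample_interval)

    wound_rows = []
    for rep in range(spec.n_replicates):
        pct = 100.0 / (1.0 + np.exp(-spec.closure_rate * (times - spec.wc50_true)))
        if spec.noise_sd > 0:
            pct = np.clip(pct + rng.normal(0.0, spec.noise_sd, size=pct.shape), 0, 100)
        for t, v in zip(times, pct):
            wound_rows.append({"replicate": f"R{rep+1}", "time_h": t, "value": v})
    wound = pd.DataFrame(wound_rows)

    teer_rows = []
    for rep in range(spec.n_replicates):
        vals = np.where(
            times == 0.0,
            spec.teer_baseline,
            spec.teer_baseline
            - (spec.teer_baseline - spec.teer_wound_drop)
            * np.exp(-(times - spec.sample_interval) / spec.teer_recovery_tau),
        )
        if spec.noise_sd > 0:
            vals = np.maximum(vals + rng.normal(0.0, spec.noise_sd, size=vals.shape), 1.0)
        for t, v in zip(times, vals):
            teer_rows.append({"replicate": f"R{rep+1}", "time_h": t, "value": v})
    teer = pd.DataFrame(teer_rows)

    n_rhod = np.maximum(rng.poisson(spec.dye_rhod_mean, size=spec.n_fields), 1)
    n_ly = rng.poisson(spec.dye_mean_index * n_rhod)
    dye = pd.DataFrame(
        {
            "field_id": [f"F{i+1}" for i in range(spec.n_fields)],
            "n_ly": n_ly,
            "n_rhod": n_rhod,
        }
    )
    return {"wound": wound, "teer": teer, "dye": dye}
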