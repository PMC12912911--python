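"""Co-regulation refinement of an induced gene set and survival stratification.

Workflow: an in-vitro induced gene list is taken into a tumour expression
cohort, the cohort is restricted to luminal consensus classes (with
stroma-rich samples reassigned to their best-fit urothelial class by
centroid correlation), a pairwise Spearman matrix over the gene set is
computed on log2(TPM+1) values, genes that are not co-regulated with the
rest of the set are pruned away to leave a "regulon", and samples are
split into regulon-high/low groups by k-means for Kaplan-Meier analysis
(log-rank, Gehan-Breslow-Wilcoxon, Mantel-Haenszel hazard ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines import statistics as lls
from scipy import stats
from sklearn.cluster import KMeans

__all__ = [
    "ExpressionCohort",
    "RegulonConfig",
    "RegulonResult",
    "StratificationResult",
    "counts_to_tpm",
    "log2_tpm1",
    "reclassify_stroma_rich",
    "filter_luminal",
    "spearman_matrix",
    "refine_regulon",
    "kmeans_stratify",
    "km_curve",
    "logrank_test",
    "gbw_test",
    "mh_hazard_ratio",
    "stratify_cohort",
    "LUMINAL_CLASSES",
    "CONSENSUS_CLASSES",
]

#: Fixed consensus-class order, also used for deterministic tie-breaking.
CONSENSUS_CLASSES = ("Ba/Sq", "LumP", "LumNS", "LumU", "NE-like")
LUMINAL_CLASSES = frozenset({"LumP", "LumNS", "LumU"})


@dataclass
class ExpressionCohort:
    """Gene-by-sample abundance matrix with per-sample clinical annotation.

    ``abundance`` is indexed by gene id with one column per sample.
    ``kind`` flags the unit: ``counts`` (requires ``gene_length_kb``),
    ``tpm`` (columns must sum to 1e6 within 0.1%) or ``au`` (arbitrary,
    e.g. synthetic log-normal abundances).  ``clinical`` is indexed by
    sample id with columns ``time`` (months), ``event`` (0/1) and
    ``subtype``.
    """

    abundance: pd.DataFrame
    kind: str = "tpm"
    gene_length_kb: pd.Series | None = None
    clinical: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"counts", "tpm", "au"}:
            raise ValueError(f"unknown abundance kind {self.kind!r}")
        if self.kind == "counts" and self.gene_length_kb is None:
            raise ValueError("counts data require gene_length_kb")
        if self.kind == "tpm":
            colsum = self.abundance.sum(axis=0)
            if not np.allclose(colsum, 1e6, rtol=1e-3):
                bad = colsum[~np.isclose(colsum, 1e6, rtol=1e-3)]
                raise ValueError(
                    f"TPM columns must sum to 1e6 within 0.1%; offending "
                    f"samples: {list(bad.index[:5])}"
                )
        if self.clinical is not None:
            missing = [s for s in self.samples if s not in self.clinical.index]
            if missing:
                raise ValueError(f"clinical table missing samples: {missing[:5]}")

    @property
    def genes(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def to_tpm(self) -> "ExpressionCohort":
        """Return a TPM-unit copy (no-op for ``tpm``; error for ``au``)."""
        if self.kind == "tpm":
            return self
        if self.kind == "au":
            raise ValueError("arbitrary-unit abundances cannot be converted to TPM")
        tpm = counts_to_tpm(self.abundance, self.gene_length_kb)
        return ExpressionCohort(tpm, kind="tpm", clinical=self.clinical)


def counts_to_tpm(counts: pd.DataFrame, gene_length_kb: pd.Series) -> pd.DataFrame:
    """Convert a gene x sample count matrix to transcripts per million.

    Per sample: rate_g = counts_g / length_g, TPM_g = 1e6 * rate_g / sum(rate).
    """
    lengths = gene_length_kb.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError(
            f"missing gene lengths for {list(lengths.index[lengths.isna()][:5])}"
        )
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    total = rate.sum(axis=0)
    zero = total[total == 0]
    if len(zero):
        raise ValueError(f"zero total rate in sample(s): {list(zero.index)}")
    return rate.div(total, axis=1) * 1e6


def log2_tpm1(tpm: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Elementwise log2(TPM + 1)."""
    if np.any(np.asarray(tpm) < 0):
        raise ValueError("negative abundance values")
    return np.log2(tpm + 1)


def reclassify_stroma_rich(
    log_expr: pd.DataFrame,
    subtypes: pd.Series,
    centroids: pd.DataFrame,
    metric: str = "pearson",
    stroma_label: str = "Stroma-rich",
) -> pd.Series:
    """Reassign stroma-rich samples to their best-fit urothelial class.

    ``centroids`` is a class x gene table over the five urothelial
    consensus classes.  Each stroma-rich sample is correlated against
    every centroid on the shared gene universe and takes the class of the
    best-correlated centroid; all other samples keep their label.  Ties
    are broken by the fixed class order ``CONSENSUS_CLASSES``.
    """
    if metric not in {"pearson", "spearman"}:
        raise ValueError(f"unknown metric {metric!r}")
    shared = [g for g in centroids.columns if g in log_expr.index]
    if not shared:
        raise ValueError("centroid gene universe does not overlap cohort genes")
    frac = len(shared) / len(centroids.columns)
    if frac < 0.8:
        warnings.warn(
            f"only {frac:.0%} of centroid genes found in cohort", stacklevel=2
        )
    classes = [c for c in CONSENSUS_CLASSES if c in centroids.index]
    cent = centroids.loc[classes, shared].to_numpy(dtype=float)
    out = subtypes.copy()
    for sample in subtypes.index[subtypes == stroma_label]:
        vec = log_expr.loc[shared, sample].to_numpy(dtype=float)
        if metric == "spearman":
            vec = stats.rankdata(vec)
            cc = np.array([stats.rankdata(c) for c in cent])
        else:
            cc = cent
        r = np.array([stats.pearsonr(vec, c).statistic for c in cc])
        out.loc[sample] = classes[int(np.argmax(r))]
    return out


def filter_luminal(
    cohort: ExpressionCohort,
    classes: pd.Series,
    luminal: frozenset[str] | set[str] = LUMINAL_CLASSES,
) -> ExpressionCohort:
    """Restrict a cohort to samples whose final consensus class is luminal."""
    keep = [s for s in cohort.samples if classes.get(s) in luminal]
    if not keep:
        raise ValueError("no luminal samples remain after filtering")
    clinical = cohort.clinical.loc[keep] if cohort.clinical is not None else None
    return ExpressionCohort(
        cohort.abundance[keep],
        kind=cohort.kind,
        gene_length_kb=cohort.gene_length_kb,
        clinical=clinical,
    )


def spearman_matrix(log_expr: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman rho over a gene subset (average-rank ties).

    Rows/columns of zero-variance genes are set to NaN (flagged, not an
    error); the diagonal is 1 for well-defined genes.
    """
    sub = log_expr.loc[genes] if genes is not None else log_expr
    if sub.shape[1] < 3:
        raise ValueError("at least 3 samples are required")
    x = sub.to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, axis=1).statistic
    rho = np.atleast_2d(rho)
    if rho.shape != (len(sub), len(sub)):  # spearmanr collapses the 2-gene case
        r = float(np.ravel(rho)[0]) if rho.size == 1 else float(rho[0, -1])
        rho = np.array([[1.0, r], [r, 1.0]])
    zero_var = x.std(axis=1) == 0
    rho[zero_var, :] = np.nan
    rho[:, zero_var] = np.nan
    np.fill_diagonal(rho, np.where(zero_var, np.nan, 1.0))
    return pd.DataFrame(rho, index=sub.index, columns=sub.index)


@dataclass
class RegulonConfig:
    """Refinement settings.

    ``rho_min`` is the minimum per-gene summary (``mean`` or ``median``)
    off-diagonal Spearman rho in ``rho_threshold`` mode.  ``significance``
    mode instead requires a significant (two-sided P < ``alpha``) positive
    correlation with more than half of the other genes.  ``iterative``
    prunes the weakest gene and re-evaluates until every survivor passes,
    which is required for the retained set to actually satisfy the stated
    criterion among itself; ``iterative=False`` applies a literal single
    pass over the full input set.
    """

    rho_min: float = 0.5
    summary: str = "median"
    mode: str = "rho_threshold"
    alpha: float = 0.05
    iterative: bool = True
    k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho_min < 1:
            raise ValueError("rho_min must be in [0, 1)")
        if self.summary not in {"mean", "median"}:
            raise ValueError(f"unknown summary {self.summary!r}")
        if self.mode not in {"rho_threshold", "significance"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class RegulonResult:
    input_genes: list[str]
    retained_genes: list[str]
    per_gene_summary_rho: pd.Series
    correlation_matrix: pd.DataFrame
    dropped_reasons: dict[str, str] = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        """Per-gene disposition table (gene, summary rho, disposition)."""
        rows = []
        for g in self.input_genes:
            rows.append(
                {
                    "gene": g,
                    "summary_rho": self.per_gene_summary_rho.get(g, np.nan),
                    "disposition": "retained"
                    if g in self.retained_genes
                    else self.dropped_reasons.get(g, "dropped"),
                }
            )
        return pd.DataFrame(rows)


def _rho_p_value(rho: float, n: int) -> float:
    # t-approximation for the null distribution of Spearman rho
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2 * stats.t.sf(abs(t), df=n - 2))


def refine_regulon(
    matrix: pd.DataFrame,
    config: RegulonConfig | None = None,
    n_samples: int | None = None,
) -> RegulonResult:
    """Prune a gene set down to its mutually co-regulated core.

    ``matrix`` is a symmetric Spearman matrix from :func:`spearman_matrix`.
    ``n_samples`` (cohort size) is required in ``significance`` mode.
    """
    config = config or RegulonConfig()
    input_genes = list(matrix.index)
    if len(input_genes) < 2:
        raise ValueError("at least 2 input genes are required")
    if config.mode == "significance" and n_samples is None:
        raise ValueError("significance mode requires n_samples")

    summary_fn = np.nanmean if config.summary == "mean" else np.nanmedian
    dropped: dict[str, str] = {}
    keep = []
    for g in input_genes:
        row = matrix.loc[g].drop(g)
        if row.isna().all():
            dropped[g] = "zero variance"
        else:
            keep.append(g)

    def summaries(genes: list[str]) -> pd.Series:
        sub = matrix.loc[genes, genes].to_numpy(dtype=float).copy()
        np.fill_diagonal(sub, np.nan)
        if config.mode == "rho_threshold":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vals = summary_fn(sub, axis=1)
        else:
            vals = np.empty(len(genes))
            for i in range(len(genes)):
                rhos = sub[i][~np.isnan(sub[i])]
                sig = [
                    r for r in rhos if r > 0 and _rho_p_value(r, n_samples) < config.alpha
                ]
                vals[i] = len(sig) / max(len(rhos), 1)
        return pd.Series(vals, index=genes)

    passes = (lambda s: s > config.rho_min) if config.mode == "rho_threshold" else (
        lambda s: s > 0.5
    )

    if config.iterative:
        while len(keep) >= 2:
            s = summaries(keep)
            ok = passes(s)
            if ok.all():
                break
            # drop the single weakest gene (lexicographic tie-break) and retry
            worst = s[~ok]
            weakest = sorted(worst.index[worst == worst.min()])[0]
            keep.remove(weakest)
            dropped[weakest] = "below threshold"
        if len(keep) < 2 or not passes(summaries(keep)).all():
            for g in list(keep):
                dropped[g] = "below threshold"
            keep = []
    else:
        s = summaries(keep)
        ok = passes(s)
        for g in s.index[~ok]:
            dropped[g] = "below threshold"
        keep = [g for g in keep if ok[g]]

    final_summary = (
        summaries(keep) if len(keep) >= 2 else pd.Series(dtype=float)
    )
    # record the full-set summary for dropped genes, for the report
    all_summary = pd.Series(index=input_genes, dtype=float)
    if len(input_genes) >= 2:
        well_defined = [g for g in input_genes if dropped.get(g) != "zero variance"]
        if len(well_defined) >= 2:
            all_summary.loc[well_defined] = summaries(well_defined)
    all_summary.loc[final_summary.index] = final_summary
    return RegulonResult(
        input_genes=input_genes,
        retained_genes=keep,
        per_gene_summary_rho=all_summary,
        correlation_matrix=matrix,
        dropped_reasons=dropped,
    )


def kmeans_stratify(
    log_expr: pd.DataFrame, config: RegulonConfig | None = None
) -> pd.Series:
    """Split samples into regulon-high/low groups by k-means (k=2, Euclidean).

    ``log_expr`` holds the retained genes (rows) by samples (columns).
    The cluster with the higher mean expression over the gene set is
    labelled ``high``.
    """
    config = config or RegulonConfig()
    if log_expr.shape[0] == 0:
        raise ValueError("retained gene set is empty")
    x = log_expr.to_numpy(dtype=float).T  # samples x genes
    if x.shape[0] < config.k:
        raise ValueError(f"need at least k={config.k} samples")
    if np.allclose(x, x[0]):
        raise ValueError("all samples identical; clustering is degenerate")
    km = KMeans(n_clusters=config.k, n_init=10, random_state=config.seed)
    labels = km.fit_predict(x)
    means = [x[labels == i].mean() for i in range(config.k)]
    high = int(np.argmax(means))
    return pd.Series(
        np.where(labels == high, "high", "low"), index=log_expr.columns, name="group"
    )


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit curve with at-risk counts."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    return pd.DataFrame(
        {
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
            "at_risk": at_risk.to_numpy(dtype=float),
        }
    )


def _check_two_groups(t1, e1, t2, e2):
    t1, e1, t2, e2 = (np.asarray(a, dtype=float) for a in (t1, e1, t2, e2))
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("no events in either group")
    return t1, e1.astype(int), t2, e2.astype(int)


def logrank_test(t1, e1, t2, e2) -> tuple[float, float]:
    """Mantel-Cox log-rank test; returns (chi2, two-sided p)."""
    t1, e1, t2, e2 = _check_two_groups(t1, e1, t2, e2)
    res = lls.logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)


def gbw_test(t1, e1, t2, e2) -> tuple[float, float]:
    """Gehan-Breslow-Wilcoxon test (log-rank weighted by numbers at risk)."""
    t1, e1, t2, e2 = _check_two_groups(t1, e1, t2, e2)
    res = lls.logrank_test(
        t1, t2, event_observed_A=e1, event_observed_B=e2, weightings="wilcoxon"
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class HazardRatio:
    hr: float
    ci_low: float
    ci_high: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def logrank_oe(t1, e1, t2, e2) -> tuple[float, float, float, float, float]:
    """Observed/expected event decomposition of the log-rank statistic.

    Returns (O1, E1, O2, E2, V) accumulated over the pooled event times,
    with E and V from the conditional hypergeometric at each event time.
    """
    t1, e1, t2, e2 = _check_two_groups(t1, e1, t2, e2)
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.concatenate([np.zeros(t1.size), np.ones(t2.size)])
    o1 = e1.sum()
    E1 = 0.0
    V = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    o2 = e2.sum()
    E2 = (o1 + o2) - E1
    return float(o1), float(E1), float(o2), float(E2), float(V)


def mh_hazard_ratio(t1, e1, t2, e2, alpha: float = 0.05) -> HazardRatio:
    """Mantel-Haenszel hazard ratio (O1/E1)/(O2/E2) with log-scale CI."""
    o1, E1, o2, E2, _ = logrank_oe(t1, e1, t2, e2)
    if o1 == 0 or o2 == 0:
        raise ValueError("each group needs at least one event")
    if E1 == 0 or E2 == 0:
        raise ValueError("zero expected events")
    hr = (o1 / E1) / (o2 / E2)
    se = np.sqrt(1.0 / E1 + 1.0 / E2)
    z = stats.norm.ppf(1 - alpha / 2)
    return HazardRatio(
        hr=float(hr),
        ci_low=float(hr * np.exp(-z * se)),
        ci_high=float(hr * np.exp(z * se)),
        observed=(o1, o2),
        expected=(E1, E2),
    )


@dataclass
class StratificationResult:
    assignments: pd.Series
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    logrank_chi2: float
    logrank_p: float
    gbw_chi2: float
    gbw_p: float
    hazard_ratio: HazardRatio

    def stats_dict(self) -> dict:
        return {
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
            "gbw_chi2": self.gbw_chi2,
            "gbw_p": self.gbw_p,
            "hazard_ratio": self.hazard_ratio.hr,
            "hr_ci_low": self.hazard_ratio.ci_low,
            "hr_ci_high": self.hazard_ratio.ci_high,
            "n_high": int((self.assignments == "high").sum()),
            "n_low": int((self.assignments == "low").sum()),
        }


def stratify_cohort(
    cohort: ExpressionCohort,
    retained_genes: list[str],
    config: RegulonConfig | None = None,
) -> StratificationResult:
    """K-means stratification + survival comparison of high vs low groups."""
    config = config or RegulonConfig()
    if cohort.clinical is None:
        raise ValueError("cohort has no clinical annotation")
    expr = cohort.abundance if cohort.kind == "au" else cohort.to_tpm().abundance
    log_expr = log2_tpm1(expr.loc[retained_genes])
    groups = kmeans_stratify(log_expr, config)
    clin = cohort.clinical
    hi = groups.index[groups == "high"]
    lo = groups.index[groups == "low"]
    t1, e1 = clin.loc[hi, "time"], clin.loc[hi, "event"]
    t2, e2 = clin.loc[lo, "time"], clin.loc[lo, "event"]
    chi2, p = logrank_test(t1, e1, t2, e2)
    gchi2, gp = gbw_test(t1, e1, t2, e2)
    return StratificationResult(
        assignments=groups,
        km_high=km_curve(t1, e1),
        km_low=km_curve(t2, e2),
        logrank_chi2=chi2,
        logrank_p=p,
        gbw_chi2=gchi2,
        gbw_p=gp,
        hazard_ratio=mh_hazard_ratio(t1, e1, t2, e2),
    )
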