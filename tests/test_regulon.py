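"""Regulon refinement and survival statistics, including brute-force
oracles for the rank correlation, product-limit and log-rank machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uroquant import regulon as reg, simulate as sim


# ---------------------------------------------------------------------------
# TPM conversion and log transform
# ---------------------------------------------------------------------------

class TestCountsToTpm:
    def test_single_gene_is_one_million(self):
        counts = pd.DataFrame({"s1": [37.0]}, index=["G1"])
        tpm = reg.counts_to_tpm(counts, pd.Series({"G1": 1.5}))
        assert tpm.loc["G1", "s1"] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths_split_evenly(self):
        counts = pd.DataFrame({"s1": [10.0, 10.0]}, index=["A", "B"])
        tpm = reg.counts_to_tpm(counts, pd.Series({"A": 2.0, "B": 2.0}))
        assert tpm["s1"].tolist() == pytest.approx([5e5, 5e5])

    def test_length_normalisation_hand_computed(self):
        # rates (10/2, 90/1) = (5, 90); TPM = 1e6 * rate / 95
        counts = pd.DataFrame({"s1": [10.0, 90.0]}, index=["A", "B"])
        tpm = reg.counts_to_tpm(counts, pd.Series({"A": 2.0, "B": 1.0}))
        assert tpm["s1"].tolist() == pytest.approx([52631.6, 947368.4], abs=0.1)

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(30, 8)).astype(float),
            index=[f"G{i}" for i in range(30)],
        )
        lengths = pd.Series(rng.uniform(0.5, 5, 30), index=counts.index)
        tpm = reg.counts_to_tpm(counts, lengths)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_zero_sample_named_in_error(self):
        counts = pd.DataFrame({"good": [5.0], "empty": [0.0]}, index=["G1"])
        with pytest.raises(ValueError, match="empty"):
            reg.counts_to_tpm(counts, pd.Series({"G1": 1.0}))


def test_log2_tpm1_values_and_negative_rejection():
    mat = pd.DataFrame({"s": [0.0, 1.0, 7.0]})
    assert reg.log2_tpm1(mat)["s"].tolist() == [0.0, 1.0, 3.0]
    with pytest.raises(ValueError):
        reg.log2_tpm1(pd.DataFrame({"s": [-1.0]}))


# ---------------------------------------------------------------------------
# Subtype handling
# ---------------------------------------------------------------------------

class TestReclassify:
    def _toy(self):
        genes = [f"g{i}" for i in range(6)]
        centroids = pd.DataFrame(
            np.arange(30).reshape(5, 6) % 7,
            index=list(reg.CONSENSUS_CLASSES),
            columns=genes,
        ).astype(float)
        return genes, centroids

    def test_self_match(self):
        genes, centroids = self._toy()
        expr = pd.DataFrame({"s1": centroids.loc["LumP"]}, index=genes)
        classes = reg.reclassify_stroma_rich(
            expr, pd.Series({"s1": "Stroma-rich"}), centroids
        )
        assert classes["s1"] == "LumP"

    def test_anticorrelated_with_all_but_one(self):
        genes = [f"g{i}" for i in range(6)]
        v = np.array([1.0, 2, 3, 4, 5, 6])
        centroids = pd.DataFrame(
            [-v, -v, v, -v, -v],
            index=list(reg.CONSENSUS_CLASSES),
            columns=genes,
        )
        expr = pd.DataFrame({"s1": v}, index=genes)
        classes = reg.reclassify_stroma_rich(
            expr, pd.Series({"s1": "Stroma-rich"}), centroids
        )
        assert classes["s1"] == "LumNS"

    def test_non_stroma_samples_unchanged(self):
        genes, centroids = self._toy()
        expr = pd.DataFrame({"s1": centroids.loc["LumP"]}, index=genes)
        classes = reg.reclassify_stroma_rich(
            expr, pd.Series({"s1": "Ba/Sq"}), centroids
        )
        assert classes["s1"] == "Ba/Sq"

    def test_planted_cohort_accuracy(self):
        spec = sim.CohortSpec(n_samples=250, seed=13)
        cohort, truth = sim.gen_cohort(spec)
        log_expr = reg.log2_tpm1(cohort.abundance)
        classes = reg.reclassify_stroma_rich(
            log_expr, cohort.clinical["subtype"], truth["centroids"]
        )
        sr = cohort.clinical["subtype"] == "Stroma-rich"
        latent = truth["samples"].loc[sr[sr].index, "latent_class"]
        assert (classes[sr] == latent).mean() >= 0.95

    def test_empty_overlap_rejected(self):
        genes, centroids = self._toy()
        expr = pd.DataFrame({"s1": [1.0]}, index=["other"])
        with pytest.raises(ValueError):
            reg.reclassify_stroma_rich(
                expr, pd.Series({"s1": "Stroma-rich"}), centroids
            )


class TestFilterLuminal:
    def _cohort(self, subtypes):
        n = len(subtypes)
        abundance = pd.DataFrame(
            np.ones((2, n)), index=["A", "B"], columns=[f"s{i}" for i in range(n)]
        )
        clinical = pd.DataFrame(
            {"time": [10.0] * n, "event": [1] * n, "subtype": subtypes},
            index=abundance.columns,
        )
        return reg.ExpressionCohort(abundance, kind="au", clinical=clinical)

    def test_only_luminal_retained(self):
        cohort = self._cohort(["LumP", "Ba/Sq", "NE-like"])
        out = reg.filter_luminal(cohort, cohort.clinical["subtype"])
        assert out.samples == ["s0"]

    def test_reclassified_basal_excluded(self):
        cohort = self._cohort(["LumP", "Stroma-rich"])
        classes = pd.Series({"s0": "LumP", "s1": "Ba/Sq"})  # post-reclassification
        out = reg.filter_luminal(cohort, classes)
        assert out.samples == ["s0"]

    def test_all_basal_errors(self):
        cohort = self._cohort(["Ba/Sq", "Ba/Sq"])
        with pytest.raises(ValueError):
            reg.filter_luminal(cohort, cohort.clinical["subtype"])


# ---------------------------------------------------------------------------
# Spearman matrix
# ---------------------------------------------------------------------------

def _rank_average(x):
    """Average-rank assignment, written out longhand as the oracle."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sx = np.asarray(x, dtype=float)[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


class TestSpearmanMatrix:
    def test_monotone_pair_is_one(self):
        expr = pd.DataFrame(
            {"s1": [1, 2], "s2": [2, 4], "s3": [5, 10], "s4": [3, 6]},
            index=["A", "B"],
        ).astype(float)
        mat = reg.spearman_matrix(expr)
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_reversed_pair_is_minus_one(self):
        expr = pd.DataFrame(
            {"s1": [1, -1], "s2": [2, -2], "s3": [5, -5]}, index=["A", "B"]
        ).astype(float)
        assert reg.spearman_matrix(expr).loc["A", "B"] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        """Six samples with ties agree with Pearson on average ranks."""
        a = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0])
        b = np.array([2.0, 1.0, 4.0, 4.0, 4.0, 6.0])
        expr = pd.DataFrame([a, b], index=["A", "B"],
                            columns=[f"s{i}" for i in range(6)])
        mat = reg.spearman_matrix(expr)
        oracle = stats.pearsonr(_rank_average(a), _rank_average(b)).statistic
        assert mat.loc["A", "B"] == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.uniform(1, 50, size=(4, 30)),
                            index=list("ABCD"))
        m1 = reg.spearman_matrix(expr)
        m2 = reg.spearman_matrix(np.exp(expr / 10.0))
        pd.testing.assert_frame_equal(m1, m2)

    def test_zero_variance_flagged_not_fatal(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 7.0], "s2": [2.0, 7.0], "s3": [3.0, 7.0]},
            index=["A", "FLAT"],
        )
        mat = reg.spearman_matrix(expr)
        assert np.isnan(mat.loc["FLAT"]).all()
        assert mat.loc["A", "A"] == 1.0

    def test_too_few_samples_rejected(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0], "s2": [2.0, 1.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            reg.spearman_matrix(expr)


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def _planted_matrix(seed, n=300, nb=25, nd=25, rho=0.7):
    spec = sim.CohortSpec(n_samples=n, block_rho=rho, seed=seed)
    cohort, _ = sim.gen_cohort(spec)
    log_expr = reg.log2_tpm1(cohort.abundance)
    genes = spec.regulon_genes + spec.decoy_genes
    return spec, reg.spearman_matrix(log_expr, genes)


class TestRefineRegulon:
    def test_planted_block_retained_both_modes(self):
        spec, mat = _planted_matrix(seed=31)
        for mode in ("rho_threshold", "significance"):
            res = reg.refine_regulon(
                mat, reg.RegulonConfig(mode=mode), n_samples=300
            )
            assert set(res.retained_genes) == set(spec.regulon_genes), mode

    def test_independent_genes_all_rejected(self):
        spec, mat = _planted_matrix(seed=32, rho=0.0)
        res = reg.refine_regulon(mat, reg.RegulonConfig(), n_samples=300)
        assert res.retained_genes == []
        assert all(v == "below threshold" for v in res.dropped_reasons.values())

    def test_comonotone_pair_retained(self):
        expr = pd.DataFrame(
            {"s1": [1.0, 2.0], "s2": [2.0, 4.0], "s3": [3.0, 9.0]},
            index=["A", "B"],
        )
        mat = reg.spearman_matrix(expr)
        res = reg.refine_regulon(mat, reg.RegulonConfig())
        assert set(res.retained_genes) == {"A", "B"}

    def test_monotone_in_rho_min(self):
        _, mat = _planted_matrix(seed=33)
        keep_05 = set(
            reg.refine_regulon(mat, reg.RegulonConfig(rho_min=0.5)).retained_genes
        )
        keep_06 = set(
            reg.refine_regulon(mat, reg.RegulonConfig(rho_min=0.6)).retained_genes
        )
        assert keep_06 <= keep_05

    def test_every_input_gene_has_one_disposition(self):
        spec, mat = _planted_matrix(seed=34)
        res = reg.refine_regulon(mat, reg.RegulonConfig(), n_samples=300)
        report = res.report()
        assert sorted(report["gene"]) == sorted(res.input_genes)
        retained = set(report.loc[report["disposition"] == "retained", "gene"])
        assert retained == set(res.retained_genes)
        assert retained.isdisjoint(res.dropped_reasons)

    def test_single_gene_rejected(self):
        mat = pd.DataFrame([[1.0]], index=["A"], columns=["A"])
        with pytest.raises(ValueError):
            reg.refine_regulon(mat)


class TestKmeansStratify:
    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.0, 0.1, size=(5, 30))
        b = rng.normal(4.0, 0.1, size=(5, 30))
        expr = pd.DataFrame(
            np.hstack([a, b]), index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(60)],
        )
        groups = reg.kmeans_stratify(expr, reg.RegulonConfig(seed=0))
        assert (groups.iloc[:30] == "low").all()
        assert (groups.iloc[30:] == "high").all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            np.hstack([rng.normal(0, 0.2, (4, 20)), rng.normal(3, 0.2, (4, 20))]),
            index=list("ABCD"), columns=[f"s{i}" for i in range(40)],
        )
        g1 = reg.kmeans_stratify(expr, reg.RegulonConfig(seed=0))
        perm = rng.permutation(expr.columns)
        g2 = reg.kmeans_stratify(expr[perm], reg.RegulonConfig(seed=0))
        assert (g2.reindex(g1.index) == g1).all()

    def test_fewer_samples_than_k_rejected(self):
        expr = pd.DataFrame({"s1": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ValueError):
            reg.kmeans_stratify(expr)

    def test_identical_samples_degenerate(self):
        expr = pd.DataFrame(np.ones((3, 10)), index=list("ABC"))
        with pytest.raises(ValueError):
            reg.kmeans_stratify(expr)


# ---------------------------------------------------------------------------
# Survival statistics
# ---------------------------------------------------------------------------

def _km_oracle(times, events):
    """Brute-force product-limit over distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = {}
    for t in sorted(set(times[events == 1])):
        n_at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / n_at_risk
        out[t] = s
    return out


class TestKmCurve:
    def test_all_censored_stays_at_one(self):
        curve = reg.km_curve([3.0, 6.0, 9.0], [0, 0, 0])
        assert (curve["survival"] == 1.0).all()

    def test_two_events_closed_form(self):
        curve = reg.km_curve([1.0, 2.0], [1, 1]).set_index("time")
        assert curve.loc[1.0, "survival"] == pytest.approx(0.5)
        assert curve.loc[2.0, "survival"] == pytest.approx(0.0)

    def test_ten_subject_worked_set_matches_oracle(self):
        times = [1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 6.0, 8.0, 9.0, 11.0]
        events = [1, 1, 0, 1, 0, 1, 1, 0, 1, 0]
        curve = reg.km_curve(times, events).set_index("time")
        for t, s in _km_oracle(times, events).items():
            assert curve.loc[t, "survival"] == pytest.approx(s, abs=1e-12)

    def test_curve_non_increasing_from_one(self):
        df = sim.gen_survival(80, 1.5, seed=40)
        curve = reg.km_curve(df["time"], df["event"])
        assert curve["survival"].iloc[0] <= 1.0
        assert (np.diff(curve["survival"]) <= 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reg.km_curve([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t = [2.0, 4.0, 6.0, 8.0]
        e = [1, 0, 1, 1]
        chi2, p = reg.logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_six_subject_example_matches_brute_force(self):
        """(O1-E1)^2 / V from explicit 2x2 tables at each event time."""
        t1, e1 = [1.0, 4.0, 6.0], [1, 1, 0]
        t2, e2 = [2.0, 3.0, 7.0], [1, 1, 1]
        o1, E1, o2, E2, V = reg.logrank_oe(t1, e1, t2, e2)
        chi2, p = reg.logrank_test(t1, e1, t2, e2)
        assert chi2 == pytest.approx((o1 - E1) ** 2 / V, rel=1e-9)
        assert p == pytest.approx(2 * stats.norm.sf(abs(o1 - E1) / np.sqrt(V)), rel=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            reg.logrank_test([1.0], [1], [], [])


class TestGbw:
    def test_identical_groups_null(self):
        t, e = [1.0, 2.0, 5.0], [1, 1, 0]
        _, p = reg.gbw_test(t, e, t, e)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_early_difference_upweighted(self):
        """A large early gap with late convergence scores higher under the
        at-risk weighting than under the plain log-rank."""
        t1 = [1.0, 1.5, 2.0, 2.5, 3.0] + [20.0] * 10
        e1 = [1] * 5 + [1] * 10
        t2 = [10.0] * 5 + [20.0] * 10
        e2 = [1] * 5 + [1] * 10
        chi2_lr, _ = reg.logrank_test(t1, e1, t2, e2)
        chi2_gbw, _ = reg.gbw_test(t1, e1, t2, e2)
        assert chi2_gbw > chi2_lr

    def test_matches_weighted_oracle_without_censoring(self):
        """With no censoring the GBW statistic equals the n-weighted O-E
        sum computed directly."""
        t1, e1 = [1.0, 3.0, 5.0], [1, 1, 1]
        t2, e2 = [2.0, 4.0, 6.0], [1, 1, 1]
        times = np.array(t1 + t2)
        group = np.array([0] * 3 + [1] * 3)
        num = 0.0
        var = 0.0
        for t in sorted(times):
            at = times >= t
            n = at.sum()
            n1 = (at & (group == 0)).sum()
            d = (times == t).sum()
            num += n * (int(t in t1) - d * n1 / n)
            if n > 1:
                var += n**2 * d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2, _ = reg.gbw_test(t1, e1, t2, e2)
        assert chi2 == pytest.approx(num**2 / var, rel=1e-9)


class TestHazardRatio:
    def test_exchangeable_groups_unity(self):
        t, e = [1.0, 2.0, 3.0, 4.0], [1, 1, 1, 0]
        hr = reg.mh_hazard_ratio(t, e, t, e)
        assert hr.hr == pytest.approx(1.0)

    def test_label_swap_inverts(self):
        df = sim.gen_survival(120, 2.0, seed=41)
        hi, lo = df[df["group"] == "high"], df[df["group"] == "low"]
        a = reg.mh_hazard_ratio(hi["time"], hi["event"], lo["time"], lo["event"])
        b = reg.mh_hazard_ratio(lo["time"], lo["event"], hi["time"], hi["event"])
        assert a.hr == pytest.approx(1.0 / b.hr, rel=1e-9)

    def test_ci_coverage_under_truth(self):
        """95% CI covers the generating hazard ratio in most of 60 runs."""
        cover = 0
        for s in range(60):
            df = sim.gen_survival(400, 2.0, seed=500 + s)
            hi, lo = df[df["group"] == "high"], df[df["group"] == "low"]
            hr = reg.mh_hazard_ratio(hi["time"], hi["event"], lo["time"], lo["event"])
            cover += hr.ci_low <= 2.0 <= hr.ci_high
        assert cover >= 51  # ~95% nominal; allow binomial slack

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            reg.mh_hazard_ratio([1.0, 2.0], [0, 0], [1.0], [1])


class TestEndToEnd:
    def test_pipeline_recovers_regulon_and_hazard(self):
        """Full chain on a planted cohort: reclassify, restrict to luminal,
        refine, stratify; the regulon is recovered and the HR CI covers
        the generating value in >= 90% of seeded runs."""
        n_runs, cover, exact = 30, 0, 0
        for s in range(n_runs):
            spec = sim.CohortSpec(n_samples=400, true_hr=1.8, seed=900 + s)
            cohort, truth = sim.gen_cohort(spec)
            log_expr = reg.log2_tpm1(cohort.abundance)
            classes = reg.reclassify_stroma_rich(
                log_expr, cohort.clinical["subtype"], truth["centroids"]
            )
            lum = reg.filter_luminal(cohort, classes)
            mat = reg.spearman_matrix(
                reg.log2_tpm1(lum.abundance), spec.regulon_genes + spec.decoy_genes
            )
            res = reg.refine_regulon(mat, reg.RegulonConfig(), n_samples=len(lum.samples))
            exact += set(res.retained_genes) == set(spec.regulon_genes)
            strat = reg.stratify_cohort(cohort, res.retained_genes, reg.RegulonConfig())
            cover += strat.hazard_ratio.ci_low <= 1.8 <= strat.hazard_ratio.ci_high
        assert exact == n_runs
        assert cover / n_runs >= 0.9
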