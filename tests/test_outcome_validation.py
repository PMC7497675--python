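"""ROC dichotomization, Mann–Whitney, Kaplan–Meier and log-rank checks."""

import numpy as np
import pytest

from chemoselect import (
    ExpressionCohort,
    km_estimate,
    logrank_test,
    mann_whitney,
    read_cohort,
    roc_dichotomize,
    validate_genes,
)

import pandas as pd


class TestRocDichotomize:
    def test_perfect_separation(self):
        auc, cut = roc_dichotomize([1, 2, 3, 4], [0, 0, 1, 1])
        assert auc == 1.0 and cut == 2.5

    def test_constant_expression_is_uninformative(self):
        auc, cut = roc_dichotomize([2.0] * 6, [0, 0, 0, 1, 1, 1])
        assert auc == 0.5 and cut == 2.0

    def test_orientation_keeps_auc_above_half(self):
        auc, _ = roc_dichotomize([4, 3, 2, 1], [0, 0, 1, 1])
        assert auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_dichotomize([1, 2, 3], [1, 1, 1])

    def test_matches_exhaustive_threshold_scan(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=20)
        s = (rng.random(20) < 0.4).astype(int)
        if s.sum() in (0, len(s)):
            s[0] = 1 - s[0]
        auc, cut = roc_dichotomize(v, s)
        # brute force over all midpoint thresholds, same orientation rule
        ranks = pd.Series(v).rank().to_numpy()
        n1, n0 = s.sum(), len(s) - s.sum()
        raw_auc = (ranks[s == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
        flip = raw_auc < 0.5
        assert auc == pytest.approx(max(raw_auc, 1 - raw_auc), abs=1e-12)
        uniq = np.unique(v)
        best_j, best_cut = -np.inf, None
        for c in (uniq[:-1] + uniq[1:]) / 2:
            hi = v > c
            pos = (s == 0) if flip else (s == 1)
            j = (hi & pos).sum() / pos.sum() + ((~hi) & ~pos).sum() / (~pos).sum() - 1
            if j > best_j + 1e-12:
                best_j, best_cut = j, c
        hi = v > cut
        pos = (s == 0) if flip else (s == 1)
        got_j = (hi & pos).sum() / pos.sum() + ((~hi) & ~pos).sum() / (~pos).sum() - 1
        assert got_j == pytest.approx(best_j, abs=1e-12)

    def test_auc_equals_mann_whitney_u_identity(self):
        rng = np.random.default_rng(4)
        v = rng.normal(size=40)
        s = np.array([0] * 25 + [1] * 15)
        auc, _ = roc_dichotomize(v, s)
        u, _ = mann_whitney(v[s == 1], v[s == 0])
        raw = u / (15 * 25)
        assert auc == pytest.approx(max(raw, 1 - raw), abs=1e-12)


class TestMannWhitney:
    def test_exact_small_sample(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_samples_uninformative(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_asymptotic_agrees_with_permutation_oracle(self):
        """Tie-corrected normal approximation vs label-permutation null."""
        rng = np.random.default_rng(12)
        x = rng.normal(0.25, 1, size=300)
        y = rng.normal(0.0, 1, size=300)
        _, p = mann_whitney(x, y)
        from scipy.stats import PermutationMethod, mannwhitneyu

        ref = mannwhitneyu(
            x, y, alternative="two-sided",
            method=PermutationMethod(n_resamples=100_000, batch=2_000, rng=1),
        )
        assert p == pytest.approx(ref.pvalue, abs=1e-3)


class TestKaplanMeier:
    def test_all_events_stepwise_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1])
        assert km(0.5) == 1.0
        assert km(1) == pytest.approx(2 / 3)
        assert km(2) == pytest.approx(1 / 3)
        assert km(3) == 0.0

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km(100) == 1.0

    def test_censoring_enters_risk_set(self):
        km = km_estimate([5, 8], [1, 0])
        assert km(5) == 0.5

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])

    def test_monotone_and_median_without_censoring(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, size=51)
        km = km_estimate(times, np.ones(51))
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert km.median() == pytest.approx(np.median(times))

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(10)
        t = rng.exponential(12, size=80)
        e = (rng.random(80) < 0.7).astype(int)
        km = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for q in np.quantile(t, [0.1, 0.4, 0.7, 0.95]):
            assert km(q) == pytest.approx(
                float(kmf.survival_function_at_times(q).iloc[0]), abs=1e-10
            )


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        t = [1, 2, 3, 1, 2, 3]
        e = [1, 1, 1, 1, 1, 1]
        g = [0, 0, 0, 1, 1, 1]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_no_events_flagged_as_uninformative(self):
        chi2, p = logrank_test([1, 2, 3, 4], [0, 0, 0, 0], [0, 0, 1, 1])
        assert (chi2, p) == (0.0, 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [1, 1])

    def test_agrees_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        t = np.concatenate([rng.exponential(8, 40), rng.exponential(16, 40)])
        e = (rng.random(80) < 0.8).astype(int)
        g = np.array([0] * 40 + [1] * 40)
        chi2, p = logrank_test(t, e, g)
        ref = ll_logrank(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_matches_permutation_null_on_small_fixture(self):
        rng = np.random.default_rng(21)
        t = rng.exponential(10, size=24)
        e = np.ones(24, dtype=int)
        g = np.array([0, 1] * 12)
        chi2, p = logrank_test(t, e, g)
        stats = []
        for _ in range(10_000):
            stats.append(logrank_test(t, e, rng.permutation(g))[0])
        perm_p = np.mean(np.asarray(stats) >= chi2 - 1e-12)
        assert p == pytest.approx(perm_p, abs=0.03)


def make_cohort(rng, n=200, genes=("G1", "G2", "G3"), prognostic=()):
    z = rng.standard_normal((n, len(genes)))
    loghaz = np.log(1 / 60) + sum(
        np.log(2) * z[:, i] for i, g in enumerate(genes) if g in prognostic
    )
    t_event = rng.exponential(1 / np.exp(loghaz), size=n)
    t_cens = rng.uniform(1, 200, n)
    df = pd.DataFrame(z, columns=list(genes))
    df.index = [f"M{i}" for i in range(n)]
    return ExpressionCohort(
        df,
        pd.Series(np.minimum(t_event, t_cens), index=df.index),
        pd.Series((t_event <= t_cens).astype(int), index=df.index),
    )


class TestValidateGenes:
    def test_planted_prognostic_gene_detected(self):
        rng = np.random.default_rng(17)
        genes = tuple(f"G{i}" for i in range(14))
        hits = 0
        for _ in range(20):
            cohort = make_cohort(rng, n=300, genes=genes, prognostic=("G0",))
            results = {r.gene: r for r in validate_genes(cohort, genes)}
            hits += results["G0"].significant
        assert hits >= 18

    def test_null_cohort_rarely_significant(self):
        rng = np.random.default_rng(18)
        genes = tuple(f"G{i}" for i in range(14))
        n_sig = []
        for _ in range(30):
            cohort = make_cohort(rng, n=200, genes=genes)
            results = validate_genes(cohort, genes)
            n_sig.append(sum(r.significant for r in results))
        assert np.mean([s > 0 for s in n_sig]) <= 0.15

    def test_constant_gene_not_significant(self):
        rng = np.random.default_rng(19)
        cohort = make_cohort(rng, n=100, genes=("G1", "G2"))
        cohort.expression["G1"] = 0.0
        results = {r.gene: r for r in validate_genes(cohort, ["G1", "G2"])}
        assert results["G1"].auc == 0.5
        assert not results["G1"].significant

    def test_absent_genes_skipped(self):
        rng = np.random.default_rng(20)
        cohort = make_cohort(rng, n=60)
        results = validate_genes(cohort, ["G1", "MISSING"])
        assert [r.gene for r in results] == ["G1"]

    def test_cohort_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(23)
        cohort = make_cohort(rng, n=30)
        path = tmp_path / "cohort.tsv"
        df = cohort.expression.copy()
        df.insert(0, "patient_id", df.index)
        df.insert(1, "survival_time", cohort.survival_time)
        df.insert(2, "event", cohort.event)
        df.to_csv(path, sep="\t", index=False)
        loaded = read_cohort(str(path))
        assert loaded.expression.shape == cohort.expression.shape
        assert list(loaded.genes) == list(cohort.genes)
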