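"""Variance-explained machinery: likelihood oracles, resampling,
label-noise bookkeeping and contingency tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from ibdprofiler.cohort_io import PhenotypeTable
from ibdprofiler.model_eval import (
    FactorSet,
    NoisePlan,
    auc_and_youden,
    bootstrap_metric,
    conditional_variance,
    contingency_chi2,
    flip_labels,
    marginal_variance,
    nagelkerke_r2,
    or_per_sd,
    repeated_cv,
)


def nagelkerke_oracle(y, X0, X1):
    """Both likelihoods by direct numerical optimization (BFGS on the
    negative Bernoulli log-likelihood), independent of the IRLS path."""
    def nll(beta, X):
        eta = X @ beta
        return -(y @ eta - np.logaddexp(0, eta).sum())

    def maxll(X):
        res = optimize.minimize(nll, np.zeros(X.shape[1]), args=(X,),
                                method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        return -res.fun

    n = len(y)
    l0, l1 = maxll(X0), maxll(X1)
    cs = 1 - math.exp(2 * (l0 - l1) / n)
    return cs / (1 - math.exp(2 * l0 / n))


def _design(n, k, seed):
    rng = np.random.default_rng(seed)
    return np.column_stack([np.ones(n), rng.standard_normal((n, k))])


class TestNagelkerke:
    def test_identical_designs_zero(self):
        rng = np.random.default_rng(0)
        y = rng.binomial(1, 0.5, 100)
        X = _design(100, 2, 1)
        assert nagelkerke_r2(y, X, X).r2 == pytest.approx(0.0, abs=1e-10)

    def test_matches_direct_likelihood_oracle(self):
        """200-sample fixture agrees with an independent direct-likelihood
        optimizer to 1e-8."""
        rng = np.random.default_rng(2)
        n = 200
        X0 = _design(n, 3, 3)
        score = rng.standard_normal(n)
        eta = 0.8 * score + 0.3 * X0[:, 1]
        y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
        X1 = np.column_stack([X0, score])
        res = nagelkerke_r2(y, X0, X1)
        assert res.r2 == pytest.approx(nagelkerke_oracle(y, X0, X1), abs=1e-8)
        assert res.loglik_alt >= res.loglik_baseline

    def test_affine_invariance_of_score_column(self):
        rng = np.random.default_rng(4)
        n = 300
        X0 = _design(n, 2, 5)
        score = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-score)))
        X1 = np.column_stack([X0, score])
        X1b = np.column_stack([X0, -3.7 * score + 11.0])
        r_a = nagelkerke_r2(y, X0, X1).r2
        r_b = nagelkerke_r2(y, X0, X1b).r2
        assert r_a == pytest.approx(r_b, abs=1e-8)

    def test_perfect_separator_saturates(self):
        rng = np.random.default_rng(6)
        n = 200
        X0 = np.ones((n, 1))
        y = rng.binomial(1, 0.5, n)
        X1 = np.column_stack([X0, 2.0 * y - 1.0])
        res = nagelkerke_r2(y, X0, X1)
        assert res.r2 >= 0.99
        assert res.capped

    def test_non_nested_designs_error(self):
        rng = np.random.default_rng(7)
        y = rng.binomial(1, 0.5, 50)
        X0 = _design(50, 2, 8)
        X1 = _design(50, 3, 9)  # different columns entirely
        with pytest.raises(ValueError, match="nested"):
            nagelkerke_r2(y, X0, X1)


def _factor_phenotypes(n=800, seed=0, bio_from_liability=0.0):
    """Phenotypes with PCs + biomarkers + smoking; liability recorded."""
    rng = np.random.default_rng(seed)
    liability = rng.standard_normal(n)
    smoking = rng.choice(["Never", "Quit", "Current"], n, p=[0.5, 0.25, 0.25])
    eta = 1.0 * liability
    y = rng.binomial(1, 1 / (1 + np.exp(-eta)))
    df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)], "subtype": y,
                       "smoking": smoking})
    for k in range(10):
        df[f"pc{k + 1}"] = rng.standard_normal(n)
    for name in ("ASCA-IgA", "ANCA", "CBir1"):
        df[name] = (
            0.6 * y + bio_from_liability * liability + rng.standard_normal(n)
        )
    return PhenotypeTable(df), liability


class TestMarginalConditional:
    def test_empty_subset_errors(self):
        pheno, liab = _factor_phenotypes()
        fs = FactorSet(pheno, prs=liab)
        with pytest.raises(ValueError, match="empty"):
            marginal_variance(fs, [])

    def test_full_model_dominates_single_blocks(self):
        pheno, liab = _factor_phenotypes(seed=1)
        fs = FactorSet(pheno, prs=liab)
        full = marginal_variance(fs, ["prs", "biomarkers", "smoking"]).r2
        for block in ("prs", "biomarkers", "smoking"):
            assert full >= marginal_variance(fs, block).r2 - 1e-10

    def test_conditional_equals_marginal_for_independent_noise_block(self):
        """Conditioning on pure-noise biomarkers (independent of both the
        outcome and the PRS) leaves the PRS contribution unchanged."""
        rng = np.random.default_rng(2)
        n = 4000
        liability = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-liability)))
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "subtype": y})
        for k in range(10):
            df[f"pc{k + 1}"] = rng.standard_normal(n)
        for name in ("ASCA-IgA", "ANCA", "CBir1"):
            df[name] = rng.standard_normal(n)
        fs = FactorSet(PhenotypeTable(df), prs=liability)
        marg = marginal_variance(fs, "prs").r2
        cond = conditional_variance(fs, "prs", ["biomarkers"]).r2
        assert abs(marg - cond) < 0.02

    def test_conditional_shrinks_when_biomarkers_share_liability(self):
        pheno, liab = _factor_phenotypes(n=2000, seed=3, bio_from_liability=0.8)
        fs = FactorSet(pheno, prs=liab)
        marg = marginal_variance(fs, "prs").r2
        cond = conditional_variance(fs, "prs", ["biomarkers"]).r2
        assert cond < marg

    def test_target_in_conditioning_errors(self):
        pheno, liab = _factor_phenotypes(seed=4)
        fs = FactorSet(pheno, prs=liab)
        with pytest.raises(ValueError, match="conditioning"):
            conditional_variance(fs, "prs", ["prs", "smoking"])


class TestOrPerSd:
    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 30
        score = rng.standard_normal(n)
        y = rng.binomial(1, 1 / (1 + np.exp(-score)))
        y[:2] = [0, 1]
        or_hat, (lo, hi) = or_per_sd(y, score)
        z = (score - score.mean()) / score.std()
        fit = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
        assert math.log(or_hat) == pytest.approx(fit.params[1], abs=1e-6)
        assert math.log(lo) == pytest.approx(
            fit.params[1] - 1.959964 * fit.bse[1], abs=1e-5
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        score = rng.standard_normal(500)
        y = rng.binomial(1, 1 / (1 + np.exp(-score)))
        a, _ = or_per_sd(y, score)
        b, _ = or_per_sd(y, 2.0 * score)
        assert a == pytest.approx(b, rel=1e-8)

    def test_null_coverage(self):
        rng = np.random.default_rng(7)
        cover = 0
        for _ in range(200):
            y = rng.binomial(1, 0.5, 120)
            score = rng.standard_normal(120)
            _, (lo, hi) = or_per_sd(y, score)
            cover += lo <= 1.0 <= hi
        assert 0.90 <= cover / 200 <= 0.99

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            or_per_sd(np.array([0, 1, 0, 1]), np.ones(4))


class TestAucYouden:
    def test_perfect_score(self):
        y = np.array([0, 0, 1, 1])
        auc, thr, sens, spec = auc_and_youden(y, y.astype(float))
        assert (auc, sens, spec) == (1.0, 1.0, 1.0)

    def test_random_score_near_half(self):
        rng = np.random.default_rng(8)
        y = rng.binomial(1, 0.5, 2000)
        auc, *_ = auc_and_youden(y, rng.standard_normal(2000))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_matches_pair_counting_oracle(self):
        y = np.array([1, 0, 1, 0, 1, 0, 0, 1, 0, 1])
        s = np.array([3.2, 1.0, 2.5, 2.5, 4.0, 0.5, 2.0, 1.5, 3.0, 3.0])
        auc, *_ = auc_and_youden(y, s)
        conc = ties = 0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                conc += s[i] > s[j]
                ties += s[i] == s[j]
        oracle = (conc + 0.5 * ties) / (y.sum() * (1 - y).sum())
        assert auc == pytest.approx(oracle, abs=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            auc_and_youden(np.ones(5), np.arange(5.0))


class TestBootstrap:
    def test_constant_metric_zero_width(self):
        mean, (lo, hi), nf = bootstrap_metric(
            np.arange(50.0), lambda x: 1.23, n_boot=50, seed=0
        )
        assert (mean, lo, hi, nf) == (1.23, 1.23, 1.23, 0)

    def test_seed_reproducible(self):
        data = np.random.default_rng(9).standard_normal(100)
        a = bootstrap_metric(data, np.mean, n_boot=200, seed=7)
        b = bootstrap_metric(data, np.mean, n_boot=200, seed=7)
        assert a == b

    def test_mean_ci_matches_analytic(self):
        """Bootstrap CI of a sample mean agrees with the normal-theory
        interval on a Gaussian fixture within 0.01."""
        rng = np.random.default_rng(10)
        data = rng.standard_normal(500) * 0.5
        mean, (lo, hi), _ = bootstrap_metric(data, np.mean, n_boot=2000, seed=1)
        se = data.std(ddof=1) / math.sqrt(500)
        assert lo == pytest.approx(data.mean() - 1.96 * se, abs=0.01)
        assert hi == pytest.approx(data.mean() + 1.96 * se, abs=0.01)

    def test_failed_replicates_reported(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return float(np.mean(x))

        with pytest.warns(UserWarning, match="failed"):
            _, _, nf = bootstrap_metric(
                np.arange(20.0), flaky, n_boot=30, seed=2
            )
        assert nf > 0


class TestRepeatedCv:
    def test_seed_reproducible(self):
        pheno, liab = _factor_phenotypes(n=400, seed=11)
        fs = FactorSet(pheno, prs=liab)
        a = repeated_cv(fs, "prs", n_reps=20, seed=3)
        b = repeated_cv(fs, "prs", n_reps=20, seed=3)
        assert a["mean"] == b["mean"]
        np.testing.assert_array_equal(a["values"], b["values"])

    def test_null_phenotype_no_optimism(self):
        """With factors unrelated to the outcome, test-fold R^2 stays
        near zero (no train-to-test leakage)."""
        rng = np.random.default_rng(12)
        n = 2000
        df = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)],
                           "subtype": rng.binomial(1, 0.5, n)})
        for k in range(10):
            df[f"pc{k + 1}"] = rng.standard_normal(n)
        for name in ("ASCA-IgA", "ANCA"):
            df[name] = rng.standard_normal(n)
        fs = FactorSet(PhenotypeTable(df), prs=rng.standard_normal(n))
        out = repeated_cv(fs, ["prs", "biomarkers"], n_reps=30, seed=4)
        assert out["mean"] < 0.02

    def test_fold_too_small_errors(self):
        pheno, liab = _factor_phenotypes(n=24, seed=13)
        fs = FactorSet(pheno, prs=liab)
        with pytest.raises(ValueError, match="fold"):
            repeated_cv(fs, "prs", n_reps=2, folds=2, seed=0)


class TestFlipLabels:
    def test_zero_fraction_identity(self):
        labels = np.array([1, 0, 1, 1, 0])
        noisy, log = flip_labels(labels, NoisePlan(0.0, 1.0, seed=0))
        np.testing.assert_array_equal(noisy, labels)
        assert len(log) == 0

    def test_clinical_ratio_arithmetic(self):
        """fraction 0.2, ratio 9, n=1,000 (560 CD / 440 UC) yields 180
        CD->UC flips and 20 UC->CD flips."""
        labels = np.array([1] * 560 + [0] * 440)
        noisy, log = flip_labels(labels, NoisePlan(0.2, 9.0, seed=1))
        assert (log["direction"] == "CD->UC").sum() == 180
        assert (log["direction"] == "UC->CD").sum() == 20
        assert noisy.sum() == 560 - 180 + 20

    def test_full_symmetric_flip_complements(self):
        labels = np.array([1] * 50 + [0] * 50)
        noisy, _ = flip_labels(labels, NoisePlan(1.0, 1.0, seed=2))
        np.testing.assert_array_equal(noisy, 1 - labels)

    def test_infeasible_request_errors(self):
        labels = np.array([1] * 10 + [0] * 90)
        with pytest.raises(ValueError, match="flips"):
            flip_labels(labels, NoisePlan(0.5, 9.0, seed=3))


class TestNoiseExperiment:
    def test_zero_fraction_retains_everything(self):
        from ibdprofiler.model_eval import PrsPipeline, noise_experiment
        from conftest import build_study

        train, test = build_study(n_train=800, n_test=600, n_variants=150,
                                  seed=5)
        curve = noise_experiment(
            (train[0], train[1]), (test[0], test[1]), PrsPipeline(),
            fractions=[0.0, 0.4], ratio=1.0, seed=0,
        )
        assert curve["retained"].iloc[0] == pytest.approx(1.0)
        assert list(curve["flip_fraction"]) == [0.0, 0.4]
        assert (curve["r2"] >= 0).all()


class TestContingency:
    def test_balanced_2x2_null(self):
        smoking = np.array(["Never"] * 20 + ["Current"] * 20)
        loc = np.array((["colonic"] * 10 + ["small_bowel"] * 10) * 2)
        chi2, dof, p, props = contingency_chi2(smoking, loc)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert dof == 1

    def test_matches_hand_formula(self):
        """3x2 table agrees with the textbook sum of (O-E)^2/E."""
        smoking = np.repeat(["Never", "Quit", "Current"], [100, 60, 40])
        loc = np.concatenate([
            np.repeat(["colonic", "small_bowel"], [25, 75]),
            np.repeat(["colonic", "small_bowel"], [20, 40]),
            np.repeat(["colonic", "small_bowel"], [7, 33]),
        ])
        chi2, dof, p, props = contingency_chi2(smoking, loc)
        obs = np.array([[25, 75], [20, 40], [7, 33]], dtype=float)
        row, col = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)
        assert dof == 2
        assert props.loc["Never", "colonic"] == pytest.approx(0.25)

    def test_empty_category_errors(self):
        with pytest.raises(ValueError, match="empty"):
            contingency_chi2(np.array([]), np.array([]))
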