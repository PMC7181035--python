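import numpy as np
import pandas as pd
import pytest

from urbanhealth.stats import (
    backward_stepwise_aic,
    contingency_chi2,
    discretize_tertiles,
    fit_multinomial,
    tertile_dummies,
)

from conftest import multinomial_sample


class TestDiscretizeTertiles:
    def test_equal_thirds(self):
        scheme, cats = discretize_tertiles(np.arange(1, 10, dtype=float))
        assert scheme.counts == (3, 3, 3)
        assert list(cats) == [1, 1, 1, 2, 2, 2, 3, 3, 3]

    def test_counts_differ_by_at_most_one(self):
        _, cats = discretize_tertiles(np.random.default_rng(0).random(10))
        counts = [int((cats == c).sum()) for c in (1, 2, 3)]
        assert max(counts) - min(counts) <= 1

    def test_ties_split_by_stable_rank(self):
        scheme, cats = discretize_tertiles(np.array([1.0, 1, 1, 1, 1, 2]))
        assert scheme.counts == (2, 2, 2)

    def test_missing_stays_missing(self):
        _, cats = discretize_tertiles(np.array([1.0, np.nan, 2, 3, 4]))
        assert np.isnan(cats[1])
        assert not np.isnan(np.delete(cats, 1)).any()

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            discretize_tertiles(np.full(9, 3.0))


class TestContingencyChi2:
    def test_perfect_independence(self):
        labels = np.repeat([1, 2, 3, 4], 30)
        cats = np.tile(np.repeat([1, 2, 3], 10), 4)
        ct = contingency_chi2(labels, cats)
        assert ct.chi2_statistic == pytest.approx(0.0)
        assert ct.p_value == pytest.approx(1.0)
        assert ct.dof == 6

    def test_matches_hand_summed_statistic(self):
        counts = np.array([[30, 10, 10], [10, 30, 10], [10, 10, 30], [20, 10, 20]])
        labels = np.repeat(np.arange(1, 5), counts.sum(axis=1))
        cats = np.concatenate(
            [np.repeat([1, 2, 3], row) for row in counts]
        )
        ct = contingency_chi2(labels, cats)
        # independent oracle: expected counts from margins, summed by hand
        n = counts.sum()
        expected = np.outer(counts.sum(1), counts.sum(0)) / n
        stat = ((counts - expected) ** 2 / expected).sum()
        assert ct.chi2_statistic == pytest.approx(stat, rel=1e-12)
        assert np.array_equal(ct.counts.to_numpy(), counts)

    def test_missing_categories_dropped(self):
        labels = np.repeat([1, 2, 3, 4], 30)
        cats = np.tile(np.repeat([1.0, 2, 3], 10), 4)
        cats[::7] = np.nan
        ct = contingency_chi2(labels, cats)
        assert ct.counts.to_numpy().sum() == (~np.isnan(cats)).sum()

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            contingency_chi2(np.array([1, 1, 2, 2]), np.array([1, 1, 1, 1]))

    def test_type_one_error_calibrated(self):
        # under independence the 5%-level test should reject ~5% of the time
        rng = np.random.default_rng(2024)
        n, reps, rejections = 200, 1000, 0
        for _ in range(reps):
            labels = rng.integers(1, 5, n)
            _, cats = discretize_tertiles(rng.random(n))
            if contingency_chi2(labels, cats).p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / reps <= 0.07


class TestFitMultinomial:
    def test_no_association_gives_unit_ors(self):
        # identical predictor distribution in every cluster
        labels = np.repeat([1, 2, 3, 4], 40)
        x = pd.DataFrame({"z": np.tile(np.repeat([0.0, 1.0], 20), 4)})
        fit = fit_multinomial(x, labels, baseline=1)
        betas = fit.table.loc[fit.table["term"] == "z", "beta"]
        assert np.allclose(betas, 0.0, atol=1e-6)
        assert fit.converged

    def test_or_matches_cross_product_ratio(self):
        # saturated single-binary-predictor model: the contrast OR is the
        # cross-product ratio of the 2x2 sub-table vs the baseline cluster
        rng = np.random.default_rng(5)
        labels = rng.integers(1, 5, 600)
        x = (rng.random(600) < 0.3 + 0.1 * labels).astype(float)
        fit = fit_multinomial(pd.DataFrame({"z": x}), labels, baseline=1)
        for c in (2, 3, 4):
            n11 = ((labels == c) & (x == 1)).sum()
            n10 = ((labels == c) & (x == 0)).sum()
            n01 = ((labels == 1) & (x == 1)).sum()
            n00 = ((labels == 1) & (x == 0)).sum()
            oracle = (n11 * n00) / (n10 * n01)
            got = fit.table.query("contrast == @c and term == 'z'")["OR"].item()
            assert got == pytest.approx(oracle, abs=1e-6, rel=1e-6)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        n = 5000
        x = rng.normal(0, 1, (n, 2))
        betas = np.array(
            [[0.3, 0.8, -0.5], [-0.2, -0.6, 0.9], [0.1, 0.4, 0.7]]
        )  # contrasts 2..4: intercept, slope1, slope2
        labels = multinomial_sample(x, betas, rng)
        fit = fit_multinomial(pd.DataFrame(x, columns=["a", "b"]), labels, baseline=1)
        est = (
            fit.table.pivot(index="contrast", columns="term", values="beta")
            [["const", "a", "b"]]
            .to_numpy()
        )
        assert np.max(np.abs(est - betas)) < 0.15

    def test_saturated_model_reproduces_empirical_proportions(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 5, 900)
        _, cats = discretize_tertiles(rng.random(900) + 0.3 * labels)
        x = tertile_dummies(cats, "v")
        fit = fit_multinomial(x, labels, baseline=1)
        probs = np.asarray(fit._result.predict(fit._result.model.exog))
        order = fit.contrasts  # columns 1.. map to these cluster ids
        for t in (1, 2, 3):
            sel = cats == t
            emp = [(labels[sel] == c).mean() for c in [1] + order]
            got = probs[sel].mean(axis=0)
            assert np.allclose(got, emp, atol=1e-6)

    def test_aic_matches_independent_loglik(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(1, 5, 400)
        x = pd.DataFrame({"z": rng.normal(size=400)})
        fit = fit_multinomial(x, labels, baseline=1)
        # independent log-likelihood at the fitted parameters
        design = np.hstack([np.ones((400, 1)), x.to_numpy()])
        b = (
            fit.table.pivot(index="contrast", columns="term", values="beta")
            [["const", "z"]]
            .to_numpy()
        )
        eta = np.hstack([np.zeros((400, 1)), design @ b.T])
        logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
        code = np.array([([1] + fit.contrasts).index(l) for l in labels])
        ll = logp[np.arange(400), code].sum()
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * ll, rel=1e-8)


class TestBackwardStepwiseAic:
    def _simulate(self, seed, n=2000, informative=3, noise=3):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, (n, informative + noise))
        # only the first `informative` columns affect cluster membership
        b = np.zeros((3, informative + 1))
        b[:, 1:] = np.array([[1.0, -0.8, 0.6], [0.7, 0.9, -0.5], [-0.6, 0.5, 0.8]])
        labels = multinomial_sample(x[:, :informative], b, rng)
        cols = [f"s{i}" for i in range(informative)] + [f"n{i}" for i in range(noise)]
        return pd.DataFrame(x, columns=cols), labels

    def test_keeps_signal_removes_noise(self):
        signal_runs = 0
        noise_removed = noise_total = 0
        runs = 20
        for seed in range(runs):
            x, labels = self._simulate(seed)
            groups = {c: [c] for c in x.columns}
            selected, _, log = backward_stepwise_aic(groups, x, labels, baseline=1)
            signal_runs += all(f"s{i}" in selected for i in range(3))
            noise_removed += sum(f"n{i}" not in selected for i in range(3))
            noise_total += 3
            assert (np.diff(log["aic"].to_numpy()) < 0).all()
        # planted predictors survive selection in at least 90% of runs and
        # at least 80% of pure-noise terms are eliminated overall
        assert signal_runs >= 0.9 * runs
        assert noise_removed >= 0.8 * noise_total

    def test_no_removal_when_all_informative(self):
        x, labels = self._simulate(99, n=3000, informative=3, noise=0)
        groups = {c: [c] for c in x.columns}
        selected, fit, log = backward_stepwise_aic(groups, x, labels, baseline=1)
        assert set(selected) == set(x.columns)
        assert len(log) == 1
        assert fit.converged
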