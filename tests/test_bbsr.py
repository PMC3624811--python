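import itertools
import math

import numpy as np
import pytest
from scipy import stats

from grnprior import (
    GPriorSpec,
    PriorMatrix,
    bbsr_fit,
    best_subset,
    bic_score,
    bootstrap_ensemble,
    expected_sigma2,
    initial_filtration,
    posterior,
    rank_combine,
    aupr,
    standard_dataset,
)
from grnprior.design import DesignResponse


def _dr(X, y, gene="y"):
    p = X.shape[1]
    return DesignResponse(gene_id=gene, response=y, design=X,
                         predictor_ids=[f"T{j}" for j in range(p)],
                         alpha=0.1, raw_response=y,
                         condition_index=[f"c{i}" for i in range(len(y))])


def brute_force_best_subset(X, y, g):
    """Independent oracle: score every subset with plain-Python formulas."""
    n, p = X.shape
    best = None
    for k in range(p + 1):
        if k > 0 and n <= k + 1:
            break
        for subset in itertools.combinations(range(p), k):
            idx = list(subset)
            Xs = X[:, idx]
            if k == 0:
                ssr = float(y @ y)
                pen = 0.0
            else:
                gram = Xs.T @ Xs
                if np.linalg.matrix_rank(gram) < k:
                    continue
                bh = np.linalg.inv(gram) @ Xs.T @ y
                r = y - Xs @ bh
                ssr = float(r @ r)
                w = np.array([bh[m] / math.sqrt(g[j] + 1.0)
                              for m, j in enumerate(idx)])
                pen = float(w @ gram @ w)
            scale = 0.5 * (ssr + pen)
            if scale <= 1e-9 * float(y @ y):
                bic = float("-inf")
            else:
                sigma2 = scale / (n / 2.0 - 1.0)
                bic = n * math.log(sigma2) + k * math.log(n)
            key = (bic, k, subset)
            if best is None or key < best:
                best = key
    return best


class TestPosterior:
    def test_scalar_halving_at_unit_g(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 1))
        y = 2 * X[:, 0] + rng.normal(size=20)
        bh = float(np.linalg.lstsq(X, y, rcond=None)[0][0])
        m = posterior(X, y, np.array([1.0]))
        assert m.beta_tilde[0] == pytest.approx(bh / 2)

    def test_large_g_centres_on_ols(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        bh = np.linalg.lstsq(X, y, rcond=None)[0]
        m = posterior(X, y, np.full(3, 1e12))
        np.testing.assert_allclose(m.beta_tilde, bh, atol=1e-8)
        r = y - X @ bh
        assert m.scale == pytest.approx(float(r @ r) / 2, rel=1e-8)

    def test_small_g_centres_on_prior_mean(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25)
        m = posterior(X, y, np.full(3, 1e-12))
        np.testing.assert_allclose(m.beta_tilde, 0.0, atol=1e-8)
        # all variance charged: scale -> y'y / 2 by the Pythagorean identity
        assert m.scale == pytest.approx(float(y @ y) / 2, rel=1e-6)

    def test_infinite_g_mode_is_exact_ols(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        m = posterior(X, y, np.full(2, np.inf))
        bh = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(m.beta_tilde, bh, atol=1e-12)

    def test_insufficient_observations_rejected(self):
        X = np.eye(3)
        with pytest.raises(ValueError):
            posterior(X, np.ones(3), np.ones(3))


class TestSigmaAndBic:
    def test_inverse_gamma_mean(self):
        assert expected_sigma2(3.0, 4.0) == 2.0
        assert expected_sigma2(2.0, 0.0) == 0.0

    def test_inverse_gamma_mean_matches_sampling(self):
        rng = np.random.default_rng(0)
        shape, scale = 4.0, 2.5
        draws = stats.invgamma.rvs(shape, scale=scale, size=10**6,
                                   random_state=rng)
        assert expected_sigma2(shape, scale) == pytest.approx(draws.mean(),
                                                              rel=0.01)

    def test_degenerate_shape_falls_back_to_mode(self):
        assert expected_sigma2(0.5, 3.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("n, k, sigma2, expected", [
        (10, 0, 1.0, 0.0),
        (20, 2, 0.5, 20 * math.log(0.5) + 2 * math.log(20)),
    ])
    def test_bic_values(self, n, k, sigma2, expected):
        assert bic_score(sigma2, n, k) == pytest.approx(expected)

    def test_useless_predictor_costs_log_n(self):
        n = 37
        assert bic_score(1.3, n, 3) - bic_score(1.3, n, 2) == pytest.approx(math.log(n))

    def test_perfect_fit_sentinel(self):
        assert bic_score(0.0, 10, 1) == float("-inf")


class TestBestSubset:
    def test_exact_single_predictor_selected(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        y = 2.0 * X[:, 0]
        res = best_subset(_dr(X, y), np.ones(2))
        assert res.selected == ["T0"]

    def test_pure_noise_selects_empty_model(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(50, 4))
            y = rng.normal(size=50)
            res = best_subset(_dr(X, y), np.ones(4))
            hits += not res.selected
        assert hits >= 90

    def test_matches_brute_force_oracle(self):
        """Vectorised subset scoring equals an independent plain-Python oracle."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(15, 40))
            p = int(rng.integers(1, 7))
            X = rng.normal(size=(n, p))
            k_true = int(rng.integers(0, p + 1))
            beta = np.zeros(p)
            beta[:k_true] = rng.normal(size=k_true)
            y = X @ beta + 0.5 * rng.normal(size=n)
            g = rng.choice([0.5, 1.0, 4.0, 100.0], size=p)
            res = best_subset(_dr(X, y), g)
            oracle_bic, _, oracle_subset = brute_force_best_subset(X, y, g)
            assert tuple(int(t[1:]) for t in res.selected) == oracle_subset
            if math.isfinite(oracle_bic):
                assert res.model_score == pytest.approx(oracle_bic, rel=1e-9)

    def test_no_priors_mode_invariant_to_prior_content(self):
        """With a flat g vector, the prior matrix cannot change the result."""
        ds, gold, _ = standard_dataset(seed=1)
        prior = PriorMatrix(entries=gold.entries.copy(),
                            tf_ids=list(gold.tf_ids),
                            gene_ids=list(gold.gene_ids))
        flat = GPriorSpec(g_prior=1.0, g_no_prior=1.0)
        a = bootstrap_ensemble(ds, prior, "bbsr", gprior=flat, n_boot=3, seed=0)
        b = bootstrap_ensemble(ds, None, "bbsr", gprior=flat, n_boot=3, seed=0)
        for ma, mb in zip(a, b):
            np.testing.assert_array_equal(ma.scores, mb.scores)


class TestInitialFiltration:
    def _dr15(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 15))
        y = X[:, 3] + 0.5 * X[:, 7] + 0.1 * rng.normal(size=40)
        return _dr(X, y)

    def test_priors_always_kept(self):
        dr = self._dr15()
        keep = initial_filtration(dr, {"T13", "T14"}, np.ones(15), limit=10)
        assert len(keep) == 10
        assert {"T13", "T14"} <= set(keep)
        assert {"T3", "T7"} <= set(keep)  # strong marginal fits survive

    def test_within_limit_unchanged(self):
        rng = np.random.default_rng(1)
        dr = _dr(rng.normal(size=(30, 10)), rng.normal(size=30))
        assert initial_filtration(dr, set(), np.ones(10)) == dr.predictor_ids

    def test_excess_priors_capped_by_marginal_fit(self):
        dr = self._dr15()
        priors = {f"T{j}" for j in range(12)}
        keep = initial_filtration(dr, priors, np.ones(15), limit=10)
        assert len(keep) == 10
        assert set(keep) <= priors
        assert "T3" in keep

    def test_fit_applies_filtration_above_limit(self):
        dr = self._dr15()
        res = bbsr_fit(dr, set(), GPriorSpec())
        assert set(res.selected) <= set(dr.predictor_ids)
        assert {"T3", "T7"} <= set(res.selected)


class TestWeightSemantics:
    def test_aupr_nondecreasing_in_g(self):
        """With all true edges as priors, confidence in the gold standard
        grows with the prior weight g (up to Monte-Carlo tolerance)."""
        gs = [1.0, 4.0, 1e3]
        medians = []
        for g in gs:
            vals = []
            for seed in range(3):
                ds, gold, _ = standard_dataset(seed=seed)
                prior = PriorMatrix(entries=gold.entries.copy(),
                                    tf_ids=list(gold.tf_ids),
                                    gene_ids=list(gold.gene_ids))
                mats = bootstrap_ensemble(ds, prior, "bbsr",
                                          gprior=GPriorSpec(g_prior=g),
                                          n_boot=10, seed=seed)
                net = rank_combine(mats)
                vals.append(aupr(net.ranked_pairs(), gold,
                                 scores=net.scores(), seed=seed).aupr)
            medians.append(np.median(vals))
        assert medians[1] >= medians[0] - 0.02
        assert medians[2] >= medians[1] - 0.02
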