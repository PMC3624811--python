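import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnprior import (
    GoldStandard,
    PriorMatrix,
    aupr,
    corrupt_priors,
    evaluation_universe,
    leave_out_eval,
    naive_prior_ranking,
    subsample_priors,
)


def _gold(entries, n_tfs=None, n_genes=None):
    entries = np.asarray(entries, dtype=np.int8)
    n_tfs, n_genes = entries.shape
    return GoldStandard(entries=entries,
                        tf_ids=[f"T{j}" for j in range(n_tfs)],
                        gene_ids=[f"T{j}" for j in range(n_tfs)]
                        + [f"Y{i}" for i in range(n_genes - n_tfs)])


def _random_gold(rng, n_tfs=5, n_genes=12, density=0.25):
    entries = (rng.random((n_tfs, n_genes)) < density).astype(np.int8)
    np.fill_diagonal(entries[:, :n_tfs], 0)
    g = _gold(entries)
    return g


class TestAupr:
    def test_all_gold_first_is_perfect(self):
        rng = np.random.default_rng(0)
        gold = _random_gold(rng)
        uni = sorted(evaluation_universe(gold))
        positives = set(gold.edge_list()) & set(uni)
        ranked = sorted(positives) + [e for e in uni if e not in positives]
        assert aupr(ranked, gold, seed=0).aupr == pytest.approx(1.0)

    def test_two_edge_hand_example(self):
        # universe {e1, e2}, gold {e1}, ranking (e2, e1): the gold hit comes
        # second at precision 1/2, so the step-sum area is 0.5
        gold = _gold([[0, 1]], )
        uni = evaluation_universe(gold)
        assert uni == {("T0", "Y0")}
        # build a 2-pair universe by passing it explicitly
        uni = {("T0", "Y0"), ("T0", "Y1")}
        pr = aupr([("T0", "Y1"), ("T0", "Y0")], gold, seed=0, universe=uni,
                  positives={("T0", "Y0")})
        assert pr.aupr == pytest.approx(0.5)
        assert pr.precision[-1] == pytest.approx(0.5)

    def test_unranked_universe_pairs_are_appended(self):
        rng = np.random.default_rng(1)
        gold = _random_gold(rng)
        pr = aupr([], gold, seed=0)
        assert pr.n_eval == len(evaluation_universe(gold))
        assert pr.recall[-1] == pytest.approx(1.0)

    def test_no_gold_positives_is_an_error(self):
        gold = _gold([[0, 1]])
        empty = GoldStandard(entries=np.zeros((1, 2), dtype=np.int8),
                             tf_ids=gold.tf_ids, gene_ids=gold.gene_ids)
        with pytest.raises(ValueError):
            aupr([], empty, seed=0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10**6))
    def test_aupr_bounded_and_reversal_bracket(self, seed):
        """Any ranking's AUPR lies in [0,1]; a ranking and its reversal
        bracket the prevalence baseline on average."""
        rng = np.random.default_rng(seed)
        gold = _random_gold(rng)
        uni = sorted(evaluation_universe(gold))
        if not set(gold.edge_list()) & set(uni):
            return
        order = rng.permutation(len(uni))
        ranked = [uni[i] for i in order]
        fwd = aupr(ranked, gold, seed=0).aupr
        rev = aupr(ranked[::-1], gold, seed=0).aupr
        assert 0.0 <= fwd <= 1.0 and 0.0 <= rev <= 1.0
        prevalence = len(set(gold.edge_list()) & set(uni)) / len(uni)
        assert min(fwd, rev) <= prevalence * 2.5
        assert max(fwd, rev) >= prevalence * 0.4


class TestLeaveOut:
    def test_empty_pki_equals_plain_aupr(self):
        rng = np.random.default_rng(2)
        gold = _random_gold(rng)
        uni = sorted(evaluation_universe(gold))
        ranked = [uni[i] for i in rng.permutation(len(uni))]
        pki = PriorMatrix(entries=np.zeros_like(gold.entries),
                          tf_ids=gold.tf_ids, gene_ids=gold.gene_ids)
        a = aupr(ranked, gold, seed=3).aupr
        b = leave_out_eval(ranked, gold, pki, seed=3).aupr
        assert a == pytest.approx(b)

    def test_all_gold_as_pki_is_an_error(self):
        rng = np.random.default_rng(3)
        gold = _random_gold(rng)
        pki = PriorMatrix(entries=gold.entries.copy(), tf_ids=gold.tf_ids,
                          gene_ids=gold.gene_ids)
        with pytest.raises(ValueError):
            leave_out_eval([], gold, pki, seed=0)

    def test_universe_and_positives_shrink(self):
        rng = np.random.default_rng(4)
        gold = _random_gold(rng, n_tfs=6, n_genes=14, density=0.3)
        n_gold_in_uni = len(set(gold.edge_list()) & evaluation_universe(gold))
        pki = subsample_priors(gold, 0.4, seed=9)
        pr = leave_out_eval([], gold, pki, seed=0)
        n_pki_in_uni = len(set(pki.edge_list()) & evaluation_universe(gold))
        assert pr.n_gold == n_gold_in_uni - n_pki_in_uni
        assert pr.n_eval == len(evaluation_universe(gold)) - n_pki_in_uni


class TestCorruptPriors:
    def _big_gold(self):
        # sparse enough that 10 false priors per true prior fit in the
        # non-gold pool
        rng = np.random.default_rng(0)
        return _random_gold(rng, n_tfs=10, n_genes=40, density=0.06)

    def test_ratio_zero_gives_tpis_only(self):
        gold = self._big_gold()
        prior, tpis, fpis = corrupt_priors(gold, 0.5, 0, seed=1)
        assert not fpis
        assert set(prior.edge_list()) == tpis
        assert len(tpis) == round(0.5 * gold.n_edges)

    def test_one_to_ten_ratio_fraction(self):
        gold = self._big_gold()
        prior, tpis, fpis = corrupt_priors(gold, 0.5, 10, seed=2)
        assert len(fpis) == 10 * len(tpis)
        frac = len(fpis) / (len(tpis) + len(fpis))
        assert frac == pytest.approx(10 / 11)

    def test_fpis_never_overlap_gold(self):
        gold = self._big_gold()
        for seed in range(5):
            _, tpis, fpis = corrupt_priors(gold, 0.5, 5, seed=seed)
            assert not fpis & set(gold.edge_list())
            assert tpis <= set(gold.edge_list())

    def test_insufficient_non_gold_pairs_rejected(self):
        gold = _gold([[0, 1, 1]])
        with pytest.raises(ValueError):
            corrupt_priors(gold, 1.0, 10, seed=0)


class TestNaiveRanking:
    def test_priors_equal_gold_scores_one(self):
        rng = np.random.default_rng(5)
        gold = _random_gold(rng)
        uni = evaluation_universe(gold)
        prior = PriorMatrix(entries=gold.entries.copy(), tf_ids=gold.tf_ids,
                            gene_ids=gold.gene_ids)
        ranked = naive_prior_ranking(prior, uni, seed=0)
        assert aupr(ranked, gold, seed=0).aupr == pytest.approx(1.0)

    def test_empty_priors_score_near_prevalence(self):
        # a large universe keeps the small-sample upward bias of random-
        # ranking AUPR negligible
        rng = np.random.default_rng(6)
        gold = _random_gold(rng, n_tfs=10, n_genes=50, density=0.15)
        uni = evaluation_universe(gold)
        prior = PriorMatrix(entries=np.zeros_like(gold.entries),
                            tf_ids=gold.tf_ids, gene_ids=gold.gene_ids)
        prevalence = len(set(gold.edge_list()) & uni) / len(uni)
        vals = [aupr(naive_prior_ranking(prior, uni, seed=s), gold, seed=s).aupr
                for s in range(200)]
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - prevalence) < 3 * se + 0.01


class TestSubsamplePriors:
    def test_full_fraction_returns_gold(self):
        rng = np.random.default_rng(7)
        gold = _random_gold(rng)
        pki = subsample_priors(gold, 1.0, seed=0)
        np.testing.assert_array_equal(pki.entries, gold.entries)

    def test_fraction_counts(self):
        rng = np.random.default_rng(8)
        gold = _random_gold(rng, n_tfs=10, n_genes=40, density=0.25)
        pki = subsample_priors(gold, 0.2, seed=0)
        assert pki.n_edges == round(0.2 * gold.n_edges)

    def test_rep_reproducibility_and_independence(self):
        rng = np.random.default_rng(9)
        gold = _random_gold(rng, n_tfs=10, n_genes=40, density=0.25)
        a = subsample_priors(gold, 0.4, rep=1, seed=3)
        b = subsample_priors(gold, 0.4, rep=1, seed=3)
        c = subsample_priors(gold, 0.4, rep=2, seed=3)
        np.testing.assert_array_equal(a.entries, b.entries)
        assert not np.array_equal(a.entries, c.entries)
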