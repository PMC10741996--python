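"""Enrichment score and permutation test, checked against a brute-force
oracle implemented independently of the production code."""

import numpy as np
import pytest

from rfgsea import GeneSet
from rfgsea.gsea import RankedList, enrichment_score, gsea_test


def oracle_es(genes, scores, members, weight_exponent=1.0):
    """Literal O(N) walk down the ranked list (independent oracle)."""
    members = set(members)
    n = len(genes)
    hits = [g in members for g in genes]
    k = sum(hits)
    wts = [abs(s) ** weight_exponent if h else 0.0 for s, h in zip(scores, hits)]
    total = sum(wts)
    running = []
    ph, pm = 0.0, 0
    for i in range(n):
        if hits[i]:
            ph += wts[i]
        else:
            pm += 1
        running.append(ph / total - pm / (n - k))
    mx, mn = max(running), min(running)
    return mx if mx >= -mn else mn


def ranked(n, rng=None, scores=None):
    genes = tuple(f"g{i}" for i in range(n))
    if scores is None:
        scores = rng.normal(size=n)
    return RankedList.from_scores(genes, scores)


class TestEnrichmentScore:
    def test_agrees_with_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(5, 51))
            rl = ranked(n, rng)
            k = int(rng.integers(1, n))
            members = tuple(rng.choice(rl.genes, k, replace=False))
            es, _, _ = enrichment_score(rl, GeneSet("s", members))
            assert es == pytest.approx(
                oracle_es(rl.genes, rl.scores, members), abs=1e-12
            )

    def test_fixed_instance_matches_frozen_oracle_value(self):
        # N=10, scores 10..1, members at ranked positions 1, 4, 10
        rl = RankedList(tuple(f"g{i}" for i in range(10)), np.arange(10, 0, -1.0))
        gs = GeneSet("s", (rl.genes[0], rl.genes[3], rl.genes[9]))
        es, running, hit_idx = enrichment_score(rl, gs)
        assert es == pytest.approx(0.6587301587301587, abs=1e-12)
        assert list(hit_idx) == [0, 3, 9]
        assert len(running) == 10

    def test_top_k_set_reaches_plus_one_exactly(self):
        rl = RankedList(tuple(f"g{i}" for i in range(12)), np.arange(12, 0, -1.0))
        es, _, _ = enrichment_score(rl, GeneSet("s", rl.genes[:4]))
        assert es == 1.0

    def test_bottom_k_set_reaches_minus_one_exactly(self):
        rl = RankedList(tuple(f"g{i}" for i in range(12)), np.arange(12, 0, -1.0))
        es, _, _ = enrichment_score(rl, GeneSet("s", rl.genes[-4:]))
        assert es == -1.0

    def test_es_bounded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(4, 40))
            rl = ranked(n, rng)
            k = int(rng.integers(1, n))
            members = tuple(rng.choice(rl.genes, k, replace=False))
            es, _, _ = enrichment_score(rl, GeneSet("s", members))
            assert -1.0 <= es <= 1.0

    def test_scale_invariance_of_scores(self):
        rng = np.random.default_rng(9)
        rl = ranked(30, rng)
        members = tuple(rng.choice(rl.genes, 8, replace=False))
        es1, _, _ = enrichment_score(rl, GeneSet("s", members))
        scaled = RankedList(rl.genes, rl.scores * 37.5)
        es2, _, _ = enrichment_score(scaled, GeneSet("s", members))
        assert es2 == pytest.approx(es1, abs=1e-12)

    def test_empty_or_full_overlap_rejected(self):
        rl = RankedList(("a", "b", "c"), np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="no member"):
            enrichment_score(rl, GeneSet("s", ("zz",)))
        with pytest.raises(ValueError, match="whole ranked list"):
            enrichment_score(rl, GeneSet("s", ("a", "b", "c")))


class TestGseaTest:
    def test_top_k_set_is_significant(self):
        rl = RankedList(tuple(f"g{i}" for i in range(50)), np.arange(50, 0, -1.0))
        res = gsea_test(rl, GeneSet("s", rl.genes[:6]), n_perm=1000, seed=11)
        assert res.es == 1.0
        assert res.direction == "positive"
        assert res.p_value < 0.05

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        rl = ranked(40, rng)
        gs = GeneSet("s", tuple(rng.choice(rl.genes, 10, replace=False)))
        a = gsea_test(rl, gs, n_perm=200, seed=99)
        b = gsea_test(rl, gs, n_perm=200, seed=99)
        assert a.es == b.es and a.p_value == b.p_value and a.nes == b.nes

    def test_p_value_never_zero_and_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for seed in range(20):
            rl = ranked(25, rng)
            gs = GeneSet("s", tuple(rng.choice(rl.genes, 5, replace=False)))
            res = gsea_test(rl, gs, n_perm=100, seed=seed)
            assert 0.0 < res.p_value <= 1.0
            assert res.direction == (
                "positive" if res.es > 0 else "negative" if res.es < 0 else "zero"
            )

    def test_too_few_permutations_rejected(self):
        rl = RankedList(("a", "b", "c"), np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError, match="minimum"):
            gsea_test(rl, GeneSet("s", ("a",)), n_perm=50, seed=0)

    def test_null_p_values_super_uniform(self):
        """Under random scores and random sets, p-values should track
        U(0,1) (two-sided KS below the 1% critical value at 500 reps)."""
        from scipy import stats

        rng = np.random.default_rng(7)
        ps = []
        for _ in range(500):
            rl = ranked(100, scores=rng.uniform(-1, 1, 100))
            members = tuple(rng.choice(rl.genes, 15, replace=False))
            ps.append(
                gsea_test(
                    rl, GeneSet("s", members), n_perm=1000,
                    seed=int(rng.integers(2**31)),
                ).p_value
            )
        d, _ = stats.kstest(ps, "uniform")
        crit = stats.kstwo.ppf(0.99, 500)
        assert d < crit
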