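import itertools

import numpy as np
import pytest
from scipy import stats

from sigprog.engine import (
    ConnectionResult,
    ScoringConfig,
    connection_score,
    max_raw_score,
    null_scores,
    permutation_p,
    perturbation_stability,
    query_database,
    random_signature,
    set_score,
)
from sigprog.io import ConfigError, ReferenceDatabase, ReferenceSet, SigprogError
from sigprog.signature import QuerySignature

from conftest import make_profile, random_profile, random_set


def exact_null(rs, m, mode):
    """Exhaustive null: every ordered m-tuple of distinct probes x signs."""
    n = len(rs.universe)
    scores = []
    for combo in itertools.permutations(range(n), m):
        for signs in itertools.product((-1, 1), repeat=m):
            sig = QuerySignature.from_lists([rs.universe[i] for i in combo], list(signs))
            scores.append(set_score(sig, rs, mode))
    return np.array(scores)


class TestConnectionScore:
    def test_hand_enumeration_example(self):
        prof = make_profile("x", {"A": 5, "B": 4, "C": -3, "D": 2, "E": -1},
                            universe=("A", "B", "C", "D", "E"))
        sig = QuerySignature.from_lists(["A", "B"], [1, -1])
        # raw = (+2)(+5) + (-1)(+4) = 6; c_max = 2*5 + 1*4 = 14
        assert connection_score(sig, prof, "ordered") == pytest.approx(6 / 14)

    def test_maximal_agreement_single_gene(self):
        prof = make_profile("x", {"A": 3, "B": -2, "C": 1}, universe=("A", "B", "C"))
        up = QuerySignature.from_lists(["A"], [1])
        assert connection_score(up, prof) == pytest.approx(1.0)
        assert connection_score(up.negated(), prof) == pytest.approx(-1.0)

    def test_best_matching_signature_attains_one(self):
        # exhaustive: for every m, the signature listing the profile's top
        # probes (by |rank|) with concordant signs scores exactly +1 and no
        # other configuration exceeds it
        prof = make_profile("x", {"A": -4, "B": 3, "C": -2, "D": 1},
                            universe=("A", "B", "C", "D"))
        rs = ReferenceSet("x", [prof])
        for m in (1, 2):
            best = QuerySignature.from_lists(
                ["A", "B"][:m], [-1, 1][:m]
            )
            assert set_score(best, rs) == pytest.approx(1.0)
            null = exact_null(rs, m, "ordered")
            assert null.max() == pytest.approx(1.0)
            assert np.all(null <= 1.0 + 1e-12) and np.all(null >= -1.0 - 1e-12)

    def test_antisymmetry(self, rng):
        prof = random_profile("p", 20, rng)
        sig = random_signature(6, list(prof.universe), rng)
        s = connection_score(sig, prof)
        assert connection_score(sig.negated(), prof) == pytest.approx(-s)
        assert abs(s) <= 1.0

    def test_unordered_mode(self):
        prof = make_profile("x", {"A": 5, "B": 4, "C": -3, "D": 2, "E": -1},
                            universe=("A", "B", "C", "D", "E"))
        sig = QuerySignature.from_lists(["A", "B"], [1, -1])
        # raw = 5 - 4 = 1; c_max = 5 + 4 = 9
        assert connection_score(sig, prof, "unordered") == pytest.approx(1 / 9)

    def test_missing_probe_instructs_restriction(self):
        prof = make_profile("x", {"A": 1, "B": -2})
        sig = QuerySignature.from_lists(["Z"], [1])
        with pytest.raises(SigprogError, match="restrict"):
            connection_score(sig, prof)


class TestSetScore:
    def test_single_replicate_equals_profile_score(self, rng):
        prof = random_profile("p", 12, rng)
        rs = ReferenceSet("c", [prof])
        sig = random_signature(4, list(prof.universe), rng)
        assert set_score(sig, rs) == pytest.approx(connection_score(sig, prof))

    def test_mean_over_replicates(self, rng):
        rs = random_set("c", 15, 3, rng)
        sig = random_signature(5, list(rs.universe), rng)
        manual = np.mean([connection_score(sig, p) for p in rs.profiles])
        assert set_score(sig, rs) == pytest.approx(manual)

    def test_opposite_replicates_cancel(self):
        p1 = make_profile("a", {"A": 3, "B": -2, "C": 1}, universe=("A", "B", "C"))
        p2 = make_profile("b", {"A": -3, "B": 2, "C": -1}, universe=("A", "B", "C"))
        sig = QuerySignature.from_lists(["A", "B"], [1, -1])
        assert set_score(sig, ReferenceSet("c", [p1, p2])) == pytest.approx(0.0)


class TestRandomSignature:
    def test_pair_frequencies_match_combinatorics(self):
        rng = np.random.default_rng(99)
        universe = ["A", "B", "C", "D"]
        counts = {}
        n_draw = 10_000
        for _ in range(n_draw):
            sig = random_signature(2, universe, rng)
            key = (frozenset(sig.probe_ids),
                   tuple(sorted(zip(sig.probe_ids, (int(g.sign) for g in sig.genes)))))
            counts[key] = counts.get(key, 0) + 1
        # 6 unordered pairs x 4 sign patterns, each with probability 1/24
        assert len(counts) == 24
        observed = np.array(list(counts.values()))
        chi2 = ((observed - n_draw / 24) ** 2 / (n_draw / 24)).sum()
        assert stats.chi2.sf(chi2, 23) > 1e-3

    def test_full_universe_permutation(self, rng):
        sig = random_signature(5, ["A", "B", "C", "D", "E"], rng)
        assert sorted(sig.probe_ids) == ["A", "B", "C", "D", "E"]

    def test_determinism(self):
        u = [f"G{i}" for i in range(10)]
        a = [random_signature(3, u, np.random.default_rng(5)).probe_ids for _ in range(1)]
        b = [random_signature(3, u, np.random.default_rng(5)).probe_ids for _ in range(1)]
        assert a == b

    def test_oversized_m_rejected(self, rng):
        with pytest.raises(ConfigError):
            random_signature(3, ["A", "B"], rng)


class TestPermutationP:
    def test_exact_enumeration_agreement(self, rng):
        rs = random_set("c", 4, 1, rng)
        cfg = ScoringConfig(n_perm=20_000, rng_seed=7)
        sig = QuerySignature.from_lists([rs.universe[0]], [1])
        exact = exact_null(rs, 1, "ordered")  # 8 equally likely outcomes
        assert exact.size == 8
        obs = set_score(sig, rs)
        p_exact = np.mean(exact < obs)
        res = permutation_p(sig, rs, cfg)
        se = np.sqrt(max(p_exact * (1 - p_exact), 1 / cfg.n_perm) / cfg.n_perm)
        assert abs(res.p_value - p_exact) <= 3 * se + 0.5 / cfg.n_perm

    def test_median_observed_p_half(self, rng):
        rs = random_set("c", 30, 2, rng)
        cfg = ScoringConfig(n_perm=4000, rng_seed=3)
        null = null_scores(3, rs, cfg)
        # craft a signature whose score sits at the null median
        best_sig, best_gap = None, np.inf
        med = np.median(null)
        for _ in range(200):
            sig = random_signature(3, list(rs.universe), rng)
            gap = abs(set_score(sig, rs) - med)
            if gap < best_gap:
                best_sig, best_gap = sig, gap
        res = permutation_p(best_sig, rs, ScoringConfig(n_perm=4000, rng_seed=3,
                                                        sidedness="left"))
        assert res.p_value == pytest.approx(0.5, abs=0.05)

    def test_cache_changes_nothing(self, rng):
        rs = random_set("c", 25, 2, rng)
        sig = random_signature(4, list(rs.universe), rng)
        cfg = ScoringConfig(n_perm=2000, rng_seed=11)
        cache: dict = {}
        a = permutation_p(sig, rs, cfg, cache)
        b = permutation_p(sig, rs, cfg, cache)  # cache hit
        c = permutation_p(sig, rs, cfg, None)   # cache-free
        assert a == b == c

    def test_two_sided_cap(self, rng):
        rs = random_set("c", 10, 1, rng)
        sig = random_signature(2, list(rs.universe), rng)
        res = permutation_p(sig, rs, ScoringConfig(n_perm=1000, rng_seed=0, sidedness="two"))
        assert 0 < res.p_value <= 1

    def test_null_p_values_uniform(self, rng):
        # random query signatures against a fixed set: left-sided p uniform
        rs = random_set("c", 40, 2, rng)
        cfg = ScoringConfig(n_perm=2000, rng_seed=21, sidedness="left")
        cache: dict = {}
        ps = []
        for _ in range(300):
            sig = random_signature(5, list(rs.universe), rng)
            ps.append(permutation_p(sig, rs, cfg, cache).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestQueryDatabase:
    def _db(self, rng, n=30, n_sets=5):
        sets = [random_set(f"c{i}", n, 1, rng) for i in range(n_sets)]
        universe = sets[0].universe
        sets = [ReferenceSet(s.compound, [p.reindexed(universe) for p in s.profiles])
                for s in sets]
        return ReferenceDatabase(sets, universe)

    def test_planted_anti_compound_most_negative(self, rng):
        db = self._db(rng)
        target = db.sets[2]
        ranks = target.profiles[0].rank_of()
        top = sorted(db.probe_universe, key=lambda p: -abs(ranks[p]))[:5]
        sig = QuerySignature.from_lists(top, [-int(np.sign(ranks[p])) for p in top])
        cfg = ScoringConfig(n_perm=2000, rng_seed=4, sidedness="left")
        results = query_database(sig, db, cfg)
        assert results[0].compound == "c2"
        assert results[0].cscore == pytest.approx(-1.0)
        zs = [r.z_score for r in results]
        assert zs == sorted(zs)  # left-sided: most negative first

    def test_sm_threshold(self, rng):
        db = self._db(rng, n_sets=4)
        sig = random_signature(3, list(db.probe_universe), rng)
        cfg = ScoringConfig(n_perm=1000, rng_seed=9, threshold_n_fp=1.0)
        for r in query_database(sig, db, cfg):
            assert r.sm == int(r.p_value < 1.0 / db.n_sets)

    def test_empty_signature_rejected(self, rng):
        db = self._db(rng)
        with pytest.raises(SigprogError):
            query_database(QuerySignature([]), db, ScoringConfig(n_perm=1000))


class TestPerturbationStability:
    def test_single_gene_undefined(self, rng):
        rs = random_set("c", 10, 1, rng)
        sig = random_signature(1, list(rs.universe), rng)
        assert perturbation_stability(sig, rs, 10, ScoringConfig(n_perm=1000)) is None

    def test_fully_stable_and_fully_unstable(self, rng):
        n = 40
        rs = random_set("c", n, 1, rng)
        ranks = rs.profiles[0].rank_of()
        top = sorted(rs.universe, key=lambda p: -abs(ranks[p]))[:8]
        concordant = QuerySignature.from_lists(top, [int(np.sign(ranks[p])) for p in top])
        cfg = ScoringConfig(n_perm=2000, rng_seed=2, sidedness="right")
        # strongly matched signature: every leave-one-out remains extreme
        # (threshold 1/1000 is still above the permutation floor 2.5e-4)
        ps = perturbation_stability(concordant, rs, 1000, cfg)
        assert ps == pytest.approx(1.0)
        # a random signature is never significant, before or after LOO
        rand = random_signature(8, list(rs.universe), np.random.default_rng(77))
        ps0 = perturbation_stability(rand, rs, 1000, ScoringConfig(n_perm=2000, rng_seed=2))
        assert ps0 == pytest.approx(0.0)

    def test_matches_brute_force_loop(self, rng):
        rs = random_set("c", 25, 2, rng)
        sig = random_signature(6, list(rs.universe), rng)
        cfg = ScoringConfig(n_perm=1000, rng_seed=13, sidedness="left")
        threshold = 1.0 / 20
        cache: dict = {}
        ps = perturbation_stability(sig, rs, 20, cfg, cache)
        ids, signs = sig.probe_ids, [g.sign for g in sig.genes]
        manual = 0
        for i in range(sig.m):
            loo = QuerySignature.from_lists(ids[:i] + ids[i + 1:], signs[:i] + signs[i + 1:])
            if permutation_p(loo, rs, cfg).p_value < threshold:
                manual += 1
        assert ps == pytest.approx(manual / sig.m)
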