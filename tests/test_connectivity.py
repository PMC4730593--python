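"""Connectivity scores, permutation null, critical p-value, query ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fishcmap as fc
from fishcmap.iodata import ValidationError
from fishcmap.rogl import ROGLSet

from conftest import make_rogl, make_signature, random_rogl


class TestRawAndNormalizedScore:
    def test_hand_computed_scores_on_toy_rogl(self, toy_rogl):
        assert fc.raw_score(make_signature({"P2": -1, "P5": 1}), toy_rogl) == 9
        assert fc.raw_score(make_signature({"P1": 1, "P2": 1}), toy_rogl) == -4

    def test_sign_flip_negates_exactly(self, toy_rogl):
        sig = make_signature({"P1": 1, "P3": -1, "P5": 1})
        flipped = make_signature({"P1": -1, "P3": 1, "P5": -1})
        assert fc.raw_score(sig, toy_rogl) == -fc.raw_score(flipped, toy_rogl)
        assert fc.normalized_score(sig, toy_rogl) == -fc.normalized_score(flipped, toy_rogl)

    def test_perfect_match_scores_one(self, toy_rogl):
        sig = make_signature({"P2": -1, "P5": 1})  # top-2 |ranks| with matching signs
        assert fc.normalized_score(sig, toy_rogl) == 1.0

    def test_normalized_hand_value(self, toy_rogl):
        assert fc.normalized_score(
            make_signature({"P1": 1, "P2": 1}), toy_rogl
        ) == pytest.approx(-4 / 9)

    def test_max_score_values(self):
        assert fc.max_score(2, 5) == 9
        assert fc.max_score(1, 1) == 1
        for n in (1, 4, 17):
            assert fc.max_score(n, n) == n * (n + 1) // 2
        with pytest.raises(ValidationError):
            fc.max_score(6, 5)

    def test_set_of_identical_members_equals_single_score(self, toy_rogl):
        sig = make_signature({"P2": -1, "P4": -1, "P5": 1})
        rset = ROGLSet("s", [toy_rogl, toy_rogl, toy_rogl])
        assert fc.set_score(sig, rset) == pytest.approx(
            fc.normalized_score(sig, toy_rogl)
        )

    def test_missing_probes_dropped_with_warning_and_min_size_guard(self, toy_rogl):
        sig = make_signature({"P2": -1, "P5": 1, "QQ": 1})
        with pytest.warns(UserWarning, match="absent"):
            assert fc.raw_score(sig, toy_rogl) == 9
        with pytest.raises(ValidationError, match="minimum"):
            fc.normalized_score(make_signature({"QQ": 1, "RR": 1}), toy_rogl, min_size=1)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_score_bounds_and_relabel_invariance(self, seed):
        """|normalized| <= 1 and renaming non-signature probes changes nothing."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 25))
        m = int(rng.integers(1, min(n, 6)))
        logfc = {f"P{i:03d}": float(v) for i, v in enumerate(rng.normal(0, 1, n))}
        rogl = make_rogl(logfc)
        probes = list(rng.choice(sorted(logfc), size=m, replace=False))
        sig = make_signature({p: int(s) for p, s in zip(probes, rng.choice((-1, 1), m))})
        score = fc.normalized_score(sig, rogl)
        assert -1.0 <= score <= 1.0
        relabeled = {
            (k if k in probes else f"Z{k}"): v for k, v in logfc.items()
        }
        assert fc.normalized_score(sig, make_rogl(relabeled)) == pytest.approx(score)


class TestEmpiricalPValue:
    def test_toy_exhaustive_p_is_one_in_forty(self, toy_set):
        sig = make_signature({"P2": -1, "P5": 1})
        obs, p, n = fc.empirical_pvalue(sig, toy_set)
        assert obs == 1.0
        assert p == pytest.approx(1 / 40)
        assert n == 40  # C(5,2) * 2^2 enumerated exactly

    def test_worst_score_gives_p_one(self, toy_set):
        sig = make_signature({"P2": 1, "P5": -1})  # perfectly anti-matched
        obs, p, _ = fc.empirical_pvalue(sig, toy_set)
        assert obs == -1.0 and p == 1.0

    def test_monte_carlo_is_deterministic_given_seed(self):
        rng = np.random.default_rng(0)
        rogl = random_rogl(rng, 60)
        rset = ROGLSet("s", [rogl])
        sig = make_signature(
            {p: 1 for p in rogl.probe_ids[:5]}
        )
        r1 = fc.empirical_pvalue(sig, rset, n_sim=2000, seed=7, method="montecarlo")
        r2 = fc.empirical_pvalue(sig, rset, n_sim=2000, seed=7, method="montecarlo")
        assert r1 == r2

    def test_monte_carlo_requires_seed(self, toy_set):
        sig = make_signature({"P2": -1, "P5": 1})
        with pytest.raises(ValidationError, match="seed"):
            fc.empirical_pvalue(sig, toy_set, method="montecarlo")

    def test_monte_carlo_matches_exhaustive_within_binomial_error(self):
        rng = np.random.default_rng(3)
        rogl = random_rogl(rng, 7)
        rset = ROGLSet("s", [rogl])
        sig = make_signature(
            {rogl.probe_ids[0]: 1, rogl.probe_ids[3]: -1, rogl.probe_ids[5]: 1}
        )
        _, p_exact, _ = fc.empirical_pvalue(sig, rset, method="exhaustive")
        n_sim = 10_000
        _, p_mc, _ = fc.empirical_pvalue(
            sig, rset, n_sim=n_sim, seed=11, method="montecarlo"
        )
        tol = 4 * np.sqrt(p_exact * (1 - p_exact) / n_sim)
        assert abs(p_mc - p_exact) <= tol

    def test_smoothing_avoids_zero_p(self, toy_set):
        sig = make_signature({"P2": -1, "P5": 1})
        _, p, n = fc.empirical_pvalue(
            sig, toy_set, n_sim=200, seed=1, method="montecarlo", smoothing=True
        )
        assert p >= 1 / 201

    def test_unsigned_null_compares_magnitudes(self, toy_set):
        # anti-matched signature: worst under the signed null, extreme on |score|
        sig = make_signature({"P2": 1, "P5": -1})
        _, p_signed, _ = fc.empirical_pvalue(sig, toy_set)
        _, p_unsigned, _ = fc.empirical_pvalue(sig, toy_set, signed_null=False)
        assert p_signed == 1.0
        # all-positive null signatures never reach |score| = 1 on this ROGL
        # (the top-2 ranks have opposite signs), so the anti-match is extreme
        assert p_unsigned == 0.0


class TestCriticalPValue:
    def test_printed_cutoffs(self):
        for s, printed in ((45, 0.022), (39, 0.026), (132, 0.0076)):
            assert fc.round_sigfigs(fc.critical_pvalue(s)) == printed

    def test_invalid_s(self):
        with pytest.raises(ValidationError):
            fc.critical_pvalue(0)


class TestQuery:
    def _collection(self, rng, n_sets=5, n=40):
        return [
            ROGLSet(
                f"set{k}",
                [random_rogl(rng, n, chemical=f"C{k}", experiment_id=f"e{k}",
                             sample_id=f"s{k}")],
                key_values={"chemical": f"C{k}"},
            )
            for k in range(n_sets)
        ]

    def test_results_ranked_by_score_descending(self):
        rng = np.random.default_rng(5)
        coll = self._collection(rng)
        sig = make_signature(
            {p: 1 for p in coll[0].members[0].probe_ids[:6]}, experiment_id="eQ"
        )
        results = fc.query(sig, coll, n_sim=500, seed=3)
        scores = [r.score for r in results]
        assert scores == sorted(scores, reverse=True)
        assert [r.rank for r in results] == list(range(1, len(coll) + 1))
        assert all(r.critical_p == pytest.approx(1 / len(coll)) for r in results)
        assert all(r.significant == (r.p_value <= r.critical_p + 1e-12) for r in results)

    def test_self_flag_marks_shared_experiment(self):
        rng = np.random.default_rng(6)
        coll = self._collection(rng)
        sig = make_signature({"P0001": 1, "P0002": -1}, experiment_id="e2")
        results = fc.query(sig, coll, n_sim=200, seed=1)
        assert {r.set_id for r in results if r.self} == {"set2"}

    def test_perfect_match_set_ranks_first(self):
        rng = np.random.default_rng(8)
        coll = self._collection(rng, n_sets=6, n=50)
        target = coll[3].members[0]
        order = np.argsort(-np.abs(target.signed_rank))[:8]
        sig = make_signature(
            {
                target.probe_ids[i]: int(np.sign(target.signed_rank[i]))
                for i in order
            },
            experiment_id="eQ",
        )
        results = fc.query(sig, coll, n_sim=500, seed=2)
        assert results[0].set_id == "set3" and results[0].score == pytest.approx(1.0)

    def test_single_set_max_score(self, toy_set):
        sig = make_signature({"P2": -1, "P5": 1})
        (res,) = fc.query(sig, [toy_set], seed=0)
        assert res.rank == 1 and res.score == 1.0
        assert res.significant == (res.p_value <= 1.0)

    def test_empty_collection_rejected(self, toy_set):
        sig = make_signature({"P2": -1, "P5": 1})
        with pytest.raises(ValidationError, match="empty"):
            fc.query(sig, [], seed=0)

    def test_identical_seed_reproduces_results(self):
        rng = np.random.default_rng(9)
        coll = self._collection(rng, n_sets=4, n=60)
        sig = make_signature({f"P{i:04d}": 1 for i in range(6)})
        r1 = fc.query(sig, coll, n_sim=800, seed=13)
        r2 = fc.query(sig, coll, n_sim=800, seed=13)
        assert [(r.set_id, r.score, r.p_value) for r in r1] == [
            (r.set_id, r.score, r.p_value) for r in r2
        ]

    def test_null_cache_shares_draws_across_signatures(self):
        rng = np.random.default_rng(10)
        coll = self._collection(rng, n_sets=3, n=60)
        sig_a = make_signature({f"P{i:04d}": 1 for i in range(5)}, name="a")
        sig_b = make_signature({f"P{i:04d}": -1 for i in range(5)}, name="b")
        cache = {}
        fc.query(sig_a, coll, n_sim=300, seed=4, null_cache=cache)
        assert len(cache) == 3
        before = {k: v.copy() for k, v in cache.items()}
        fc.query(sig_b, coll, n_sim=300, seed=4, null_cache=cache)
        for k in cache:
            np.testing.assert_array_equal(cache[k], before[k])
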