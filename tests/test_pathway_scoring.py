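import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.special import comb

from stagepath import pathway_scoring as ps
from stagepath import synthetic
from stagepath.io_formats import GeneSet, validate_metadata


def prefix_oracle(z):
    """Exhaustive enumeration of every prefix of the sorted values."""
    z = sorted(z, reverse=True)
    best, best_t = -np.inf, None
    for t in range(1, len(z) + 1):
        score = sum(z[:t]) / np.sqrt(t)
        if score > best:
            best, best_t = score, t
    return best, best_t


def _coll(**sets):
    return {name: GeneSet(name, "d", frozenset(genes))
            for name, genes in sets.items()}


class TestFisherEnrichment:
    def test_full_overlap_matches_hypergeometric_point_mass(self):
        universe = {f"g{i}" for i in range(100)}
        pathway = {f"g{i}" for i in range(10)}
        res = ps.fisher_enrichment(pathway, _coll(P1=pathway), universe)
        expected = 1 / comb(100, 10)  # P(X >= 10) = P(X = 10)
        assert res.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)
        assert res.loc[0, "p_value"] == pytest.approx(5.776e-14, rel=1e-3)

    def test_zero_overlap_vacuous_tail(self):
        universe = {f"g{i}" for i in range(100)}
        res = ps.fisher_enrichment({"g0"}, _coll(P1={"g99"}), universe)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_query_equals_universe_saturated(self):
        universe = {f"g{i}" for i in range(30)}
        coll = _coll(P1={"g0", "g1", "g2"}, P2={"g5"})
        res = ps.fisher_enrichment(universe, coll, universe)
        assert np.allclose(res["p_value"], 1.0)
        assert (res["overlap"] == res["pathway_size"]).all()

    def test_matches_scipy_fisher_exact(self):
        universe = {f"g{i}" for i in range(60)}
        query = {f"g{i}" for i in range(12)}
        pathway = {f"g{i}" for i in range(8, 28)}
        res = ps.fisher_enrichment(query, _coll(P=pathway), universe)
        overlap = len(query & pathway)
        table = [[overlap, len(query) - overlap],
                 [len(pathway) - overlap,
                  60 - len(pathway) - len(query) + overlap]]
        _, p_ref = sps.fisher_exact(table, alternative="greater")
        assert res.loc[0, "p_value"] == pytest.approx(p_ref, rel=1e-9)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError):
            ps.fisher_enrichment(set(), _coll(P={"g"}), set())


class TestGeneAnova:
    def _meta(self, n=(4, 4, 4)):
        samples = [f"s{i}" for i in range(sum(n))]
        phases = (["control"] * n[0] + ["early"] * n[1] + ["late"] * n[2])
        return samples, validate_metadata(pd.DataFrame(
            {"phase": phases}, index=pd.Index(samples, name="sample_id")))

    def test_constant_gene_p_one(self):
        samples, meta = self._meta()
        m = pd.DataFrame([[3.0] * 12], index=["g"], columns=samples)
        assert ps.gene_anova(m, meta)["g"] == pytest.approx(1.0)

    def test_strong_separation_tiny_p(self):
        samples, meta = self._meta((10, 10, 10))
        rng = np.random.default_rng(8)
        row = np.r_[rng.normal(0, 1, 10), rng.normal(5, 1, 10),
                    rng.normal(10, 1, 10)]
        m = pd.DataFrame([row], index=["g"], columns=samples)
        assert ps.gene_anova(m, meta)["g"] < 1e-10

    def test_matches_scipy_f_oneway(self):
        samples, meta = self._meta((6, 5, 7))
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.standard_normal((30, 18)), columns=samples)
        p = ps.gene_anova(m, meta)
        ref = sps.f_oneway(m.iloc[:, :6], m.iloc[:, 6:11], m.iloc[:, 11:],
                           axis=1).pvalue
        np.testing.assert_allclose(p, ref, atol=1e-12)

    def test_single_sample_phase_is_error(self):
        samples, meta = self._meta((4, 1, 4))
        m = pd.DataFrame(np.zeros((2, 9)), columns=samples)
        with pytest.raises(ValueError, match="early"):
            ps.gene_anova(m, meta)


class TestPToZ:
    def test_median_maps_to_zero(self):
        assert ps.p_to_z(0.5, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_standard_quantile(self):
        assert ps.p_to_z(0.05, 1.0) == pytest.approx(1.6448536269514722,
                                                     rel=1e-9)

    def test_weight_scales_linearly(self):
        assert ps.p_to_z(0.05, 0.5) == pytest.approx(0.8224268134757361,
                                                     rel=1e-9)

    def test_floor_keeps_z_finite(self):
        z = ps.p_to_z(0.0, 1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(sps.norm.isf(1e-16))

    def test_p_above_one_rejected(self):
        with pytest.raises(ValueError):
            ps.p_to_z(1.5, 1.0)


class TestDeviationScore:
    @pytest.mark.parametrize("z,expected_a,expected_t", [
        ([3.0], 3.0, 1),
        ([3.0, 1.0], 3.0, 1),            # max(3, 4/sqrt(2)=2.83)
        ([1.0, 1.0, 1.0, 1.0], 2.0, 4),  # equal values: sqrt(k)
        ([-1.0, -2.0], -1.0, 1),         # all-negative: least negative wins
    ])
    def test_hand_enumerated_prefixes(self, z, expected_a, expected_t):
        a, t = ps.deviation_score(z)
        assert a == pytest.approx(expected_a)
        assert t == expected_t

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError):
            ps.deviation_score([])

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            k = int(rng.integers(1, 51))
            z = rng.normal(0, 2, size=k)
            a, t = ps.deviation_score(z)
            a_ref, t_ref = prefix_oracle(z)
            assert a == pytest.approx(a_ref, rel=1e-12)
            assert t == t_ref

    def test_order_invariant_and_homogeneous(self):
        rng = np.random.default_rng(56)
        z = rng.normal(size=20)
        a1, _ = ps.deviation_score(z)
        a2, _ = ps.deviation_score(z[::-1])
        assert a1 == a2
        a3, _ = ps.deviation_score(3.5 * z)
        assert a3 == pytest.approx(3.5 * a1, rel=1e-12)

    def test_monotone_in_each_value(self):
        rng = np.random.default_rng(57)
        z = rng.normal(size=15)
        a0, _ = ps.deviation_score(z)
        for i in range(15):
            bumped = z.copy()
            bumped[i] += 0.5
            a1, _ = ps.deviation_score(bumped)
            assert a1 >= a0 - 1e-12


class TestCalibrateScore:
    def test_constant_background_is_degenerate(self):
        pool = np.full(50, 2.0)
        with pytest.raises(ValueError, match="sigma"):
            ps.calibrate_score(3.0, 5, pool, n_perm=100, seed=1)

    def test_score_at_null_mean_centres_to_zero(self):
        rng = np.random.default_rng(2)
        pool = rng.standard_normal(200)
        null_rng = np.random.default_rng(7)
        mu, sigma, _ = ps.calibrate_score(0.0, 10, pool, n_perm=500, seed=7)
        _, _, centred = ps.calibrate_score(mu, 10, pool, n_perm=500, seed=7)
        assert centred == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_permutation_loop(self):
        """Same sampling protocol, A' computed by exhaustive prefix
        enumeration instead of the vectorized path."""
        rng = np.random.default_rng(3)
        pool = rng.standard_normal(200)
        k, n_perm, seed = 10, 400, 11
        mu, sigma, ac = ps.calibrate_score(3.0, k, pool, n_perm=n_perm,
                                           seed=seed)
        # re-draw the same subsets (random-key argpartition) and score each
        # with the brute-force oracle
        oracle_rng = np.random.default_rng(seed)
        keys = oracle_rng.random((n_perm, pool.size))
        idx = np.argpartition(keys, k, axis=1)[:, :k]
        scores = np.array([prefix_oracle(pool[row])[0] for row in idx])
        assert mu == pytest.approx(scores.mean(), rel=1e-12)
        assert sigma == pytest.approx(scores.std(ddof=1), rel=1e-12)

    def test_planted_signal_exceeds_null(self):
        rng = np.random.default_rng(4)
        pool = rng.standard_normal(200)
        a, _ = ps.deviation_score(np.full(10, 3.0))
        _, _, ac = ps.calibrate_score(a, 10, pool, n_perm=2000, seed=1)
        assert ac > 3.0


class TestScorePathways:
    def test_top_z_pathway_dominates(self):
        rng = np.random.default_rng(20)
        z = dict(zip([f"g{i}" for i in range(100)],
                     np.sort(rng.standard_normal(100))[::-1]))
        members = {"top": [f"g{i}" for i in range(10)],
                   "mid": [f"g{i}" for i in range(40, 50)],
                   "low": [f"g{i}" for i in range(90, 100)]}
        out = ps.score_pathways(members, z, n_perm=500, seed=2)
        assert out.loc[0, "pathway"] == "top"
        assert list(out["A_corrected"]) == sorted(out["A_corrected"],
                                                  reverse=True)

    def test_identical_member_sets_score_identically(self):
        rng = np.random.default_rng(21)
        z = dict(zip([f"g{i}" for i in range(50)], rng.standard_normal(50)))
        genes = [f"g{i}" for i in range(5, 15)]
        out = ps.score_pathways({"a": genes, "b": list(reversed(genes))},
                                z, n_perm=300, seed=9)
        a = out.set_index("pathway")
        assert a.loc["a", "A"] == a.loc["b", "A"]
        assert a.loc["a", "A_corrected"] == a.loc["b", "A_corrected"]

    def test_evaluation_order_does_not_matter(self):
        rng = np.random.default_rng(22)
        z = dict(zip([f"g{i}" for i in range(60)], rng.standard_normal(60)))
        m1 = {"a": [f"g{i}" for i in range(8)],
              "b": [f"g{i}" for i in range(30, 42)]}
        m2 = dict(reversed(list(m1.items())))
        o1 = ps.score_pathways(m1, z, n_perm=300, seed=5).set_index("pathway")
        o2 = ps.score_pathways(m2, z, n_perm=300, seed=5).set_index("pathway")
        pd.testing.assert_frame_equal(o1.sort_index(), o2.sort_index())

    def test_pathway_without_scored_members_skipped(self):
        z = {"g1": 1.0, "g2": 0.5}
        out = ps.score_pathways({"ok": ["g1"], "ghost": ["zzz"]}, z,
                                n_perm=50, seed=0)
        assert list(out["pathway"]) == ["ok"]


class TestSampleScores:
    def test_all_zero_members_score_zero(self):
        m = pd.DataFrame(np.zeros((4, 3)), index=list("abcd"),
                         columns=["s1", "s2", "s3"])
        s = ps.sample_scores(m, list("abcd"))
        assert (s == 0).all()

    def test_equal_values_closed_form(self):
        # k members all equal to v with weight 1 score v * sqrt(k)
        m = pd.DataFrame(np.full((4, 2), 2.0), index=list("abcd"),
                         columns=["s1", "s2"])
        s = ps.sample_scores(m, list("abcd"))
        assert s["s1"] == pytest.approx(4.0)

    def test_weights_applied(self):
        m = pd.DataFrame([[2.0], [2.0]], index=["a", "b"], columns=["s"])
        s = ps.sample_scores(m, ["a", "b"], {"a": 0.5, "b": 0.5})
        assert s["s"] == pytest.approx(1.0 * np.sqrt(2))

    def test_null_data_no_phase_effect(self):
        expr, meta, _, _ = synthetic.simulate_dataset(
            300, (40, 20, 30), n_de_early=0, n_de_late=0, n_shared=0,
            n_blocks=0, n_pathways=0, seed=33)
        genes = list(expr.index[:15])
        s = ps.sample_scores(expr, genes)
        ctrl = s[meta.index[meta["phase"] == "control"]]
        case = s[meta.index[meta["phase"] != "control"]]
        assert abs(ctrl.mean() - case.mean()) < 0.5


class TestPathwayAnova:
    def _profiles_meta(self, seed=0, effect=0.0):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(60)]
        meta = validate_metadata(pd.DataFrame(
            {"phase": ["control"] * 30 + ["early"] * 15 + ["late"] * 15},
            index=pd.Index(samples, name="sample_id")))
        scores = rng.standard_normal((3, 60))
        scores[0, 30:] += effect
        profiles = pd.DataFrame(scores, index=["p1", "p2", "p3"],
                                columns=samples)
        return profiles, meta

    def test_constant_scores_p_one(self):
        profiles, meta = self._profiles_meta()
        profiles.iloc[1] = 5.0
        out = ps.pathway_anova(profiles, meta).set_index("pathway")
        assert out.loc["p2", "p_value"] == pytest.approx(1.0)

    def test_planted_effect_significant(self):
        profiles, meta = self._profiles_meta(seed=1, effect=2.0)
        out = ps.pathway_anova(profiles, meta).set_index("pathway")
        assert out.loc["p1", "p_value"] < 0.001
        assert out.loc["p1", "significant"]

    def test_null_scores_not_inflated(self):
        rng = np.random.default_rng(40)
        samples = [f"s{i}" for i in range(90)]
        meta = validate_metadata(pd.DataFrame(
            {"phase": ["control"] * 40 + ["early"] * 20 + ["late"] * 30},
            index=pd.Index(samples, name="sample_id")))
        profiles = pd.DataFrame(rng.standard_normal((200, 90)),
                                columns=samples,
                                index=[f"p{i}" for i in range(200)])
        out = ps.pathway_anova(profiles, meta)
        frac = (out["p_value"] < 0.05).mean()
        assert 0.01 <= frac <= 0.10
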