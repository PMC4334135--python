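import itertools
import math

import numpy as np
import pytest

from metaseed.enrichment import (
    PfafflInput,
    RankedList,
    _es_from_positions,
    correlation_clustering,
    ks_enrichment,
    linkage_to_newick,
    msea,
    permutation_pvalue,
    pfaffl_fold_change,
    rank_features,
)
from metaseed.preprocess import FeatureRecord

from _oracles import exhaustive_ks_pvalue, ks_walk

IDS4 = ("r1", "r2", "r3", "r4")


def make_feature(fid, pct):
    f = FeatureRecord(fid, 200.0, 300.0, 201.0)
    f.status = "retained"
    f.percent_change = pct
    f.fold_change = 1.0
    return f


class TestRankFeatures:
    def test_descending_order(self):
        ranked = rank_features([make_feature("A", 30), make_feature("B", -10),
                                make_feature("C", 5)])
        assert ranked.ids == ("A", "C", "B")

    def test_ties_broken_by_id(self):
        ranked = rank_features([make_feature(x, 1.0) for x in "cab"])
        assert ranked.ids == ("a", "b", "c")

    def test_empty(self):
        assert rank_features([]).ids == ()

    def test_nan_score_errors(self):
        f = make_feature("A", 1.0)
        f.percent_change = None
        f.fold_change = 1.0
        with pytest.raises(ValueError, match="A"):
            rank_features([f])


class TestKsEnrichment:
    @pytest.mark.parametrize("members, expected", [
        ({"r1", "r2"}, 1.0),
        ({"r3", "r4"}, -1.0),
        ({"r2", "r4"}, -0.5),
    ])
    def test_hand_walked_cases(self, members, expected):
        assert ks_enrichment(IDS4, members) == pytest.approx(expected)

    def test_bounds_and_prefix_extreme(self):
        rng = np.random.default_rng(3)
        ids = tuple(f"f{i}" for i in range(40))
        for _ in range(50):
            h = int(rng.integers(1, 20))
            members = set(rng.choice(ids, size=h, replace=False))
            es = ks_enrichment(ids, members)
            assert abs(es) <= 1.0 + 1e-12
            assert (es == pytest.approx(1.0)) == (members == set(ids[:h]))

    def test_sign_flips_on_reversed_ranking(self):
        ids = tuple(f"f{i}" for i in range(30))
        members = set(ids[:5]) | {ids[10]}
        es = ks_enrichment(ids, members)
        es_rev = ks_enrichment(tuple(reversed(ids)), members)
        assert es_rev == pytest.approx(-es)

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError):
            ks_enrichment(IDS4, set())
        with pytest.raises(ValueError):
            ks_enrichment(IDS4, set(IDS4))

    def test_positions_formula_equals_walk(self):
        """The O(H) extremum formula must agree with the literal walk
        (up to the sign convention on exactly tied +/- excursions, where
        float accumulation order can differ)."""
        rng = np.random.default_rng(9)
        for _ in range(200):
            n = int(rng.integers(3, 30))
            h = int(rng.integers(1, n))
            ids = [str(i) for i in range(n)]
            members = set(rng.choice(ids, size=h, replace=False))
            pos = np.array(sorted(int(m) for m in members))
            ours = _es_from_positions(pos, n)
            walk = ks_walk(ids, members)
            assert abs(ours) == pytest.approx(abs(walk), abs=1e-12)
            if abs(ours - walk) > 1e-9:  # tied excursion, opposite sign
                assert ours + walk == pytest.approx(0.0, abs=1e-9)


class TestPermutationPvalue:
    def test_exhaustive_prefix_case(self):
        # ES=1.0 for members {r1, r2}: only {r1,r2} and {r3,r4} reach |ES|=1
        p = permutation_pvalue(IDS4, ["r1", "r2"])
        assert p == pytest.approx(2 / 6)

    def test_minimal_excursion_gives_p_one(self):
        # the placement with the smallest |ES| is exceeded by every other
        ids = tuple("abcdef")
        combos = list(itertools.combinations(ids, 3))
        best = min(combos, key=lambda c: abs(ks_enrichment(ids, set(c))))
        assert permutation_pvalue(ids, list(best)) == pytest.approx(1.0)

    def test_same_seed_reproducible(self):
        ids = tuple(f"f{i}" for i in range(60))
        members = [f"f{i}" for i in range(0, 12)]
        p1 = permutation_pvalue(ids, members, n_perm=500, seed=5,
                                exhaustive_limit=0)
        p2 = permutation_pvalue(ids, members, n_perm=500, seed=5,
                                exhaustive_limit=0)
        assert p1 == p2

    def test_n_perm_floor(self):
        ids = tuple(f"f{i}" for i in range(60))
        with pytest.raises(ValueError):
            permutation_pvalue(ids, ["f0", "f1"], n_perm=50, exhaustive_limit=0)

    @pytest.mark.parametrize("n, h", [(n, h) for n in range(3, 9)
                                      for h in range(1, min(5, n))])
    def test_monte_carlo_matches_exhaustive(self, n, h):
        """MC p within 3 SE of the exact enumeration, all small cases."""
        ids = tuple(str(i) for i in range(n))
        members = list(ids[:h])  # prefix placement, |ES| maximal
        es = ks_enrichment(ids, set(members))
        p_ex = exhaustive_ks_pvalue(n, h, es)
        n_perm = 50000
        p_mc = permutation_pvalue(ids, members, n_perm=n_perm, seed=123,
                                  exhaustive_limit=0)
        se = math.sqrt(p_ex * (1 - p_ex) / n_perm)
        assert abs(p_mc - p_ex) <= 3 * se + 2 / n_perm


class TestMsea:
    def make_ranking(self, n=40):
        feats = [make_feature(f"f{i:02d}", float(n - i)) for i in range(n)]
        return rank_features(feats)

    def test_top_loaded_set_has_smallest_p(self):
        ranked = self.make_ranking()
        sets = {
            "top": [f"f{i:02d}" for i in range(5)],
            "mid": [f"f{i:02d}" for i in range(17, 22)],
            "spread": [f"f{i:02d}" for i in (0, 9, 19, 29, 39)],
        }
        results = msea(ranked, sets, n_perm=2000, seed=1)
        assert results[0].pathway_id == "top"
        assert results[0].direction == "up"

    def test_duplicate_set_identical_result(self):
        ranked = self.make_ranking()
        members = [f"f{i:02d}" for i in range(4)]
        r = msea(ranked, {"A": members, "A2": members}, n_perm=1000, seed=9)
        # different id -> different substream, but ES identical
        assert r[0].es == r[1].es
        r1 = msea(ranked, {"A": members}, n_perm=1000, seed=9)
        r2 = msea(ranked, {"A": members, "other": [f"f{i:02d}" for i in range(20, 30)]},
                  n_perm=1000, seed=9)
        assert r1[0].p_value == [x for x in r2 if x.pathway_id == "A"][0].p_value

    def test_type_one_error_calibrated(self):
        """Random sets in random rankings: p <= 0.05 at ~nominal rate."""
        rng = np.random.default_rng(2024)
        n, h = 80, 6
        ids = tuple(f"f{i}" for i in range(n))
        rejections = 0
        reps = 300
        for _ in range(reps):
            members = list(rng.choice(ids, size=h, replace=False))
            p = permutation_pvalue(ids, members, n_perm=499,
                                   seed=int(rng.integers(2**31)),
                                   exhaustive_limit=0)
            rejections += p <= 0.05
        # 95% binomial CI around 0.05 for 300 replicates
        lo, hi = 0.05 - 1.96 * math.sqrt(0.05 * 0.95 / reps), \
            0.05 + 1.96 * math.sqrt(0.05 * 0.95 / reps)
        assert lo <= rejections / reps <= hi


class TestCorrelationClustering:
    def test_identical_vectors_merge_first(self):
        vecs = {"a": [1, 2, 3, 4], "b": [2, 4, 6, 8], "c": [4, 3, 2, 1]}
        r, linkage, leaves = correlation_clustering(vecs)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert set(linkage[0, :2].astype(int)) == {0, 1}  # a,b merged first

    def test_anticorrelated_distance_two(self):
        vecs = {"a": [1.0, 2.0, 3.0], "b": [-1.0, -2.0, -3.0], "c": [1.0, 0.0, 2.0]}
        r, _linkage, _leaves = correlation_clustering(vecs)
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_matches_closed_form_pearson(self):
        rng = np.random.default_rng(4)
        vecs = {k: rng.normal(size=6) for k in "xyz"}
        r, _linkage, _ = correlation_clustering(vecs)
        for a, b in itertools.combinations("xyz", 2):
            va, vb = vecs[a], vecs[b]
            num = ((va - va.mean()) * (vb - vb.mean())).sum()
            den = math.sqrt(((va - va.mean()) ** 2).sum()
                            * ((vb - vb.mean()) ** 2).sum())
            assert r.loc[a, b] == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_excluded_with_warning(self):
        vecs = {"a": [1, 2, 3], "b": [5, 5, 5], "c": [3, 1, 2]}
        with pytest.warns(UserWarning, match="zero-variance"):
            r, _linkage, _ = correlation_clustering(vecs)
        assert list(r.index) == ["a", "c"]

    def test_newick_output_parses(self):
        vecs = {"a": [1, 2, 3, 4], "b": [2, 4, 6, 8], "c": [4, 3, 2, 1]}
        r, linkage, _ = correlation_clustering(vecs)
        nwk = linkage_to_newick(linkage, list(r.index))
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")
        for name in "abc":
            assert name in nwk


class TestPfaffl:
    def test_cubed_efficiency(self):
        fold = pfaffl_fold_change(PfafflInput(2.0, 2.0, 3.0, 0.0))
        assert fold == pytest.approx(8.0)

    def test_identity(self):
        assert pfaffl_fold_change(PfafflInput(2.0, 2.0, 0.0, 0.0)) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        fold = pfaffl_fold_change(PfafflInput(1.9, 1.8, 2.0, 1.0))
        assert fold == pytest.approx(3.61 / 1.8, abs=1e-4)

    def test_monotone_in_target_dcp(self):
        folds = [pfaffl_fold_change(PfafflInput(1.9, 1.8, d, 1.0))
                 for d in (0.0, 1.0, 2.0, 3.0)]
        assert folds == sorted(folds)

    def test_swapped_conditions_reciprocal(self):
        a = pfaffl_fold_change(PfafflInput(1.9, 1.8, 2.5, 1.5))
        b = pfaffl_fold_change(PfafflInput(1.9, 1.8, -2.5, -1.5))
        assert a * b == pytest.approx(1.0)

    @pytest.mark.parametrize("eff", [1.0, 0.9, 2.1])
    def test_invalid_efficiency(self, eff):
        with pytest.raises(ValueError):
            PfafflInput(eff, 2.0, 1.0, 1.0)
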