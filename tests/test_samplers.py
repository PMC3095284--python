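import itertools
import json

import numpy as np
import pytest

import corekit as ck

from conftest import random_genotypes


def toy_distance(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [chr(ord("a") + i) for i in range(len(values))]
    return ck.DistanceMatrix(ids, values, "one_minus_ps")


def ranked_walk_oracle(D, k):
    """Independent re-implementation of the ranked-pair walk for matrices
    with all-distinct distances (no ties, fully deterministic)."""
    pairs = sorted(
        ((i, j) for i in range(D.n) for j in range(i + 1, D.n)),
        key=lambda p: -D.values[p],
    )
    chosen: list[int] = []
    for i, j in pairs:
        for m in (i, j):
            if m not in chosen and len(chosen) < k:
                chosen.append(m)
        if len(chosen) == k:
            break
    return {D.accession_ids[i] for i in chosen}


class TestCorexSelect:
    def test_k_equals_n_everything_included(self):
        D = toy_distance([[0, 1, 2], [1, 0, 3], [2, 3, 0]])
        sel = ck.corex_select(D, 3, reps=5, seed=0)
        assert all(len(r) == 3 for r in sel.repetitions)
        assert sorted(sel.stable_set()) == ["a", "b", "c"]
        assert all(f == 1.0 for f in sel.inclusion.values())

    def test_unique_max_pair_k2(self):
        # global max pair (c, d) is unique: every repetition must pick it
        v = np.array(
            [
                [0.0, 0.1, 0.2, 0.3],
                [0.1, 0.0, 0.4, 0.5],
                [0.2, 0.4, 0.0, 0.9],
                [0.3, 0.5, 0.9, 0.0],
            ]
        )
        sel = ck.corex_select(toy_distance(v), 2, reps=50, seed=1)
        assert all(r == ["c", "d"] for r in sel.repetitions)
        assert sorted(sel.stable_set()) == ["c", "d"]

    def test_distinct_distances_match_walk_oracle(self):
        rng = np.random.default_rng(11)
        n = 6
        v = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        vals = rng.permutation(len(iu)) + 1.0  # all distinct
        v[iu, ju] = vals
        v[ju, iu] = vals
        D = toy_distance(v / vals.max())
        for k in (2, 3, 4, 5):
            sel = ck.corex_select(D, k, reps=10, seed=3)
            expect = ranked_walk_oracle(D, k)
            # no ties: deterministic across repetitions up to the boundary
            stable = set(sel.stable_set())
            assert stable <= expect
            assert len(expect) == k
            for r in sel.repetitions:
                assert len(r) == k

    def test_no_ties_k3_fully_deterministic(self):
        # boundary lands exactly on a pair completion: walk is unique
        v = np.array(
            [
                [0.0, 0.9, 0.1, 0.2],
                [0.9, 0.0, 0.3, 0.4],
                [0.1, 0.3, 0.0, 0.8],
                [0.2, 0.4, 0.8, 0.0],
            ]
        )
        D = toy_distance(v)
        sel = ck.corex_select(D, 4, reps=20, seed=5)
        assert set(sel.stable_set()) == ranked_walk_oracle(D, 4)

    def test_invalid_arguments(self):
        D = toy_distance([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            ck.corex_select(D, 1, reps=1, seed=0)
        with pytest.raises(ValueError):
            ck.corex_select(D, 3, reps=1, seed=0)
        with pytest.raises(ValueError):
            ck.corex_select(D, 2, reps=0, seed=0)

    def test_transform_invariance(self):
        rng = np.random.default_rng(8)
        G = random_genotypes(rng, 10, 3)
        d1 = ck.distance_matrix(G, "one_minus_ps")
        d2 = ck.distance_matrix(G, "neg_log_ps")
        s1 = ck.corex_select(d1, 5, reps=20, seed=99)
        s2 = ck.corex_select(d2, 5, reps=20, seed=99)
        assert s1.repetitions == s2.repetitions

    def test_reproducibility_byte_identical(self):
        rng = np.random.default_rng(4)
        G = random_genotypes(rng, 8, 2)
        D = ck.distance_matrix(G)
        a = ck.corex_select(D, 4, reps=10, seed=7)
        b = ck.corex_select(D, 4, reps=10, seed=7)
        assert a.to_json() == b.to_json()


class TestStableSet:
    def test_single_repetition(self):
        D = toy_distance([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])
        sel = ck.corex_select(D, 2, reps=1, seed=0)
        assert ck.stable_set(sel) == sel.repetitions[0]

    def test_99_of_100_excluded_at_full_threshold(self):
        sel = ck.CoreSelection(
            method="x", k=1, reps=100,
            repetitions=[["a"]] * 99 + [["b"]],
            inclusion={"a": 0.99, "b": 0.01},
            selected=[],
        )
        assert ck.stable_set(sel, 1.0) == []

    def test_intermediate_threshold(self):
        sel = ck.CoreSelection(
            method="x", k=3, reps=10, repetitions=[],
            inclusion={"a": 1.0, "b": 0.6, "c": 0.4}, selected=[],
        )
        assert sorted(ck.stable_set(sel, 0.5)) == ["a", "b"]
        with pytest.raises(ValueError):
            ck.stable_set(sel, 0.0)


class TestRandomSelect:
    def test_k_equals_n(self):
        sel = ck.random_select(list("abcd"), 4, reps=3, seed=0)
        assert all(len(r) == 4 for r in sel.repetitions)

    def test_inclusion_frequency_near_k_over_n(self):
        n, k, reps = 20, 5, 1000
        sel = ck.random_select([f"s{i}" for i in range(n)], k, reps=reps, seed=12)
        expected = k / n
        se = np.sqrt(expected * (1 - expected) / reps)
        for i in range(n):
            f = sel.inclusion.get(f"s{i}", 0.0)
            assert abs(f - expected) < 3.5 * se

    def test_same_seed_identical(self):
        a = ck.random_select(list("abcdefgh"), 3, reps=5, seed=2)
        b = ck.random_select(list("abcdefgh"), 3, reps=5, seed=2)
        assert a.repetitions == b.repetitions
        # reported core is the first repetition
        assert a.selected == a.repetitions[0]


class TestMStrategyCover:
    def test_identical_accessions_cover_size_one(self):
        calls = np.tile(np.array([[[1, 2], [3, 3]]]), (5, 1, 1))
        G = ck.GenotypeMatrix([f"s{i}" for i in range(5)], ["L1", "L2"], calls)
        sel = ck.mstrategy_cover(G, seed=0)
        assert len(sel.selected) == 1

    def test_toy_cover_matches_brute_force(self):
        # accession allele sets {a,b}, {a,c}, {b,c}, {d} at one locus
        calls = np.array([[[1, 2]], [[1, 3]], [[2, 3]], [[4, 4]]])
        G = ck.GenotypeMatrix(list("wxyz"), ["L"], calls)
        sel = ck.mstrategy_cover(G, seed=0)
        assert len(sel.selected) == 3
        covered = ck.count_distinct_alleles(G, sel.selected)[0]
        assert covered == 4
        # brute force: no 2-subset covers all 4 alleles
        for combo in itertools.combinations(G.accession_ids, 2):
            assert ck.count_distinct_alleles(G, list(combo))[0] < 4

    def test_full_coverage_always(self, rice_panel):
        G, _, _ = rice_panel
        sel = ck.mstrategy_cover(G, seed=3)
        total, _ = ck.count_distinct_alleles(G)
        assert ck.count_distinct_alleles(G, sel.selected)[0] == total
        # greedy never adds a zero-gain accession: size <= distinct alleles
        assert len(sel.selected) <= total


class TestMStrategyFixed:
    def test_k_at_least_cover_size_gives_full_coverage(self):
        calls = np.array([[[1, 2]], [[1, 3]], [[2, 3]], [[4, 4]]])
        G = ck.GenotypeMatrix(list("wxyz"), ["L"], calls)
        sel = ck.mstrategy_fixed(G, 4, reps=5, seed=1)
        assert ck.count_distinct_alleles(G, sel.selected)[0] == 4

    def test_k1_rejected(self):
        calls = np.array([[[1, 2]], [[1, 3]]])
        G = ck.GenotypeMatrix(["a", "b"], ["L"], calls)
        with pytest.raises(ValueError):
            ck.mstrategy_fixed(G, 1, reps=1, seed=0)

    def test_between_random_and_exhaustive_optimum(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            G = random_genotypes(rng, 8, 2, max_allele=4)
            k = 3
            sel = ck.mstrategy_fixed(G, k, reps=10, seed=trial)
            got = ck.count_distinct_alleles(G, sel.selected)[0]
            best = max(
                ck.count_distinct_alleles(G, list(c))[0]
                for c in itertools.combinations(G.accession_ids, k)
            )
            mean_random = np.mean(
                [
                    ck.count_distinct_alleles(G, list(rng.choice(G.accession_ids, k, replace=False)))[0]
                    for _ in range(20)
                ]
            )
            assert got <= best
            assert got >= mean_random - 1e-9


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        D = toy_distance([[0, 0.5, 0.2], [0.5, 0, 0.1], [0.2, 0.1, 0]])
        sel = ck.corex_select(D, 2, reps=4, seed=9)
        path = tmp_path / "sel.json"
        sel.write_json(str(path))
        back = ck.selection_from_json(str(path))
        assert back.repetitions == sel.repetitions
        assert back.inclusion == sel.inclusion
        assert back.selected == sel.selected

    def test_csv_ordering(self, tmp_path):
        sel = ck.CoreSelection(
            method="x", k=2, reps=2,
            repetitions=[["a", "b"], ["a", "c"]],
            inclusion={"a": 1.0, "b": 0.5, "c": 0.5},
            selected=["a"],
        )
        path = tmp_path / "sel.csv"
        sel.write_csv(str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "accession,inclusion_frequency,in_stable_set"
        assert lines[1].startswith("a,1.000000,1")
        assert [ln.split(",")[0] for ln in lines[1:]] == ["a", "b", "c"]


class TestRetentionMonotonicity:
    def test_corex_stable_retention_non_decreasing(self, rice_panel):
        G, _, _ = rice_panel
        # scaled-down sweep on a subset for speed
        sub = G.accession_ids[:120]
        Gs = G.subset(sub)
        D = ck.distance_matrix(Gs)
        curve = ck.retention_curve(Gs, D, [10, 25, 40, 60, 80, 100], reps=30, seed=5)
        ret = curve.retention_pct
        assert all(b >= a - 1e-9 for a, b in zip(ret, ret[1:]))
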