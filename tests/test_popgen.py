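import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import corekit as ck
from corekit.genotypes import MISSING

from conftest import random_genotypes


def make_freq_table(freq_lists, ns):
    """Build an AlleleFrequencyTable from per-locus frequency dicts."""
    counts = []
    for fs, n in zip(freq_lists, ns):
        counts.append({a: round(f * 2 * n) for a, f in fs.items()})
    return ck.AlleleFrequencyTable(
        [f"L{i}" for i in range(len(freq_lists))], counts, np.array(ns)
    )


class TestObservedHeterozygosity:
    def test_all_homozygous(self, grouped_matrix):
        G, _ = grouped_matrix
        assert ck.observed_heterozygosity(G, "L1") == 0.0

    def test_all_heterozygous(self):
        G = ck.GenotypeMatrix(["a", "b"], ["L"], np.array([[[1, 2]], [[3, 4]]]))
        assert ck.observed_heterozygosity(G, "L") == 1.0

    def test_one_het_of_four(self):
        calls = np.array([[[1, 2]], [[1, 1]], [[2, 2]], [[1, 1]]])
        G = ck.GenotypeMatrix(list("abcd"), ["L"], calls)
        assert ck.observed_heterozygosity(G, "L") == 0.25


class TestGeneDiversity:
    def test_monomorphic_zero(self):
        t = make_freq_table([{1: 1.0}], [5])
        assert ck.gene_diversity(t, 0, unbiased=False) == 0.0
        assert ck.gene_diversity(t, 0, unbiased=True) == 0.0

    def test_biallelic_half_half_n2(self):
        t = make_freq_table([{1: 0.5, 2: 0.5}], [2])
        assert ck.gene_diversity(t, 0, unbiased=False) == pytest.approx(0.5)
        assert ck.gene_diversity(t, 0, unbiased=True) == pytest.approx(2 / 3)

    def test_three_equifrequent_n3(self):
        t = make_freq_table([{1: 1 / 3, 2: 1 / 3, 3: 1 / 3}], [3])
        assert ck.gene_diversity(t, 0, unbiased=False) == pytest.approx(2 / 3)
        assert ck.gene_diversity(t, 0, unbiased=True) == pytest.approx(0.8)


class TestPic:
    def test_monomorphic_zero(self):
        assert ck.pic(make_freq_table([{1: 1.0}], [4]), 0) == 0.0

    def test_biallelic_half_half(self):
        assert ck.pic(make_freq_table([{1: 0.5, 2: 0.5}], [10]), 0) == pytest.approx(0.375)

    def test_biallelic_skewed(self):
        t = make_freq_table([{1: 0.9, 2: 0.1}], [50])
        assert ck.pic(t, 0) == pytest.approx(0.1638)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 10), st.integers(1, 3))
    def test_pic_bounded_by_raw_gd(self, seed, n, L):
        rng = np.random.default_rng(seed)
        G = random_genotypes(rng, n, L, max_allele=5)
        freqs = ck.allele_frequencies(G)
        for l in range(L):
            raw = ck.gene_diversity(freqs, l, unbiased=False)
            unb = ck.gene_diversity(freqs, l, unbiased=True)
            p = ck.pic(freqs, l)
            assert 0.0 <= p <= raw + 1e-12
            assert raw < 1.0
            # the small-sample correction inflates, and can reach 1.0 at n=2
            assert raw <= unb <= 1.0 + 1e-12


class TestInbreedingF:
    def test_fully_selfed_polymorphic(self, grouped_matrix):
        G, _ = grouped_matrix
        assert ck.inbreeding_f(G) == pytest.approx(1.0)

    def test_monomorphic_undefined(self):
        calls = np.tile(np.array([[1, 1]]), (4, 1, 1))
        G = ck.GenotypeMatrix(list("abcd"), ["L"], calls)
        with pytest.raises(ValueError, match="undefined"):
            ck.inbreeding_f(G)

    def test_hwe_simulation_near_zero(self):
        # panmictic Hardy-Weinberg draws: f should vanish
        rng = np.random.default_rng(20260902)
        n, L = 500, 16
        calls = np.empty((n, L, 2), dtype=np.int32)
        for l in range(L):
            p = rng.dirichlet(np.ones(8))
            calls[:, l, :] = rng.choice(8, size=(n, 2), p=p) + 1
        G = ck.GenotypeMatrix([f"s{i}" for i in range(n)], [f"L{j}" for j in range(L)], calls)
        assert abs(ck.inbreeding_f(G)) < 0.05

    def test_partial_selfing_equilibrium(self):
        # selfing rate 0.98 -> equilibrium f = s/(2-s) ~ 0.9608
        cfg = ck.SimulationConfig(seed=42, n_groups=1, divergence_f=0.0)
        G, _ = ck.simulate_structured_population(cfg)
        assert ck.inbreeding_f(G) == pytest.approx(0.98 / 1.02, abs=0.05)


def wc_oracle(G, groups):
    """Brute-force Weir-Cockerham variance components, written from the
    textbook definitions with explicit loops."""
    labels = groups.labels()
    A = B = C = 0.0
    for l in range(G.n_loci):
        pops = []
        for lab in labels:
            rows = [G.index_of(a) for a in groups.members(lab)]
            cell = [G.calls[i, l].tolist() for i in rows if G.calls[i, l, 0] != MISSING]
            if cell:
                pops.append(cell)
        r = len(pops)
        if r < 2:
            continue
        sizes = [len(p) for p in pops]
        nbar = sum(sizes) / r
        if nbar <= 1:
            continue
        nc = (sum(sizes) - sum(s * s for s in sizes) / sum(sizes)) / (r - 1)
        alleles = sorted({a for p in pops for pair in p for a in pair})
        if len(alleles) < 2:
            continue
        for al in alleles:
            p_i = [sum(pair.count(al) for pair in p) / (2 * len(p)) for p in pops]
            h_i = [
                sum(1 for pair in p if pair[0] != pair[1] and al in pair) / len(p)
                for p in pops
            ]
            pbar = sum(s * x for s, x in zip(sizes, p_i)) / sum(sizes)
            s2 = sum(s * (x - pbar) ** 2 for s, x in zip(sizes, p_i)) / ((r - 1) * nbar)
            hbar = sum(s * h for s, h in zip(sizes, h_i)) / sum(sizes)
            term = pbar * (1 - pbar) - (r - 1) / r * s2
            A += (nbar / nc) * (s2 - (term - hbar / 4) / (nbar - 1))
            B += (nbar / (nbar - 1)) * (term - (2 * nbar - 1) / (4 * nbar) * hbar)
            C += hbar / 2
    return A, B, C


class TestFStatistics:
    def test_fixed_groups_fst_one(self, grouped_matrix):
        G, groups = grouped_matrix
        fs = ck.f_statistics(G, groups)
        assert fs.fst == pytest.approx(1.0)
        assert fs.fit == pytest.approx(1.0)

    def test_random_split_fst_near_zero(self):
        rng = np.random.default_rng(20260903)
        n, L = 500, 16
        calls = np.empty((n, L, 2), dtype=np.int32)
        for l in range(L):
            p = rng.dirichlet(np.ones(6))
            calls[:, l, :] = rng.choice(6, size=(n, 2), p=p) + 1
        ids = [f"s{i}" for i in range(n)]
        G = ck.GenotypeMatrix(ids, [f"L{j}" for j in range(L)], calls)
        labels = rng.permutation(n)
        groups = ck.GroupAssignment({ids[i]: ("A" if labels[i] < n // 2 else "B")
                                     for i in range(n)})
        assert abs(ck.f_statistics(G, groups).fst) < 0.02

    def test_tiny_fixture_matches_oracle(self):
        calls = np.array(
            [
                [[1, 1]], [[1, 2]], [[2, 2]], [[1, 1]],
                [[2, 2]], [[2, 2]], [[1, 2]], [[2, 2]],
            ]
        )
        ids = [f"s{i}" for i in range(8)]
        G = ck.GenotypeMatrix(ids, ["L"], calls)
        groups = ck.GroupAssignment({ids[i]: ("P1" if i < 4 else "P2") for i in range(8)})
        fs = ck.f_statistics(G, groups)
        a, b, c = wc_oracle(G, groups)
        assert fs.fst == pytest.approx(a / (a + b + c), abs=1e-12)
        assert fs.fit == pytest.approx(1 - c / (a + b + c), abs=1e-12)
        assert fs.fis == pytest.approx(1 - c / (b + c), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(4, 10), st.integers(1, 2))
    def test_property_sweep_matches_oracle(self, seed, n, L):
        rng = np.random.default_rng(seed)
        G = random_genotypes(rng, n, L, max_allele=3)
        ids = G.accession_ids
        half = n // 2
        groups = ck.GroupAssignment({ids[i]: ("A" if i < half else "B") for i in range(n)})
        a, b, c = wc_oracle(G, groups)
        if a + b + c == 0:
            with pytest.raises(ValueError):
                ck.f_statistics(G, groups)
            return
        fs = ck.f_statistics(G, groups)
        assert fs.fst == pytest.approx(a / (a + b + c), abs=1e-12)
        # moment-estimator identity: (1-FIT) = (1-FIS)(1-FST)
        if not np.isnan(fs.fis):
            assert (1 - fs.fit) == pytest.approx((1 - fs.fis) * (1 - fs.fst), abs=1e-9)

    def test_pairwise_fst_restricts_to_pair(self, rice_panel):
        G, groups, _ = rice_panel
        fs = ck.f_statistics(G, groups)
        (pair, value), = fs.pairwise_fst.items()
        assert value == pytest.approx(fs.fst, abs=1e-12)  # only two groups


class TestAlleleRichness:
    @pytest.mark.parametrize(
        "subset,reference,expected",
        [(193, 229, 84.3), (196, 229, 85.6), (167, 229, 72.9), (229, 229, 100.0)],
    )
    def test_reference_ratios(self, subset, reference, expected):
        assert round(ck.allele_richness(subset, reference), 1) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ck.allele_richness(1, 0)
        with pytest.raises(ValueError):
            ck.allele_richness(5, 3)


class TestClassifyAlleles:
    def test_constructed_fixture(self):
        # allele 9 at L1 carried only by group-A accessions at freq 0.025
        calls = np.array(
            [
                [[1, 9]], [[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]],
                [[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]],
                [[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]], [[1, 1]],
                [[2, 2]], [[2, 2]], [[2, 2]], [[2, 2]], [[1, 2]],
            ]
        )
        ids = [f"s{i}" for i in range(20)]
        G = ck.GenotypeMatrix(ids, ["L1"], calls)
        groups = ck.GroupAssignment({ids[i]: ("A" if i < 15 else "B") for i in range(20)})
        cls = ck.classify_alleles(G, groups)
        assert cls.of("L1", 9) == ("rare", "exclusive")
        assert cls.exclusive_group[("L1", 9)] == "A"
        assert cls.of("L1", 1) == ("common", "shared")

    def test_boundary_goes_to_higher_class(self):
        # freq exactly 0.05 -> intermediate; exactly 0.30 -> common
        # 20 accessions = 40 copies: allele 9 x2 (0.05), allele 5 x12 (0.30)
        calls = np.concatenate(
            [
                np.array([[[1, 9]], [[1, 9]]]),
                np.tile(np.array([[5, 5]]), (6, 1, 1)),
                np.tile(np.array([[1, 1]]), (12, 1, 1)),
            ]
        )
        ids = [f"s{i}" for i in range(20)]
        G = ck.GenotypeMatrix(ids, ["L"], calls)
        groups = ck.GroupAssignment({i: "A" for i in ids})
        freqs = ck.allele_frequencies(G)
        assert freqs.frequency("L", 9) == pytest.approx(0.05)
        assert freqs.frequency("L", 5) == pytest.approx(0.30)
        cls = ck.classify_alleles(G, groups)
        assert cls.freq_class[("L", 9)] == "intermediate"
        assert cls.freq_class[("L", 5)] == "common"


class TestSubsetGDUnbiasedness:
    def test_random_subset_mean_gd_tracks_full(self, rice_panel):
        G, _, _ = rice_panel
        full = ck.diversity_summary(G).mean_gd
        rng = np.random.default_rng(7)
        means = []
        for _ in range(100):
            sub = rng.choice(G.accession_ids, size=87, replace=False)
            means.append(ck.diversity_summary(G, list(sub)).mean_gd)
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - full) < max(2 * se, 0.01)
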