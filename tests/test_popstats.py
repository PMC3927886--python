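"""Diversity statistics, Weir-Cockerham F-statistics, permutation tests."""

import itertools
import math

import numpy as np
import pytest

from coastibd import popstats
from coastibd.genotypes import GenotypeMatrix
from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracle: Weir & Cockerham (1984) per-allele variance components
# coded from the published expressions, deliberately kept separate from the
# package implementation

def wc_theta_oracle(pops_geno):
    """theta = sum(a)/sum(a+b+c) over alleles for a single locus."""
    r = len(pops_geno)
    n = [len(g) for g in pops_geno]
    nbar = sum(n) / r
    nc = (sum(n) - sum(x * x for x in n) / sum(n)) / (r - 1)
    alleles = sorted({a for g in pops_geno for pair in g for a in pair})
    num = den = 0.0
    for al in alleles:
        p = [sum(pair.count(al) for pair in g) / (2 * len(g)) for g in pops_geno]
        h = [sum(1 for pair in g if (pair.count(al) == 1)) / len(g) for g in pops_geno]
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / sum(n)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / sum(n)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        a = (nbar / nc) * (
            s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        num += a
        den += a + b + c
    return num / den


def _random_pair_instance(seed, n_loci=1):
    rng = np.random.default_rng(seed)
    pop_calls = {}
    for p in ("A", "B"):
        probs = rng.dirichlet(np.ones(3))
        inds = []
        for _ in range(10):
            geno = [tuple(rng.choice(3, size=2, p=probs) + 1) for _ in range(n_loci)]
            inds.append(geno)
        pop_calls[p] = inds
    return make_matrix(pop_calls)


class TestWcFstats:
    def test_fixation_limit(self, fixed_difference_matrix):
        res = popstats.wc_fstats(fixed_difference_matrix)
        assert res.theta == pytest.approx(1.0, abs=0.03)

    def test_panmictic_null_is_near_zero(self):
        thetas = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            p = np.array([0.5, 0.3, 0.2])
            pop_calls = {
                pop: [[tuple(rng.choice(3, size=2, p=p) + 1)] for _ in range(30)]
                for pop in ("A", "B")
            }
            thetas.append(popstats.wc_fstats(make_matrix(pop_calls)).theta)
        assert abs(np.mean(thetas)) < 0.01

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_variance_component_oracle(self, seed):
        gm = _random_pair_instance(seed)
        pops_geno = [
            [tuple(pair) for pair in gm.calls[gm.pop_indices(p), 0, :]]
            for p in gm.pop_names
        ]
        assert popstats.wc_fstats(gm).theta == pytest.approx(
            wc_theta_oracle(pops_geno), abs=1e-12)

    def test_multilocus_is_ratio_of_sums(self):
        gm = _random_pair_instance(7, n_loci=2)
        res = popstats.wc_fstats(gm)
        per = res.per_locus
        expect = per["a"].sum() / (per["a"] + per["b"] + per["c"]).sum()
        assert res.theta == pytest.approx(expect, abs=1e-14)
        mean_of_ratios = per["theta"].mean()
        assert res.theta != pytest.approx(mean_of_ratios, abs=1e-9)

    def test_invariant_to_relabeling_and_pop_order(self):
        gm = _random_pair_instance(3)
        base = popstats.wc_fstats(gm).theta
        relabeled = GenotypeMatrix(
            gm.individual_ids, gm.populations, gm.loci, 10 * gm.calls + 7)
        assert popstats.wc_fstats(relabeled).theta == pytest.approx(base, abs=1e-14)
        reordered = gm.subset_pops(["B", "A"])
        assert popstats.wc_fstats(reordered).theta == pytest.approx(base, abs=1e-14)

    def test_single_population_rejected(self):
        gm = make_matrix({"A": [[(1, 2)]] * 5})
        with pytest.raises(ValueError, match="two populations"):
            popstats.wc_fstats(gm)

    def test_all_monomorphic_flagged_undefined(self):
        gm = make_matrix({"A": [[(1, 1)]] * 5, "B": [[(1, 1)]] * 5})
        assert math.isnan(popstats.wc_fstats(gm).theta)


class TestDiversity:
    def test_monomorphic_locus(self):
        gm = make_matrix({"A": [[(3, 3)]] * 10})
        row = popstats.diversity_summary(gm).iloc[0]
        assert row["Ho"] == 0.0
        assert row["He"] == 0.0
        assert row["Ar"] == 1.0
        assert math.isnan(row["Fis_wc"])

    def test_nei_unbiased_he(self):
        # 5 individuals, alleles 1,1,1,1,1,2,2,2,2,2 -> raw 0.5, corrected 10/9*0.5
        gm = make_matrix({"A": [[(1, 2)]] * 5})
        row = popstats.diversity_summary(gm).iloc[0]
        assert row["He"] == pytest.approx(10 / 9 * 0.5)
        assert row["Ho"] == 1.0
        assert row["Fis_nei"] == pytest.approx(1 - 1.0 / (10 / 9 * 0.5))

    def test_rarefaction_matches_exhaustive_enumeration(self):
        counts = np.array([4, 3, 1])  # 8 genes, 3 alleles
        k = 4
        genes = [0] * 4 + [1] * 3 + [2]
        exact = np.mean([
            len(set(comb)) for comb in itertools.combinations(genes, k)
        ])
        assert popstats.hurlbert_rarefaction(counts, k) == pytest.approx(exact, abs=1e-12)

    def test_rarefaction_monotone_and_saturating(self):
        counts = np.array([6, 3, 2, 1])
        vals = [popstats.hurlbert_rarefaction(counts, k) for k in range(1, 13)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(4.0)

    def test_absent_cell_flagged_not_zero(self):
        gm = make_matrix({
            "A": [[(1, 2), (0, 0)]] * 4,
            "B": [[(1, 1), (3, 4)]] * 4,
        })
        df = popstats.diversity_summary(gm)
        cell = df[(df["population"] == "A") & (df["locus"] == "L2")].iloc[0]
        assert cell["n"] == 0
        assert math.isnan(cell["Ho"])


class TestPermutationInference:
    def test_g_closed_form_on_2x2(self):
        table = np.array([[10, 2], [3, 9]])
        tot = table.sum()
        e = np.outer(table.sum(1), table.sum(0)) / tot
        hand = 2 * sum(
            table[i, j] * math.log(table[i, j] / e[i, j])
            for i in range(2) for j in range(2)
        )
        assert popstats.g_statistic(table) == pytest.approx(hand, abs=1e-12)

    def test_fixed_difference_gives_smallest_p(self, fixed_difference_matrix):
        out = popstats.permutation_fst_test(
            fixed_difference_matrix, n_perm=99, seed=5)
        assert out["p_value"] == pytest.approx(1 / 100)

    def test_seeded_reproducibility(self, random_two_pop_matrix):
        a = popstats.permutation_fst_test(random_two_pop_matrix, n_perm=99, seed=11)
        b = popstats.permutation_fst_test(random_two_pop_matrix, n_perm=99, seed=11)
        assert a["p_value"] == b["p_value"]

    def test_g_statistic_route(self, fixed_difference_matrix):
        out = popstats.permutation_fst_test(
            fixed_difference_matrix, n_perm=99, statistic="G", seed=5)
        assert out["p_value"] == pytest.approx(1 / 100)


class TestHweLd:
    def test_heterozygote_excess_negative_fis(self):
        gm = make_matrix({"A": [[(1, 2)]] * 20})
        df = popstats.hwe_test(gm, n_perm=99, seed=0)
        assert df["fis"].iloc[0] < 0

    def test_duplicated_locus_extreme_ld(self):
        rng = np.random.default_rng(2)
        inds = []
        for _ in range(25):
            g = tuple(sorted(rng.integers(1, 4, size=2)))
            inds.append([g, g])  # locus 2 duplicates locus 1
        gm = make_matrix({"A": inds})
        df = popstats.ld_test(gm, n_perm=99, seed=3)
        assert df["p"].iloc[0] == pytest.approx(1 / 100)

    def test_monomorphic_locus_reported_na(self):
        gm = make_matrix({"A": [[(1, 1)]] * 10})
        df = popstats.hwe_test(gm, n_perm=99, seed=0)
        assert math.isnan(df["p"].iloc[0])


class TestBhFdr:
    def test_all_ones_none_rejected(self):
        assert not popstats.bh_fdr([1.0] * 8).any()

    def test_all_small_all_rejected(self):
        assert popstats.bh_fdr([0.001] * 10, q=0.05).all()

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(9)
        p = np.concatenate([rng.uniform(0, 0.01, 5), rng.uniform(0, 1, 20)])
        q = 0.05
        # brute-force step-up: largest k with p_(k) <= k/m * q
        order = np.argsort(p)
        m = len(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k / m * q:
                k_star = k
        expect = np.zeros(m, dtype=bool)
        expect[order[:k_star]] = True
        assert np.array_equal(popstats.bh_fdr(p, q=q), expect)
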