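import itertools
import math

import numpy as np
import pytest
from scipy import stats

from landgen import popgen
from landgen.io_formats import MISSING, PairwiseMatrix

from conftest import make_gt


# ---------------------------------------------------------------------------
# diversity / rarefaction
# ---------------------------------------------------------------------------

def brute_force_richness(gene_list, g):
    """Mean number of distinct alleles over all g-gene subsamples."""
    total, count = 0, 0
    for combo in itertools.combinations(range(len(gene_list)), g):
        total += len({gene_list[i] for i in combo})
        count += 1
    return total / count


class TestDiversity:
    def test_rarefaction_matches_exhaustive_enumeration(self):
        # allele counts {3, 1} in 2 diploids -> A_2 = 1.5
        gt = make_gt({"p": [[(1, 1)], [(1, 2)]]})
        div = popgen.diversity(gt, g=2)
        a2 = div.per_population.loc["p", "A_g"]
        assert a2 == pytest.approx(1.5)
        assert a2 == pytest.approx(brute_force_richness([1, 1, 1, 2], 2))

    @pytest.mark.parametrize("genes,g", [
        ([1, 1, 2, 3, 3, 3], 3),
        ([1, 2, 3, 4], 2),
        ([5, 5, 5, 6, 6, 7, 8, 8], 4),
    ])
    def test_rarefaction_general_oracle(self, genes, g):
        pairs = [(genes[2 * i], genes[2 * i + 1]) for i in range(len(genes) // 2)]
        gt = make_gt({"p": [[pr] for pr in pairs]})
        div = popgen.diversity(gt, g=g)
        assert div.per_population.loc["p", "A_g"] == pytest.approx(
            brute_force_richness(genes, g))

    def test_monomorphic_locus(self):
        gt = make_gt({"p": [[(7, 7)], [(7, 7)], [(7, 7)]]})
        div = popgen.diversity(gt, g=2)
        assert div.per_population.loc["p", "H_E"] == 0.0
        assert div.per_population.loc["p", "A_g"] == pytest.approx(1.0)

    def test_full_sample_rarefaction_equals_allele_count(self):
        gt = make_gt({"p": [[(1, 2), (3, 3)], [(2, 4), (3, 5)]]})
        div = popgen.diversity(gt, g=4)  # g equals full gene count per locus
        pp = div.per_population.loc["p"]
        assert pp["A_g"] == pytest.approx(pp["A"])

    def test_unbiased_he_formula(self):
        # 2 diploids, alleles {1,1,1,2}: 1 - sum p^2 = 1 - (9+1)/16 = 0.375
        gt = make_gt({"p": [[(1, 1)], [(1, 2)]]})
        div = popgen.diversity(gt, g=2)
        assert div.per_population.loc["p", "H_E"] == pytest.approx(0.375 * 4 / 3)
        assert div.per_population.loc["p", "H_O"] == pytest.approx(0.5)

    def test_richness_never_exceeds_allele_count(self):
        rng = np.random.default_rng(3)
        pops = {f"p{k}": [[(int(a), int(b)) for a, b in rng.integers(1, 8, (3, 2))]
                          for _ in range(6)] for k in range(3)}
        div = popgen.diversity(make_gt(pops), g=6)
        assert (div.per_population["A_g"] <= div.per_population["A"] + 1e-9).all()

    def test_g_too_large_raises(self):
        gt = make_gt({"p": [[(1, 2)], [(1, 3)]]})
        with pytest.raises(ValueError, match="exceeds"):
            popgen._rarefied_richness(np.array([2, 1, 1]), 5)

    def test_missing_excluded_pairwise(self):
        gt = make_gt({"p": [[(1, 2), (MISSING, MISSING)],
                            [(1, 1), (3, 4)]]})
        assert gt.n_msat()["p"] == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_enum_p(nAA, nAa, naa):
    """Full enumeration of 2-allele tables with the observed allele counts;
    probability-test p = sum of P(table) over tables with P <= P(observed)."""
    n = nAA + nAa + naa
    nA, na = 2 * nAA + nAa, 2 * naa + nAa

    def logprob(het):
        paa, pbb = (nA - het) // 2, (na - het) // 2
        return (math.lgamma(n + 1) + math.lgamma(nA + 1) + math.lgamma(na + 1)
                + het * math.log(2) - math.lgamma(2 * n + 1)
                - math.lgamma(paa + 1) - math.lgamma(het + 1) - math.lgamma(pbb + 1))

    obs = logprob(nAa)
    tot = psum = 0.0
    for het in range(nA % 2, min(nA, na) + 1, 2):
        lp = logprob(het)
        tot += math.exp(lp)
        if lp <= obs + 1e-9:
            psum += math.exp(lp)
    return psum / tot


def hwe_gt(nAA, nAa, naa):
    rows = [[(1, 1)]] * nAA + [[(1, 2)]] * nAa + [[(2, 2)]] * naa
    return make_gt({"p": rows})


class TestHWEExact:
    @pytest.mark.parametrize("counts", [(1, 8, 1), (5, 0, 5), (2, 6, 2),
                                        (3, 3, 3), (0, 6, 6), (4, 4, 1)])
    def test_chain_matches_enumeration_within_3se(self, counts):
        gt = hwe_gt(*counts)
        res = popgen.hwe_exact_test(gt, "L1", "p", batches=30,
                                    iters_per_batch=400, seed=11)
        exact = hwe_enum_p(*counts)
        tol = max(3 * res.se, 0.01)
        assert res.defined
        assert abs(res.p_value - exact) <= tol

    def test_hw_conformant_table_not_rejected(self):
        res = popgen.hwe_exact_test(hwe_gt(1, 8, 1), "L1", "p",
                                    batches=20, iters_per_batch=300, seed=2)
        assert res.p_value > 0.05

    def test_all_homozygote_table_rejected(self):
        res = popgen.hwe_exact_test(hwe_gt(5, 0, 5), "L1", "p",
                                    batches=20, iters_per_batch=300, seed=2)
        assert res.p_value < 0.05

    def test_monomorphic_flagged(self):
        gt = make_gt({"p": [[(1, 1)]] * 5})
        res = popgen.hwe_exact_test(gt, "L1", "p", seed=0)
        assert not res.defined and res.p_value is None


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

class TestLD:
    def test_perfect_association(self):
        rng = np.random.default_rng(5)
        pairs = [tuple(sorted(rng.integers(1, 4, 2))) for _ in range(20)]
        gt = make_gt({"p": [[pr, pr] for pr in pairs]})  # locus B copies A
        res = popgen.ld_test(gt, "L1", "L2", n_perm=199, seed=1)
        p = res.per_population["p"].iloc[0]
        assert p == pytest.approx(1 / 200)

    def test_permutation_matches_exact_enumeration(self):
        # 4 individuals: enumerate all 4! genotype-column permutations
        ga = [(1, 1), (1, 2), (2, 2), (1, 2)]
        gb = [(3, 3), (3, 4), (4, 4), (3, 4)]
        gt = make_gt({"p": [[a, b] for a, b in zip(ga, gb)]})
        res = popgen.ld_test(gt, "L1", "L2", n_perm=20000, seed=7)

        # oracle: G via scipy on every permutation of locus-B genotypes
        codes_a = [0, 1, 2, 1]
        codes_b = [0, 1, 2, 1]

        def g_stat(ca, cb):
            tab = np.zeros((3, 3))
            for x, y in zip(ca, cb):
                tab[x, y] += 1
            tab = tab[tab.sum(1) > 0][:, tab.sum(0) > 0]
            return stats.chi2_contingency(tab, correction=False,
                                          lambda_="log-likelihood")[0]

        g_obs = g_stat(codes_a, codes_b)
        perms = list(itertools.permutations(codes_b))
        exact = np.mean([g_stat(codes_a, pb) >= g_obs - 1e-9 for pb in perms])
        assert res.per_population["p"].iloc[0] == pytest.approx(exact, abs=0.02)

    def test_monomorphic_locus_flagged(self):
        gt = make_gt({"p": [[(1, 1), (2, 3)], [(1, 1), (3, 3)]]})
        res = popgen.ld_test(gt, "L1", "L2", n_perm=49, seed=0)
        assert not res.per_population["defined"].iloc[0]
        assert res.combined_p is None


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def anova_theta(pop_calls_per_locus):
    """Independent oracle: the nested ANOVA (mean squares) route to the same
    variance components — populations / individuals / genes."""
    num = den = 0.0
    for pop_calls in pop_calls_per_locus:
        pops = [c for c in pop_calls if len(c)]
        r = len(pops)
        alleles = np.unique(np.concatenate([c.ravel() for c in pops]))
        n_i = np.array([len(c) for c in pops], dtype=float)
        n_tot = n_i.sum()
        nc = (n_tot - (n_i ** 2).sum() / n_tot) / (r - 1)
        for al in alleles:
            x = [((c == al).sum(axis=1)) / 2.0 for c in pops]  # per-ind dosage
            p_i = np.array([xi.mean() for xi in x])
            pw = (n_i * p_i).sum() / n_tot
            h = [((c[:, 0] == al) ^ (c[:, 1] == al)).astype(float) for c in pops]
            ssg = sum(hi.sum() / 2.0 for hi in h)
            ssi = sum(2 * ((xi - pi) ** 2).sum() for xi, pi in zip(x, p_i))
            ssp = float((2 * n_i * (p_i - pw) ** 2).sum())
            msg = ssg / n_tot
            msi = ssi / (n_tot - r)
            msp = ssp / (r - 1)
            s2g = msg
            s2i = (msi - msg) / 2.0
            s2p = (msp - msi) / (2 * nc)
            num += s2p
            den += s2p + s2i + s2g
    return num / den


class TestWeirCockerham:
    def test_two_pop_toy_matches_anova_oracle(self, two_pop_toy):
        res = popgen.weir_cockerham_fst(two_pop_toy, n_perm=0, pairwise=False)
        calls1 = two_pop_toy.calls[two_pop_toy.pop_indices("pop1"), 0]
        calls2 = two_pop_toy.calls[two_pop_toy.pop_indices("pop2"), 0]
        oracle = anova_theta([[calls1, calls2]])
        assert res.theta_global == pytest.approx(oracle, abs=1e-12)
        # frozen value from the ANOVA evaluation of this printed table
        assert res.theta_global == pytest.approx(0.58730158730, abs=1e-9)

    def test_random_data_matches_anova_oracle(self):
        rng = np.random.default_rng(8)
        pops = {f"p{k}": [[(int(a), int(b)) for a, b in rng.integers(1, 5, (4, 2))]
                          for _ in range(8 + k)] for k in range(3)}
        gt = make_gt(pops)
        res = popgen.weir_cockerham_fst(gt, n_perm=0, pairwise=False)
        per_locus = []
        for li in range(gt.n_loci):
            per_locus.append([gt.calls[gt.pop_indices(p), li]
                              for p in gt.pop_names()])
        assert res.theta_global == pytest.approx(anova_theta(per_locus), abs=1e-12)

    def test_identical_samples_give_nonpositive_theta(self):
        rows = [[(1, 2)], [(1, 1)], [(2, 3)], [(3, 3)], [(1, 3)]]
        gt = make_gt({"pA": rows, "pB": rows})
        res = popgen.weir_cockerham_fst(gt, n_perm=0, pairwise=False)
        assert res.theta_global <= 0.0

    def test_fixed_differences_give_theta_one(self, fixed_demes):
        res = popgen.weir_cockerham_fst(fixed_demes, n_perm=0, pairwise=False)
        assert res.theta_global == pytest.approx(1.0)

    def test_permutation_p_significant_for_fixed_demes(self, fixed_demes):
        res = popgen.weir_cockerham_fst(fixed_demes, n_perm=99, seed=0,
                                        pairwise=False)
        assert res.theta_global_p == pytest.approx(1 / 100)

    def test_invariant_to_allele_relabeling(self, two_pop_toy):
        relabeled = make_gt({
            "pop1": [[(9, 9)]] * 5 + [[(9, 4)]] * 5,
            "pop2": [[(9, 4)]] * 2 + [[(4, 4)]] * 8,
        })
        a = popgen.weir_cockerham_fst(two_pop_toy, n_perm=0, pairwise=False)
        b = popgen.weir_cockerham_fst(relabeled, n_perm=0, pairwise=False)
        assert a.theta_global == pytest.approx(b.theta_global, abs=1e-12)


# ---------------------------------------------------------------------------
# Jost's D
# ---------------------------------------------------------------------------

class TestJostD:
    def test_fixed_demes_give_d_one(self, fixed_demes):
        res = popgen.jost_d(fixed_demes)
        assert res.d_est_global == pytest.approx(1.0, abs=1e-9)
        assert res.d_est_pairwise.values[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_identical_populations_near_zero(self):
        rows = [[(1, 2)], [(1, 1)], [(2, 3)], [(3, 3)], [(1, 3)], [(2, 2)]]
        gt = make_gt({"pA": rows, "pB": rows})
        res = popgen.jost_d(gt)
        assert res.d_est_global < 0.01  # floored nonpositive per-locus values

    def test_harmonic_mean_within_locus_range(self):
        rng = np.random.default_rng(12)
        pops = {f"p{k}": [[(int(a), int(b)) for a, b in rng.integers(1, 6, (5, 2))]
                          for _ in range(10)] for k in range(4)}
        res = popgen.jost_d(make_gt(pops))
        pos = res.per_locus["D_est"][res.per_locus["D_est"] > 0]
        if len(pos) == len(res.per_locus):
            assert pos.min() - 1e-12 <= res.d_est_global <= pos.max() + 1e-12

    def test_single_population_rejected(self):
        gt = make_gt({"p": [[(1, 2)]]})
        with pytest.raises(ValueError, match="two populations"):
            popgen.jost_d(gt)

    def test_population_order_invariance(self):
        rng = np.random.default_rng(13)
        pops = {f"p{k}": [[(int(a), int(b)) for a, b in rng.integers(1, 6, (2, 2))]
                          for _ in range(6)] for k in range(3)}
        gt = make_gt(pops)
        a = popgen.jost_d(gt, populations=["p0", "p1", "p2"])
        b = popgen.jost_d(gt, populations=["p2", "p0", "p1"])
        assert a.d_est_global == pytest.approx(b.d_est_global, abs=1e-12)
        assert a.d_est_pairwise.loc("p0", "p2") == pytest.approx(
            b.d_est_pairwise.loc("p0", "p2"), abs=1e-12)


# ---------------------------------------------------------------------------
# p-value adjustment / linearization / regression
# ---------------------------------------------------------------------------

class TestAdjustAndHelpers:
    def test_bonferroni_threshold_for_66_tests(self):
        df = popgen.adjust_pvalues([0.5] * 66, method="bonferroni", alpha=0.05)
        assert df.attrs["threshold"] == pytest.approx(0.000758, abs=1e-6)

    def test_bh_step_up_by_hand(self):
        df = popgen.adjust_pvalues([0.01, 0.02, 0.03, 0.9], method="fdr")
        assert df["rejected"].tolist() == [True, True, True, False]

    def test_all_ones_never_rejected(self):
        for method in ("fdr", "bonferroni"):
            df = popgen.adjust_pvalues([1.0] * 10, method=method)
            assert not df["rejected"].any()
            assert (df["adjusted_p"] >= df["raw_p"] - 1e-12).all()

    def test_empty_and_invalid_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            popgen.adjust_pvalues([])
        with pytest.raises(ValueError, match="0, 1"):
            popgen.adjust_pvalues([1.5])

    @pytest.mark.parametrize("x,expected", [(0.0, 0.0), (0.5, 1.0),
                                            (0.378, 0.378 / 0.622)])
    def test_linearize_values(self, x, expected):
        m = PairwiseMatrix(["a", "b"], np.array([[0, x], [x, 0]]))
        out = popgen.linearize(m)
        assert out.values[0, 1] == pytest.approx(expected)

    def test_linearize_rejects_one(self):
        m = PairwiseMatrix(["a", "b"], np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="< 1"):
            popgen.linearize(m)

    def test_linearize_clamps_negative(self):
        m = PairwiseMatrix(["a", "b"], np.array([[0, -0.02], [-0.02, 0]]))
        assert popgen.linearize(m).values[0, 1] == 0.0

    def test_regression_perfect_fit(self):
        x = np.array([100.0, 200.0, 300.0, 400.0])
        slope, intercept, r2, p = popgen.elevation_diversity_regression(
            2 * x + 5, elevation=x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(5.0)
        assert r2 == pytest.approx(1.0)

    def test_regression_constant_elevation_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            popgen.elevation_diversity_regression(
                np.array([1.0, 2.0, 3.0]), elevation=np.array([5.0, 5.0, 5.0]))
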