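"""AMOVA / Fst / Rst checks against a spreadsheet-style brute-force oracle."""

import itertools

import numpy as np
import pytest

from ystrkit.forensic import ClassSpectrum
from ystrkit.popgen import (
    DistanceMatrix,
    ZeroVarianceError,
    amova,
    pairwise_fst,
    pairwise_rst,
    size_vectors,
)
from ystrkit.simulate import (
    island_model_haplogroups,
    smm_populations,
    table_from_spectrum,
)


def amova_oracle(populations, d2):
    """Independent evaluation with explicit loops, straight from the
    variance-decomposition definitions."""
    obs = [x for pop in populations for x in pop]
    labels = [k for k, pop in enumerate(populations) for _ in pop]
    n = len(obs)
    p = len(populations)
    ssd_total = sum(d2(obs[i], obs[j]) for i in range(n) for j in range(n))
    ssd_total /= 2.0 * n
    ssd_within = 0.0
    for k, pop in enumerate(populations):
        idx = [i for i in range(n) if labels[i] == k]
        acc = sum(d2(obs[i], obs[j]) for i in idx for j in idx)
        ssd_within += acc / (2.0 * len(idx))
    ssd_among = ssd_total - ssd_within
    df_among, df_within = p - 1, n - p
    sigma_w = ssd_within / df_within
    sizes = [len(pop) for pop in populations]
    n_c = (n - sum(s * s for s in sizes) / n) / df_among
    sigma_a = (ssd_among / df_among - sigma_w) / n_c
    return ssd_among, ssd_within, sigma_a, sigma_w, sigma_a / (sigma_a + sigma_w)


def random_toy_instances(max_n=8, n_instances=12):
    rng = np.random.default_rng(99)
    for _ in range(n_instances):
        p = int(rng.integers(2, 4))
        sizes = []
        remaining = max_n
        for k in range(p):
            need_rest = 2 * (p - k - 1)
            hi = remaining - need_rest
            s = int(rng.integers(2, max(hi, 2) + 1))
            sizes.append(s)
            remaining -= s
        pops = [
            [int(rng.integers(0, 3)) for _ in range(s)] for s in sizes
        ]
        yield pops


class TestAmova:
    def test_brute_force_equivalence_small_instances(self):
        d2 = lambda a, b: 0.0 if a == b else 1.0
        for pops in random_toy_instances():
            try:
                res = amova(pops, d2)
            except ZeroVarianceError:
                continue
            bf = amova_oracle(pops, d2)
            assert np.isclose(res.ssd_among, bf[0], atol=1e-12)
            assert np.isclose(res.ssd_within, bf[1], atol=1e-12)
            assert np.isclose(res.sigma2_among, bf[2], atol=1e-12)
            assert np.isclose(res.sigma2_within, bf[3], atol=1e-12)
            assert np.isclose(res.phi_st, bf[4], atol=1e-12)
            assert np.isclose(res.ssd_total, bf[0] + bf[1], atol=1e-12)

    def test_hand_listed_toy_instance(self):
        # 3+3 individuals, squared distances by explicit evaluation
        pops = [["a", "a", "b"], ["c", "c", "c"]]
        res = amova(pops)
        bf = amova_oracle(pops, lambda a, b: 0.0 if a == b else 1.0)
        assert np.isclose(res.phi_st, bf[4], atol=1e-12)

    def test_fixed_difference_phi_is_one(self):
        res = amova([["A"] * 4, ["B"] * 4])
        assert np.isclose(res.phi_st, 1.0)

    def test_identical_monomorphic_pops_undefined(self):
        with pytest.raises(ZeroVarianceError):
            amova([["A"] * 3, ["A"] * 3])

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            amova([["A", "B"]])
        with pytest.raises(ValueError):
            amova([["A", "B"], ["C"]])

    def test_phi_invariant_to_population_order_and_relabeling(self):
        pops = [["x", "x", "y", "z"], ["y", "y", "z", "z"]]
        base = amova(pops).phi_st
        assert np.isclose(amova(pops[::-1]).phi_st, base, atol=1e-12)
        relabeled = [[{"x": "u", "y": "v", "z": "w"}[a] for a in pop]
                     for pop in pops]
        assert np.isclose(amova(relabeled).phi_st, base, atol=1e-12)

    def test_null_phi_near_zero_in_expectation(self):
        rng = np.random.default_rng(1234)
        labels = ["O", "J", "C", "Q"]
        p = [0.57, 0.18, 0.15, 0.10]
        phis = []
        for _ in range(60):
            pops = [
                list(rng.choice(labels, size=40, p=p)),
                list(rng.choice(labels, size=40, p=p)),
            ]
            phis.append(amova(pops).phi_st)
        assert abs(np.mean(phis)) < 0.03

    def test_permutation_p_counts_observed_arrangement(self):
        res = amova([["A"] * 4, ["B"] * 4], permutations=99, seed=5)
        assert res.p_value >= 1 / 100
        assert res.p_value <= 0.1  # complete differentiation: few perms beat it

    def test_permutation_seed_reproducible(self):
        pops = [["a", "a", "b", "c"], ["b", "c", "c", "c"]]
        r1 = amova(pops, permutations=200, seed=7)
        r2 = amova(pops, permutations=200, seed=7)
        assert r1.p_value == r2.p_value


class TestDistanceMatrix:
    def test_contract_enforced(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))

    def test_combined_layout(self):
        dm = DistanceMatrix(
            ["a", "b"], np.array([[0.0, 0.25], [0.25, 0.0]]),
            np.array([[0.0, 0.04], [0.04, 0.0]]),
        )
        combined = dm.combined_dataframe()
        assert combined.at["b", "a"] == 0.25   # distance below diagonal
        assert combined.at["a", "b"] == 0.04   # p-value above

    def test_bh_adjustment_monotone(self):
        vals = np.zeros((3, 3))
        ps = np.array([[0, 0.01, 0.04], [0.01, 0, 0.03],
                       [0.04, 0.03, 0]], dtype=float)
        dm = DistanceMatrix(["a", "b", "c"], vals, ps)
        adj = dm.adjusted_p_values()
        iu = np.triu_indices(3, 1)
        assert (adj[iu] >= ps[iu] - 1e-12).all()


class TestPairwiseFst:
    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(2)
        labels = list(rng.choice(["O", "C", "D", "J"], size=200))
        dm = pairwise_fst({"P1": labels[:100], "P2": labels[100:]},
                          permutations=0, seed=0)
        assert abs(dm.values[0, 1]) < 0.05

    def test_disjoint_supports_give_one(self):
        dm = pairwise_fst({"P1": ["O"] * 10, "P2": ["J"] * 10},
                          permutations=0)
        assert np.isclose(dm.values[0, 1], 1.0)

    def test_matches_direct_amova(self):
        groups = island_model_haplogroups(n_populations=3, n=30, theta=0.1,
                                          seed=8)
        dm = pairwise_fst(groups, permutations=0)
        pops = list(groups)
        for i, j in itertools.combinations(range(3), 2):
            direct = amova([groups[pops[i]], groups[pops[j]]]).phi_st
            assert np.isclose(dm.values[i, j], direct, atol=1e-12)


class TestPairwiseRst:
    def test_monomorphic_shifted_populations_give_one(self):
        t = smm_populations(2, 10, divergence_generations=0,
                            loci=["DYS391"], mutation_rate=0.0, seed=0)
        t["Pop2"].data["DYS391"] = "20"
        t["Pop1"].data["DYS391"] = "14"
        dm = pairwise_rst(t, permutations=0)
        assert np.isclose(dm.values[0, 1], 1.0)

    def test_identical_populations_near_zero(self):
        tables = smm_populations(2, 40, divergence_generations=0, seed=3)
        dm = pairwise_rst(tables, permutations=0)
        assert abs(dm.values[0, 1]) < 0.05

    def test_rst_increases_with_divergence(self):
        medians = []
        for gens in (0.0, 500.0, 5000.0):
            vals = []
            for rep in range(6):
                tabs = smm_populations(
                    2, 25, divergence_generations=gens,
                    seed=1000 + rep + int(gens),
                )
                vals.append(pairwise_rst(tabs, permutations=0).values[0, 1])
            medians.append(np.median(vals))
        assert medians[0] < medians[1] < medians[2]

    def test_null_alleles_are_missing_with_rescaling(self):
        tabs = smm_populations(2, 10, divergence_generations=100, seed=4)
        # knock out one locus call: distance rescales, stays finite
        t1 = tabs["Pop1"]
        t1.data.iloc[0, 1] = "0"
        x = size_vectors(t1, list(t1.panel.single_copy_names()))
        assert np.isnan(x[0, 0])
        dm = pairwise_rst(tabs, permutations=0)
        assert np.isfinite(dm.values[0, 1])

    def test_multicopy_locus_rejected(self):
        t = table_from_spectrum(ClassSpectrum(6, {1: 6}), "MH9", seed=1)
        with pytest.raises(ValueError, match="multi-copy"):
            size_vectors(t, ["DYS385"])
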