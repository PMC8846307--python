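import math
import statistics

import numpy as np
import pandas as pd
import pytest

from refstab.genorm import (
    genorm_ranking,
    m_values,
    normalization_factor,
    pairwise_variability,
    pairwise_variation_series,
)
from refstab.preprocess import relative_quantities

from conftest import make_cq


def brute_force_pair_sd(cq_a, cq_b):
    """Independent oracle: SD of log2 expression ratios via plain Python.

    With E = 2, log2(q_a/q_b) = (minA - a) - (minB - b)."""
    la = [min(cq_a) - v for v in cq_a]
    lb = [min(cq_b) - v for v in cq_b]
    ratios = [x - y for x, y in zip(la, lb)]
    return statistics.stdev(ratios)


class TestPairwiseVariability:
    def test_duplicated_column_has_zero_variability(self):
        cq = make_cq([[20.0, 20.0, 30.0], [21.0, 21.0, 29.0], [22.0, 22.0, 31.0]])
        rq = relative_quantities(cq)
        assert pairwise_variability(rq, "g0", "g1") == pytest.approx(0.0, abs=1e-12)

    def test_two_point_sd_is_delta_over_sqrt2(self):
        cq = make_cq([[20.0, 20.0, 25.0], [21.0, 23.0, 25.0], [22.0, 26.0, 25.0]])
        rq = relative_quantities(cq)
        # on the first two samples the log2 ratios are {0, 2}: SD = sqrt(2)
        v = pairwise_variability(rq, "g0", "g1", samples=["s0", "s1"])
        assert v == pytest.approx(math.sqrt(2))

    def test_pbmc_rps9_rps15_matches_brute_force(self, pbmc, pbmc_rq):
        oracle = brute_force_pair_sd(
            list(pbmc.data["RPS9"]), list(pbmc.data["RPS15"])
        )
        assert pairwise_variability(pbmc_rq, "RPS9", "RPS15") == pytest.approx(
            oracle, abs=1e-12
        )

    def test_same_gene_twice_is_an_error(self, pbmc_rq):
        with pytest.raises(ValueError, match="distinct"):
            pairwise_variability(pbmc_rq, "RPS9", "RPS9")


class TestMValues:
    def test_two_genes_share_their_pairwise_sd(self, pbmc_rq, pbmc):
        m = m_values(pbmc_rq, ["RPS9", "RPS15"])
        v = pairwise_variability(pbmc_rq, "RPS9", "RPS15")
        assert m["RPS9"] == pytest.approx(v) and m["RPS15"] == pytest.approx(v)

    def test_three_gene_toy_matches_hand_enumeration(self):
        cq = make_cq(
            [
                [20.0, 25.0, 18.0],
                [21.0, 25.5, 19.5],
                [22.0, 26.5, 18.5],
                [20.5, 25.0, 19.0],
            ]
        )
        rq = relative_quantities(cq)
        m = m_values(rq)
        cols = {g: list(cq.data[g]) for g in cq.gene_ids}
        for g in cq.gene_ids:
            partners = [brute_force_pair_sd(cols[g], cols[h]) for h in cols if h != g]
            assert m[g] == pytest.approx(statistics.mean(partners), abs=1e-12)

    def test_fewer_than_two_genes_rejected(self, pbmc_rq):
        with pytest.raises(ValueError):
            m_values(pbmc_rq, ["RPS9"])


class TestStepwiseRanking:
    def test_pbmc_combined_terminal_pair_and_curve(self, pbmc_rq):
        res = genorm_ranking(pbmc_rq)
        assert set(res.final_pair) == {"RPS9", "RPS15"}
        assert res.m_of["RPS9"] == pytest.approx(0.464, abs=0.005)
        # the first-excluded gene's step records the all-genes average M
        assert res.exclusion_order[0] == "HPRT1"
        assert res.m_of["HPRT1"] == pytest.approx(1.228, abs=0.005)
        # the stability curve decreases towards the terminal pair
        curve = [res.m_of[g] for g in res.exclusion_order]
        assert all(a >= b for a, b in zip(curve, curve[1:]))

    def test_pbmc_per_environment_terminal_pairs(self, pbmc, pbmc_rq):
        cold = list(pbmc.groups.index[pbmc.groups == "cold_arid"])
        hot = list(pbmc.groups.index[pbmc.groups == "hot_arid"])
        res_cold = genorm_ranking(pbmc_rq, samples=cold)
        res_hot = genorm_ranking(pbmc_rq, samples=hot)
        assert set(res_cold.final_pair) == {"RPL4", "EEF1A1"}
        assert res_cold.m_of[res_cold.final_pair[0]] == pytest.approx(0.255, abs=0.005)
        assert set(res_hot.final_pair) == {"HPRT1", "RPS9"}
        assert res_hot.m_of[res_hot.final_pair[0]] == pytest.approx(0.229, abs=0.005)

    def test_exact_duplicates_survive_to_the_terminal_pair(self):
        rng = np.random.default_rng(7)
        a = 20 + rng.normal(0, 0.5, 8)
        noisy = 25 + rng.normal(0, 2.0, 8)
        cq = make_cq(np.column_stack([a, a + 1.0, noisy]), genes=["dupA", "dupB", "noisy"])
        res = genorm_ranking(relative_quantities(cq))
        assert set(res.final_pair) == {"dupA", "dupB"}
        assert res.m_of["dupA"] == pytest.approx(0.0, abs=1e-12)

    def test_ranks_tie_policies(self, pbmc_rq):
        res = genorm_ranking(pbmc_rq)
        rmin = res.ranks("min")
        assert rmin[res.final_pair[0]] == rmin[res.final_pair[1]] == 1
        assert sorted(rmin.values()) == [1, 1, 3, 4, 5, 6, 7, 8, 9, 10]
        rcons = res.ranks("consecutive")
        assert sorted(rcons.values()) == list(range(1, 11))


class TestNormalizationFactor:
    def test_single_gene_nf_is_its_rq_column(self, pbmc_rq):
        nf = normalization_factor(pbmc_rq, ["RPS9"])
        assert np.allclose(nf, pbmc_rq.data["RPS9"])

    def test_two_gene_geometric_mean(self):
        cq = make_cq([[20.0, 22.0], [21.0, 20.0], [22.0, 21.0]])
        rq = relative_quantities(cq)
        nf = normalization_factor(rq, ["g0", "g1"])
        # sample s0: RQ = {1, 0.25} -> geometric mean 0.5
        assert nf["s0"] == pytest.approx(0.5)

    def test_log_identity_oracle_on_top3(self, pbmc_rq):
        genes = ["RPS9", "RPS15", "RPL4"]
        nf = normalization_factor(pbmc_rq, genes)
        oracle = np.exp(np.log(pbmc_rq.data[genes]).mean(axis=1))
        assert np.allclose(nf, oracle, atol=1e-12)
        assert (nf > 0).all() and len(nf) == 30

    def test_empty_gene_list_rejected(self, pbmc_rq):
        with pytest.raises(ValueError):
            normalization_factor(pbmc_rq, [])


class TestPairwiseVariation:
    def test_pbmc_printed_v_values_and_optimum(self, pbmc_rq):
        res = genorm_ranking(pbmc_rq)
        v = pairwise_variation_series(pbmc_rq, res)
        assert v.v_of[2] == pytest.approx(0.169, abs=0.005)
        assert v.v_of[3] == pytest.approx(0.116, abs=0.005)
        assert v.optimal_n == 3
        assert set(v.v_of) == set(range(2, 10))

    def test_identical_columns_give_zero_series(self):
        base = np.array([20.0, 21.5, 19.0, 22.0])
        cq = make_cq(np.column_stack([base] * 4))
        rq = relative_quantities(cq)
        res = genorm_ranking(rq)
        v = pairwise_variation_series(rq, res)
        assert all(val == pytest.approx(0.0, abs=1e-12) for val in v.v_of.values())
        assert v.optimal_n == 2

    def test_no_v_below_threshold_warns_and_reports_all_genes(self, pbmc_rq):
        res = genorm_ranking(pbmc_rq)
        with pytest.warns(UserWarning, match="optimal"):
            v = pairwise_variation_series(pbmc_rq, res, threshold=0.05)
        assert v.optimal_n == 10


class TestInvariances:
    def test_m_from_rq_equals_m_from_cq_differences(self, pbmc, pbmc_rq):
        from refstab.deltact import delta_ct_scores

        m = m_values(pbmc_rq)
        dct = delta_ct_scores(pbmc)
        assert np.allclose(m.to_numpy(), dct[m.index].to_numpy(), atol=1e-12)

    def test_sample_permutation_invariance(self, pbmc, pbmc_rq):
        order = list(pbmc.data.index[::-1])
        rq_perm = relative_quantities(pbmc.select(samples=order))
        assert np.allclose(
            m_values(pbmc_rq).to_numpy(), m_values(rq_perm).to_numpy(), atol=1e-12
        )
        res = genorm_ranking(pbmc_rq)
        v = pairwise_variation_series(pbmc_rq, res)
        v_perm = pairwise_variation_series(rq_perm, genorm_ranking(rq_perm))
        assert v_perm.v_of == pytest.approx(v.v_of, abs=1e-12)

    def test_per_sample_loading_offsets_change_nothing(self, pbmc):
        rng = np.random.default_rng(11)
        offsets = rng.normal(0, 1.0, size=len(pbmc.sample_ids))
        shifted = pbmc.data.add(pd.Series(offsets, index=pbmc.data.index), axis=0)
        rq_shift = relative_quantities(
            make_cq(shifted.to_numpy(), groups=list(pbmc.groups),
                    samples=list(shifted.index), genes=list(shifted.columns))
        )
        rq = relative_quantities(pbmc)
        assert np.allclose(
            m_values(rq).to_numpy(), m_values(rq_shift).to_numpy(), atol=1e-10
        )
        v = pairwise_variation_series(rq, genorm_ranking(rq))
        v2 = pairwise_variation_series(rq_shift, genorm_ranking(rq_shift))
        assert v2.v_of == pytest.approx(v.v_of, abs=1e-10)

    def test_inflating_noise_raises_m_in_expectation(self):
        from refstab.simulate import SimulationSpec, generate_cq

        higher = 0
        for seed in range(50):
            ms = []
            for sd in (0.2, 0.8):
                spec = SimulationSpec(
                    groups={"a": 10},
                    baseline_cq={f"g{j}": 20.0 + j for j in range(5)},
                    noise_sd={"g0": sd, **{f"g{j}": 0.2 for j in range(1, 5)}},
                    seed=seed,
                )
                cq, _ = generate_cq(spec)
                ms.append(m_values(relative_quantities(cq))["g0"])
            higher += ms[1] > ms[0]
        assert higher >= 45  # noisier gene has larger M nearly always
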