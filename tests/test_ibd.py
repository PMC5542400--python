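"""IBD transition algebra, forward algorithm and related-model fits."""

import numpy as np
import pytest

from cfdonor.ibd import (
    fit_related, forward_loglik, haploid_pair_transition, joint_transition,
    posterior_ibd, recomb_prob, stationary_distribution,
)
from cfdonor.model import FitOptions, meioses_from_pibd, pibd_from_meioses
from cfdonor.unrelated import fit_unrelated

from _oracles import forward_bruteforce


class TestTransitionAlgebra:
    def test_meioses_closed_form(self):
        assert meioses_from_pibd(0.5) == pytest.approx(2.0)
        assert meioses_from_pibd(0.25) == pytest.approx(3.0)
        with pytest.raises(ValueError):
            meioses_from_pibd(0.6)
        with pytest.raises(ValueError):
            meioses_from_pibd(0.0)
        assert pibd_from_meioses(3.0) == pytest.approx(0.25)

    def test_recomb_prob_haldane(self):
        assert recomb_prob(0.0) == 0.0
        assert recomb_prob(2.0) == pytest.approx((1 - np.exp(-0.04)) / 2, abs=1e-12)
        assert recomb_prob(2.0) == pytest.approx(0.0196053, abs=1e-7)
        assert recomb_prob(1e6) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            recomb_prob(-1.0)

    def test_no_recombination_is_identity(self):
        np.testing.assert_allclose(
            haploid_pair_transition(0.0, 3.0), np.eye(2), atol=1e-14
        )

    def test_sibling_stay_probability(self):
        # m = 2: y1 = 1, y2 = 0.98^2 + 0.02^2 = 0.9608
        T = haploid_pair_transition(0.02, 2.0)
        assert T[1, 1] == pytest.approx(0.9608, abs=1e-12)
        np.testing.assert_allclose(T.sum(axis=1), [1.0, 1.0], atol=1e-12)

    @pytest.mark.parametrize("m", [2.0, 2.5, 3.0, 5.0, 10.0, 20.0])
    @pytest.mark.parametrize("theta", [0.0, 0.01, 0.1, 0.3, 0.49])
    def test_stationary_ibd_mass_is_pibd(self, m, theta):
        """The chain's stationary IBD mass must close the loop with
        m = 1 - log2(P_IBD)."""
        T = haploid_pair_transition(theta, m)
        pi = stationary_distribution(m)
        np.testing.assert_allclose(pi @ T, pi, atol=1e-10)
        assert pi[1] == pytest.approx(2.0 ** (1.0 - m), abs=1e-12)

    def test_joint_transition_structure(self, rng):
        assert np.array_equal(joint_transition(np.eye(2), np.eye(2)), np.eye(4))
        for _ in range(5):
            t1 = haploid_pair_transition(rng.uniform(0, 0.49), rng.uniform(2, 10))
            t2 = haploid_pair_transition(rng.uniform(0, 0.49), rng.uniform(2, 10))
            J = joint_transition(t1, t2)
            np.testing.assert_allclose(J.sum(axis=1), np.ones(4), atol=1e-12)
            # marginalizing pair II recovers t1
            marg = J.reshape(2, 2, 2, 2).sum(axis=3)[:, 0, :]
            np.testing.assert_allclose(marg, t1, atol=1e-12)


class TestForward:
    def _three_block_partition(self, tiny_map):
        from cfdonor.blocks import build_blocks
        from conftest import make_snps

        snps = make_snps([1, 2_500_000, 5_000_000])
        return build_blocks(tiny_map, snps, target_cm=2.0)

    def test_single_block_closed_form(self, tiny_map):
        from cfdonor.blocks import build_blocks
        from conftest import make_snps

        part = build_blocks(tiny_map, make_snps([1]), target_cm=2.0)
        logE = np.array([[-1.0, -2.0, -3.0]])
        m1, m2 = 2.0, 3.0
        got = forward_loglik(part, logE, m1=m1, m2=m2)
        pi = np.kron(stationary_distribution(m1), stationary_distribution(m2))
        want = np.log(np.sum(pi * np.exp(logE[0][[0, 1, 1, 2]])))
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_path_enumeration(self, tiny_map, rng):
        part = self._three_block_partition(tiny_map)
        assert part.n_blocks == 3
        (_, l_cm), = part.chrom_chains()
        for _ in range(5):
            logE3 = rng.normal(-5, 2, size=(3, 3))
            m1, m2 = rng.uniform(2, 8), rng.uniform(2, 8)
            got = forward_loglik(part, logE3, m1=m1, m2=m2)
            pi = np.kron(stationary_distribution(m1), stationary_distribution(m2))
            Ts = [
                joint_transition(
                    haploid_pair_transition(recomb_prob(l), m1),
                    haploid_pair_transition(recomb_prob(l), m2),
                )
                for l in l_cm
            ]
            want = forward_bruteforce(pi, Ts, logE3[:, [0, 1, 1, 2]])
            assert got == pytest.approx(want, abs=1e-10)

    def test_constant_emissions_cancel_path_structure(self, toy_blocks):
        _, part = toy_blocks
        logE = np.full((part.n_blocks, 3), -4.2)
        got = forward_loglik(part, logE, p_ibd_1=0.25, p_ibd_2=0.125)
        assert got == pytest.approx(-4.2 * part.n_blocks, abs=1e-9)

    def test_unrelated_limit_matches_genome_loglik(self):
        from cfdonor.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_snps=1000, n_chrom=2, total_cm=100, d_true=0.05, coverage=2.0, seed=5
        )
        ds = simulate_dataset(cfg)
        ws = ds.workspace(0)
        d, e_s, e_g = 0.04, 1e-3, 1e-4
        block_ll = ws.block_logliks(d, e_s, e_g)
        ll_hmm = forward_loglik(ds.blocks, block_ll, p_ibd_1=1e-9, p_ibd_2=1e-9)
        ll_unrel = ws.loglik_unrelated(d, e_s, e_g)
        assert ll_hmm == pytest.approx(ll_unrel, abs=1e-3)


class TestPosterior:
    def test_uniform_emissions_give_stationary(self, toy_blocks):
        _, part = toy_blocks
        logE = np.zeros((part.n_blocks, 3))
        post = posterior_ibd(part, logE, p_ibd_1=0.5, p_ibd_2=0.25)
        pi = np.kron(stationary_distribution(2.0), stationary_distribution(3.0))
        want = np.array([pi[0], pi[1] + pi[2], pi[3]])
        np.testing.assert_allclose(post, np.tile(want, (part.n_blocks, 1)), atol=1e-9)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)

    def test_informative_block_is_decoded(self, toy_blocks):
        _, part = toy_blocks
        logE = np.zeros((part.n_blocks, 3))
        logE[3] = [-50.0, -25.0, 0.0]  # strong IBD-2 evidence in one block
        post = posterior_ibd(part, logE, p_ibd_1=0.5, p_ibd_2=0.5)
        assert post[3, 2] > 0.9


class TestFitRelated:
    def test_sibling_recovery(self, small_sibling_sim):
        ds = small_sibling_sim
        fit = fit_related(
            None, None, None, blocks=ds.blocks,
            workspaces={"pop1": ds.workspace(0)}, options=FitOptions(init="grid"),
        )
        assert fit.mode == "related"
        assert fit.d_hat == pytest.approx(0.10, abs=0.01)
        assert fit.p_ibd_1_hat > 0.3 and fit.p_ibd_2_hat > 0.3
        assert fit.p_ibd_1_hat >= fit.p_ibd_2_hat  # canonical order

    def test_matches_unrelated_fit_on_unrelated_data(self, small_unrelated_sim):
        ds = small_unrelated_sim
        ws = {"pop1": ds.workspace(0)}
        rel = fit_related(
            None, None, None, blocks=ds.blocks, workspaces=ws,
            options=FitOptions(init="grid"),
        )
        unrel = fit_unrelated(None, None, None, workspaces=ws, options=FitOptions(init="grid"))
        assert rel.d_hat == pytest.approx(unrel.d_hat, abs=0.002)

    def test_forward_prefers_true_relatedness(self, small_sibling_sim):
        """At the generating d, the forward likelihood under the true
        sibling relatedness exceeds the unrelated-limit likelihood."""
        ds = small_sibling_sim
        ws = ds.workspace(0)
        block_ll = ws.block_logliks(ds.config.d_true, 1e-3, 1e-4)
        ll_sib = forward_loglik(ds.blocks, block_ll, p_ibd_1=0.5, p_ibd_2=0.5)
        ll_unrel = forward_loglik(ds.blocks, block_ll, p_ibd_1=1e-6, p_ibd_2=1e-6)
        assert ll_sib > ll_unrel

    def test_unrelated_model_underestimates_siblings(self, small_sibling_sim):
        """Ignoring IBD hides the donor reads inside shared segments: the
        naive fit recovers roughly half the true fraction."""
        ds = small_sibling_sim
        unrel = fit_unrelated(
            None, None, None, workspaces={"pop1": ds.workspace(0)},
            options=FitOptions(init="grid"),
        )
        assert unrel.d_hat < 0.8 * ds.config.d_true
        assert unrel.d_hat > 0.2 * ds.config.d_true
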