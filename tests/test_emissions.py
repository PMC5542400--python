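"""Per-SNP probability kernels against printed formulas and brute force."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cfdonor.emissions as em
from cfdonor.emissions import (
    donor_prior_arrays, donor_prior_given_ibd, donor_prior_unrelated,
    genotype_emission_prob, mixture_allele_prob, per_snp_loglik,
    sequencing_emission_prob, snp_loglik, zero_coverage_loglik,
)
from cfdonor.model import ModelParams

from _oracles import snp_lik_bruteforce

OBS = ("AA", "AB", "BB")
ORDERED = ("AA", "AB", "BA", "BB")


class TestGenotypeEmission:
    @pytest.mark.parametrize("e_g", [1e-9, 1e-6, 1e-4, 1e-3])
    def test_printed_kernel(self, e_g):
        assert genotype_emission_prob("AA", "AA", e_g) == pytest.approx((1 - e_g) ** 2)
        assert genotype_emission_prob("AA", "AB", e_g) == pytest.approx(2 * e_g * (1 - e_g))
        assert genotype_emission_prob("AA", "BB", e_g) == pytest.approx(e_g**2)
        # allele-mirrored kernel for observed BB
        assert genotype_emission_prob("BB", "BB", e_g) == pytest.approx((1 - e_g) ** 2)
        assert genotype_emission_prob("BB", "BA", e_g) == pytest.approx(2 * e_g * (1 - e_g))

    @pytest.mark.parametrize("true", ORDERED)
    def test_normalizes_over_observations(self, true):
        total = sum(genotype_emission_prob(o, true, 7e-4) for o in OBS)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_ordered_pair_symmetry(self):
        for o in OBS:
            assert genotype_emission_prob(o, "AB", 1e-3) == pytest.approx(
                genotype_emission_prob(o, "BA", 1e-3)
            )


class TestSequencingEmission:
    def test_printed_kernel(self):
        assert sequencing_emission_prob("A", "A", 0.001) == pytest.approx(0.999)
        assert sequencing_emission_prob("A", "B", 0.001) == pytest.approx(0.001)
        assert sum(sequencing_emission_prob(o, "B", 0.01) for o in "AB") == 1.0


class TestDonorPriors:
    def test_hardy_weinberg_table(self):
        p = donor_prior_unrelated(0.5)
        assert p["AA"] == pytest.approx(0.25)
        assert p["AB"] + p["BA"] == pytest.approx(0.5)
        assert p["BB"] == pytest.approx(0.25)

    @given(st.floats(1e-4, 1 - 1e-4))
    @settings(max_examples=50, deadline=None)
    def test_priors_normalize_for_all_frequencies(self, f_a):
        for ibd in (0, 1, 2):
            for r in ORDERED:
                total = sum(donor_prior_given_ibd(r, ibd, f_a).values())
                assert total == pytest.approx(1.0, abs=1e-12)

    def test_single_ibd_conditional_rows(self):
        f_a = 0.3
        p = donor_prior_given_ibd("AA", 1, f_a)
        assert p["AA"] == pytest.approx(f_a)
        assert p["AB"] + p["BA"] == pytest.approx(1 - f_a)
        assert p["BB"] == 0.0
        p = donor_prior_given_ibd("AB", 1, f_a)
        assert p["AA"] == pytest.approx(0.5 * f_a)
        # the shared-haploid middle mass is exactly 1/2 for every frequency
        assert p["AB"] + p["BA"] == pytest.approx(0.5)
        assert p["BB"] == pytest.approx(0.5 * (1 - f_a))

    def test_double_ibd_copies_recipient(self):
        assert donor_prior_given_ibd("BB", 2, 0.7)["BB"] == 1.0
        p = donor_prior_given_ibd("BA", 2, 0.7)
        assert p["AB"] + p["BA"] == pytest.approx(1.0)

    def test_ibd0_matches_unconditional(self):
        assert donor_prior_given_ibd("AB", 0, 0.42) == donor_prior_unrelated(0.42)


class TestMixtureProb:
    def test_examples(self):
        assert mixture_allele_prob("AA", "BB", 0.1) == pytest.approx(0.9)
        assert mixture_allele_prob("AA", "BB", 0.0) == pytest.approx(1.0)
        assert mixture_allele_prob("AB", "AB", 0.77) == pytest.approx(0.5)

    def test_linear_in_d(self):
        lo, hi = mixture_allele_prob("AA", "AB", 0.0), mixture_allele_prob("AA", "AB", 1.0)
        mid = mixture_allele_prob("AA", "AB", 0.25)
        assert mid == pytest.approx(lo + 0.25 * (hi - lo))


class TestSnpLoglik:
    def test_matches_bruteforce_enumeration(self, rng):
        """Exhaustive enumeration over genotypes and per-read alleles, K <= 3."""
        for _ in range(120):
            obs = OBS[rng.integers(0, 3)]
            reads = "".join(rng.choice(["A", "B"], size=rng.integers(0, 4)))
            d = float(rng.random())
            e_s = float(10 ** rng.uniform(-9, -2))
            e_g = float(10 ** rng.uniform(-9, -3))
            f_a = float(rng.uniform(1e-4, 1 - 1e-4))
            ibd = [None, 0, 1, 2][rng.integers(0, 4)]
            got = snp_loglik(
                obs, reads.count("A"), reads.count("B"),
                ModelParams(d=d, e_s=e_s, e_g=e_g), f_a, ibd_count=ibd,
            )
            want = np.log(snp_lik_bruteforce(obs, reads, d, e_s, e_g, f_a, ibd))
            assert got == pytest.approx(want, abs=1e-10)

    def test_hw_recipient_prior_matches_bruteforce(self, rng):
        """The Hardy-Weinberg recipient-prior variant agrees with its own
        exhaustive enumeration (prior masses f_{r1} f_{r2})."""
        from cfdonor.emissions import donor_prior_arrays, per_snp_loglik

        n = 60
        obs = rng.integers(0, 3, n)
        ka = rng.poisson(1.5, n)
        kb = rng.poisson(1.0, n)
        f_a = rng.uniform(1e-3, 1 - 1e-3, n)
        d, e_s, e_g = 0.08, 2e-3, 2e-4
        dp = donor_prior_arrays(f_a)
        out = per_snp_loglik(
            obs, ka, kb, f_a, d, e_s, e_g, states=(0, 1, 2),
            dp=dp, recipient_weights=dp[0],
        )
        for i in rng.choice(n, 15, replace=False):
            reads = "A" * int(ka[i]) + "B" * int(kb[i])
            for s in (0, 1, 2):
                want = np.log(
                    snp_lik_bruteforce(
                        OBS[obs[i]], reads, d, e_s, e_g, f_a[i], ibd=s,
                        recipient_prior="hw",
                    )
                )
                assert out[s, i] == pytest.approx(want, abs=1e-10)

    def test_zero_reads_reduce_to_genotype_marginal(self):
        ll = snp_loglik("AB", 0, 0, ModelParams(d=0.3), 0.4)
        marg = sum(
            0.25 * genotype_emission_prob("AB", r, 1e-4) for r in ORDERED
        )
        assert ll == pytest.approx(np.log(marg), abs=1e-12)

    def test_allele_relabeling_invariance(self, rng):
        """A<->B relabeling (flip f, swap counts, mirror genotype) is a
        symmetry of the likelihood."""
        mirror = {"AA": "BB", "AB": "AB", "BB": "AA"}
        for _ in range(20):
            obs = OBS[rng.integers(0, 3)]
            ka, kb = int(rng.integers(0, 5)), int(rng.integers(0, 5))
            f_a = float(rng.uniform(0.05, 0.95))
            p = ModelParams(d=float(rng.random()), e_s=1e-3, e_g=1e-4)
            for ibd in (None, 0, 1, 2):
                a = snp_loglik(obs, ka, kb, p, f_a, ibd_count=ibd)
                b = snp_loglik(mirror[obs], kb, ka, p, 1 - f_a, ibd_count=ibd)
                assert a == pytest.approx(b, abs=1e-10)

    def test_grid_scan_peaks_at_matching_fraction(self):
        """Homozygous recipient, donor-allele frequency ~1: the likelihood in
        d should peak near the observed B-read fraction."""
        p_base = dict(e_s=1e-9, e_g=1e-9)
        grid = np.linspace(0.01, 0.4, 200)
        lls = [
            snp_loglik("AA", 90, 10, ModelParams(d=d, **p_base), 1e-4, ibd_count=None)
            for d in grid
        ]
        d_best = grid[int(np.argmax(lls))]
        # recipient AA, f_a ~ 0 means the donor is almost surely BB: expected
        # B fraction = d, observed 10/100
        assert d_best == pytest.approx(0.10, abs=0.01)

    def test_absent_allele_reads_cost_log_es(self):
        p = ModelParams(d=0.0, e_s=1e-9, e_g=1e-9)
        lls = [snp_loglik("AA", 5, k, p, 0.5) for k in range(4)]
        diffs = np.diff(lls)
        assert (diffs < 0).all()
        assert diffs[0] == pytest.approx(np.log(1e-9), rel=0.05)


class TestVectorizedDriver:
    def test_matches_scalar_reference(self, rng):
        n = 300
        obs = rng.integers(0, 3, n)
        ka = rng.poisson(1.5, n)
        kb = rng.poisson(1.0, n)
        f_a = rng.uniform(1e-4, 1 - 1e-4, n)
        d, e_s, e_g = 0.07, 3e-4, 5e-5
        out = per_snp_loglik(obs, ka, kb, f_a, d, e_s, e_g, states=(0, 1, 2))
        params = ModelParams(d=d, e_s=e_s, e_g=e_g)
        for i in rng.choice(n, 40, replace=False):
            for s in (0, 1, 2):
                want = snp_loglik(
                    OBS[obs[i]], int(ka[i]), int(kb[i]), params, f_a[i], ibd_count=s
                )
                assert out[s, i] == pytest.approx(want, abs=1e-9)

    def test_compiled_and_numpy_paths_agree(self, rng):
        if em._NUMBA_KERNEL is None:
            pytest.skip("compiled kernel unavailable")
        n = 500
        obs = rng.integers(0, 3, n)
        ka = rng.poisson(2.0, n)
        kb = rng.poisson(1.0, n)
        f_a = rng.uniform(1e-4, 1 - 1e-4, n)
        args = (obs, ka, kb, f_a, 0.02, 1e-3, 1e-4)
        fast = per_snp_loglik(*args, states=(0, 1, 2))
        saved = em._NUMBA_KERNEL
        try:
            em._NUMBA_KERNEL = None
            slow = per_snp_loglik(*args, states=(0, 1, 2))
        finally:
            em._NUMBA_KERNEL = saved
        np.testing.assert_allclose(fast, slow, atol=1e-12)

    def test_zero_coverage_term(self):
        counts = np.array([10, 5, 7])
        got = zero_coverage_loglik(counts, 2e-4)
        want = sum(
            n * snp_loglik(o, 0, 0, ModelParams(d=0.1, e_g=2e-4), 0.3)
            for n, o in zip(counts, OBS)
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_donor_prior_arrays_columns(self):
        f = np.array([0.2, 0.5])
        dp0, dp1 = donor_prior_arrays(f)
        assert dp0[:, 0] == pytest.approx([0.04, 0.32, 0.64])
        assert dp1[0, :, 0] == pytest.approx([0.2, 0.8, 0.0])
        assert dp1[1, :, 1] == pytest.approx([0.25, 0.5, 0.25])
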