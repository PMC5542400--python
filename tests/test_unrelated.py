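"""Genome-wide likelihood and the unrelated-donor maximum-likelihood fit."""

import numpy as np
import pandas as pd
import pytest

from cfdonor.likelihood import Workspace
from cfdonor.model import FitOptions, ModelParams
from cfdonor.simulate import SimulationConfig, simulate_dataset
from cfdonor.unrelated import fit_unrelated, genome_loglik

from _oracles import snp_lik_bruteforce


def _tables(rows):
    """rows: (chrom, pos, genotype, count_a, count_b, f_a)."""
    base = pd.DataFrame(
        [r[:2] for r in rows], columns=["chrom", "pos"]
    ).assign(allele_a="A", allele_b="B")
    geno = base.assign(genotype=[r[2] for r in rows])
    counts = base.assign(count_a=[r[3] for r in rows], count_b=[r[4] for r in rows])
    freqs = base.assign(pop1=[r[5] for r in rows])
    return geno, counts, freqs


class TestGenomeLoglik:
    ROWS = [
        ("chr1", 100, "AA", 2, 1, 0.3),
        ("chr1", 200, "AB", 1, 2, 0.7),
        ("chr1", 300, "BB", 0, 3, 0.5),
        ("chr2", 100, "AA", 3, 0, 0.9),
        ("chr2", 200, "AB", 0, 0, 0.2),
    ]

    def test_additivity_and_permutation_invariance(self):
        params = ModelParams(d=0.12, e_s=2e-3, e_g=3e-4, pop="pop1")
        full = genome_loglik(*_tables(self.ROWS), params, conditional=False,
                             recipient_prior="uniform")
        parts = [
            genome_loglik(*_tables([r]), params, conditional=False,
                          recipient_prior="uniform") for r in self.ROWS
        ]
        assert full == pytest.approx(sum(parts), abs=1e-9)
        shuffled = genome_loglik(
            *_tables([self.ROWS[i] for i in (3, 0, 4, 1, 2)]),
            params,
            conditional=False,
            recipient_prior="uniform",
        )
        assert full == pytest.approx(shuffled, abs=1e-9)

    def test_matches_bruteforce_sum(self):
        params = ModelParams(d=0.12, e_s=2e-3, e_g=3e-4, pop="pop1")
        got = genome_loglik(*_tables(self.ROWS), params, conditional=False,
                            recipient_prior="uniform")
        want = sum(
            np.log(
                snp_lik_bruteforce(
                    g, "A" * ka + "B" * kb, params.d, params.e_s, params.e_g, fa
                )
            )
            for _, _, g, ka, kb, fa in self.ROWS
        )
        assert got == pytest.approx(want, abs=1e-9)

    def test_conditional_differs_by_genotype_marginal(self):
        params = ModelParams(d=0.12, pop="pop1")
        joint = genome_loglik(*_tables(self.ROWS), params, conditional=False,
                              recipient_prior="uniform")
        cond = genome_loglik(*_tables(self.ROWS), params, conditional=True,
                             recipient_prior="uniform")
        marg = sum(
            np.log(snp_lik_bruteforce(g, "", 0.0, params.e_s, params.e_g, fa))
            for _, _, g, _, _, fa in self.ROWS
        )
        assert joint - cond == pytest.approx(marg, abs=1e-9)

    def test_empty_workspace_errors(self):
        geno, counts, freqs = _tables([("chr1", 100, ".", 1, 1, 0.5)])
        geno["genotype"] = None
        ws = Workspace.from_tables(geno, counts, freqs, "pop1")
        with pytest.raises(ValueError, match="no usable SNPs"):
            ws.loglik_unrelated(0.1, 1e-3, 1e-4)
        assert ws.n_missing_genotype == 1


class TestFitUnrelated:
    def test_parameter_recovery(self):
        """Median recovery error at 50K SNPs / 1x coverage stays within
        +-0.005 of the simulated d = 0.05 (median over replicates, since a
        single draw's error is a nontrivial fraction of the tolerance)."""
        errs = []
        for seed in (4321, 4322, 4323):
            cfg = SimulationConfig(n_snps=50_000, d_true=0.05, coverage=1.0, seed=seed)
            ds = simulate_dataset(cfg)
            fit = fit_unrelated(
                None, None, None, workspaces={"pop1": ds.workspace(0)},
                options=FitOptions(init="grid"),
            )
            assert fit.converged
            errs.append(abs(fit.d_hat - 0.05))
        assert np.median(errs) <= 0.005

    def test_zero_fraction_boundary(self):
        cfg = SimulationConfig(n_snps=50_000, d_true=0.0, coverage=1.0, seed=99)
        ds = simulate_dataset(cfg)
        fit = fit_unrelated(
            None, None, None, workspaces={"pop1": ds.workspace(0)},
            options=FitOptions(init="grid"),
        )
        assert fit.d_hat <= 0.002

    def test_population_selection(self):
        cfg = SimulationConfig(
            n_snps=20_000, d_true=0.08, coverage=2.0, n_pops=2,
            divergence=0.3, seed=17,
        )
        ds = simulate_dataset(cfg)
        fit = fit_unrelated(
            None, None, None,
            workspaces={name: ds.workspace(j) for j, name in enumerate(ds.pop_names)},
            options=FitOptions(init="grid"),
        )
        # data were generated from pop1; pop2 frequencies are heavily jittered
        assert fit.pop_hat == "pop1"

    def test_allele_relabeling_leaves_d_invariant(self):
        cfg = SimulationConfig(n_snps=20_000, d_true=0.06, coverage=1.5, seed=23)
        ds = simulate_dataset(cfg)
        ws = ds.workspace(0)
        flipped = Workspace.from_arrays(
            (2 - ws.obs).astype(np.int8), ws.count_b, ws.count_a, 1.0 - ws.f_a
        )
        opt = FitOptions(init="grid")
        a = fit_unrelated(None, None, None, workspaces={"p": ws}, options=opt)
        b = fit_unrelated(None, None, None, workspaces={"p": flipped}, options=opt)
        # the likelihood is exactly symmetric; the optimizer path may
        # differ at floating-point level
        assert a.d_hat == pytest.approx(b.d_hat, abs=1e-4)

    def test_likelihood_peaks_at_generating_parameters(self):
        """Averaged over replicates, the genome log-likelihood at the
        generating parameters beats perturbed parameter points."""
        deltas_up, deltas_down = [], []
        for seed in range(6):
            cfg = SimulationConfig(n_snps=8_000, d_true=0.08, coverage=2.0, seed=seed)
            ws = simulate_dataset(cfg).workspace(0)
            ll = ws.loglik_unrelated(0.08, 1e-3, 1e-4)
            deltas_up.append(ll - ws.loglik_unrelated(0.11, 1e-3, 1e-4))
            deltas_down.append(ll - ws.loglik_unrelated(0.05, 1e-3, 1e-4))
        assert np.mean(deltas_up) > 0
        assert np.mean(deltas_down) > 0

    def test_accuracy_improves_with_reads(self):
        """Median |d_hat - d| does not grow when coverage and SNP count
        increase (small paired grid)."""
        def median_err(n_snps, coverage):
            errs = []
            for seed in (5, 6, 7):
                cfg = SimulationConfig(
                    n_snps=n_snps, d_true=0.06, coverage=coverage, seed=seed
                )
                ds = simulate_dataset(cfg)
                fit = fit_unrelated(
                    None, None, None, workspaces={"pop1": ds.workspace(0)},
                    options=FitOptions(init="grid"),
                )
                errs.append(abs(fit.d_hat - 0.06))
            return np.median(errs)

        assert median_err(40_000, 2.0) <= median_err(10_000, 0.5)

    def test_parent_child_doubling_flag(self, small_unrelated_sim):
        ds = small_unrelated_sim
        fit = fit_unrelated(
            None, None, None, workspaces={"pop1": ds.workspace(0)},
            options=FitOptions(init="grid"), double_for_parent_child=True,
        )
        assert fit.metadata["d_hat_parent_child"] == pytest.approx(2 * fit.d_hat)
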