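"""Estimate the donor fraction of cfDNA without a donor genotype.

Simulates a heart-transplant-like sample — an unrelated donor, 100K
genotyped SNPs, 1.5x cfDNA coverage, 4% donor-derived cfDNA — and
re-estimates the fraction by maximum likelihood from the recipient
genotype, the per-SNP allele counts and the population allele frequencies
alone.
"""

from cfdonor import FitOptions, SimulationConfig, fit_unrelated, simulate_dataset

cfg = SimulationConfig(n_snps=100_000, d_true=0.04, coverage=1.5, seed=11)
ds = simulate_dataset(cfg)

fit = fit_unrelated(
    ds.genotype_table(),       # recipient genotype (with array-style error)
    ds.counts_table(),         # cfDNA allele counts per SNP
    ds.freq_table(),           # population allele frequencies
    options=FitOptions(init="grid"),
)

print(f"simulated dd-cfDNA fraction : {cfg.d_true:.4f}")
print(f"realized donor-read fraction: {ds.realized_donor_fraction():.4f}")
print(f"estimated dd-cfDNA fraction : {fit.d_hat:.4f}")
print(f"fitted error rates          : e_s={fit.e_s_hat:.2e}, e_g={fit.e_g_hat:.2e}")
print(f"SNPs in the likelihood      : {fit.n_snps_used}")
print()
print("The estimate should sit within a few hundredths of a percent of the")
print("simulated fraction; the sequencing-error rate absorbs the 1e-3")
print("per-read noise injected by the simulator.")
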