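"""Sibling donors: why identity-by-descent must be modeled.

Simulates a bone-marrow-transplant-like sample whose donor is a sibling of
the recipient (both haploid pairs IBD with probability 0.5). Fitting the
naive unrelated model underestimates the donor fraction roughly two-fold —
donor molecules falling in shared segments are indistinguishable from
recipient ones — while the IBD-aware hidden Markov model recovers both the
fraction and the relatedness.
"""

from cfdonor import FitOptions, SimulationConfig, fit_related, fit_unrelated, simulate_dataset

cfg = SimulationConfig(
    n_snps=100_000, d_true=0.60, coverage=1.5,
    p_ibd_1=0.5, p_ibd_2=0.5,    # sibling: each haploid pair IBD half the genome
    seed=22,
)
ds = simulate_dataset(cfg)
ws = {"pop1": ds.workspace(0)}
opts = FitOptions(init="grid")

naive = fit_unrelated(None, None, None, workspaces=ws, options=opts)
aware = fit_related(None, None, None, blocks=ds.blocks, workspaces=ws, options=opts)

print(f"simulated dd-cfDNA fraction      : {cfg.d_true:.3f}")
print(f"unrelated-model estimate (naive) : {naive.d_hat:.3f}")
print(f"IBD-aware estimate               : {aware.d_hat:.3f}")
print(f"estimated IBD probabilities      : {aware.p_ibd_1_hat:.3f}, {aware.p_ibd_2_hat:.3f}")
print()
print("The naive estimate lands near half the truth (donor reads hidden in")
print("IBD segments are attributed to the recipient); the HMM estimate is")
print("close to the simulated fraction with both pair-IBD probabilities")
print("near the sibling value of 0.5.")
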