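"""Generative simulator for synthetic transplant cfDNA benchmarks.

The simulator emulates the four model inputs end to end: population allele
frequencies, a recipient genotyped with array-style error, a donor that is
either a random population draw or IBD-related to the recipient through the
same block-wise HMM used for inference, and cfDNA allele counts obtained by
mixing donor- and recipient-origin fragments at the target dd-cfDNA
fraction and coverage with per-read sequencing error. It also provides the
benchmark down-sampling steps: top-K SNPs per genetic block by alternative
allele frequency, binomial read thinning to a lower coverage, and the
pre-fit filter that discards homozygous SNPs whose own reads contradict the
genotype (clear genotyping errors).

The simulator draws from the model's own generative assumptions (the
original benchmark mixed real pre-transplant sequencing reads); this makes
parameter recovery a well-posed oracle and requires no external data. Reads
are simulated at the allele-count level the estimator consumes — no
FASTQ/BAM synthesis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import BlockPartition, build_blocks
from .emissions import genotype_emission_matrix
from .likelihood import Workspace
from .model import E_G_MAX, E_G_MIN, E_S_MAX, E_S_MIN, P_IBD_MAX, meioses_from_pibd
from .ibd import _stay_enter, recomb_prob, stationary_distribution

_CLASS_STR = np.array(["AA", "AB", "BB"])


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic benchmark replicate.

    Defaults mirror the full-scale benchmark design: ~600K genotyped SNPs
    over 22 autosomes (~3500 cM at a uniform 1 cM/Mb), mean cfDNA coverage
    1.75x, sequencing error 1e-3, genotyping error 1e-4, allele frequencies
    uniform on [0.05, 0.95], and 2 cM transition blocks. ``p_ibd_1/2 = 0``
    simulates an unrelated donor; 0.5/0.5 a sibling.
    """

    n_snps: int = 600_000
    d_true: float = 0.01
    coverage: float = 1.75
    e_s_true: float = 1e-3
    e_g_true: float = 1e-4
    p_ibd_1: float = 0.0
    p_ibd_2: float = 0.0
    n_pops: int = 1
    freq_low: float = 0.05
    freq_high: float = 0.95
    divergence: float = 0.0
    n_chrom: int = 22
    total_cm: float = 3500.0
    cm_per_mb: float = 1.0
    block_cm: float = 2.0
    top_k: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise ValueError("n_snps must be positive")
        if not (0.0 <= self.d_true <= 1.0):
            raise ValueError("d_true must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not (E_S_MIN <= self.e_s_true <= E_S_MAX):
            raise ValueError("e_s_true outside model bounds")
        if not (E_G_MIN <= self.e_g_true <= E_G_MAX):
            raise ValueError("e_g_true outside model bounds")
        for p in (self.p_ibd_1, self.p_ibd_2):
            if not (0.0 <= p <= P_IBD_MAX):
                raise ValueError("p_ibd must be in [0, 0.5] (0 = unrelated)")


@dataclass
class SimulatedDataset:
    """A simulated benchmark replicate with full ground truth."""

    config: SimulationConfig
    snps: pd.DataFrame                   # chrom, pos, allele_a, allele_b
    map_df: pd.DataFrame                 # chrom, pos, cm
    blocks: BlockPartition
    freqs: np.ndarray                    # (N, n_pops) allele-A frequency
    pop_names: list[str]
    recipient_true: np.ndarray           # (N,) class 0/1/2
    recipient_obs: np.ndarray            # (N,) class 0/1/2
    donor_true: np.ndarray               # (N,) class 0/1/2
    ibd_block_count: np.ndarray          # (n_blocks,) true IBD count per block
    count_a: np.ndarray
    count_b: np.ndarray
    n_donor_reads: np.ndarray            # (N,) fragment-origin tally
    keep: np.ndarray = field(default=None)  # boolean SNP mask after filters

    def __post_init__(self) -> None:
        if self.keep is None:
            self.keep = np.ones(len(self.snps), dtype=bool)

    # -- table views --------------------------------------------------------

    def genotype_table(self, which: str = "recipient_obs") -> pd.DataFrame:
        cls = getattr(self, which)
        out = self.snps.copy()
        out["genotype"] = _CLASS_STR[cls]
        return out

    def counts_table(self) -> pd.DataFrame:
        out = self.snps.copy()
        out["count_a"] = self.count_a
        out["count_b"] = self.count_b
        return out

    def freq_table(self) -> pd.DataFrame:
        out = self.snps.copy()
        for j, name in enumerate(self.pop_names):
            out[name] = self.freqs[:, j]
        return out

    def workspace(self, pop_index: int = 0) -> Workspace:
        """Aligned numeric workspace over the retained SNPs (fast path used
        by the benchmark harness; equivalent to building from the tables)."""
        k = self.keep
        return Workspace.from_arrays(
            self.recipient_obs[k].astype(np.int8),
            self.count_a[k],
            self.count_b[k],
            self.freqs[k, pop_index],
            pop=self.pop_names[pop_index],
            block_of=self.blocks.snp_block[k],
            n_blocks=self.blocks.n_blocks,
        )

    def realized_donor_fraction(self) -> float:
        total = self.count_a[self.keep].sum() + self.count_b[self.keep].sum()
        return float(self.n_donor_reads[self.keep].sum() / total) if total else 0.0

    def write(self, outdir) -> None:
        """Write the four input tables plus a ground-truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genotype_table().to_csv(outdir / "genotypes.tsv", sep="\t", index=False)
        self.counts_table().to_csv(outdir / "counts.tsv", sep="\t", index=False)
        self.freq_table().to_csv(outdir / "frequencies.tsv", sep="\t", index=False)
        m = self.map_df.copy()
        m.insert(2, "rate_cm_per_mb", self.config.cm_per_mb)
        m.to_csv(outdir / "genetic_map.txt", sep="\t", index=False)
        truth = {
            "d_true": self.config.d_true,
            "p_ibd_1": self.config.p_ibd_1,
            "p_ibd_2": self.config.p_ibd_2,
            "realized_donor_fraction": self.realized_donor_fraction(),
            "config": asdict(self.config),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


# ---------------------------------------------------------------------------
# individual generative steps
# ---------------------------------------------------------------------------

def synthetic_genome(
    n_snps: int, n_chrom: int, total_cm: float, cm_per_mb: float, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniformly spaced SNP positions over ``n_chrom`` equal chromosomes and
    the matching constant-rate genetic map."""
    chrom_cm = total_cm / n_chrom
    chrom_bp = int(chrom_cm / cm_per_mb * 1e6)
    counts = np.full(n_chrom, n_snps // n_chrom)
    counts[: n_snps % n_chrom] += 1
    snp_rows, map_rows = [], []
    for c in range(n_chrom):
        name = f"chr{c + 1}"
        pos = np.sort(rng.choice(chrom_bp, size=counts[c], replace=False)) + 1
        snp_rows.append(pd.DataFrame({"chrom": name, "pos": pos}))
        map_rows.append(
            pd.DataFrame({"chrom": name, "pos": [1, chrom_bp], "cm": [0.0, chrom_cm]})
        )
    snps = pd.concat(snp_rows, ignore_index=True)
    snps["allele_a"] = "A"
    snps["allele_b"] = "B"
    return snps, pd.concat(map_rows, ignore_index=True)


def simulate_frequencies(
    n_snps: int,
    n_pops: int,
    rng: np.random.Generator,
    low: float = 0.05,
    high: float = 0.95,
    divergence: float = 0.0,
) -> np.ndarray:
    """Per-population allele-A frequencies, shape (n_snps, n_pops).

    The base population is Uniform(low, high); additional populations add
    Normal(0, divergence) jitter, clipped back into [low, high] — divergence
    0 yields identical columns.
    """
    base = rng.uniform(low, high, size=n_snps)
    cols = [base]
    for _ in range(1, n_pops):
        cols.append(np.clip(base + rng.normal(0.0, divergence, size=n_snps), low, high))
    return np.stack(cols, axis=1)


def _categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw from an (N, K) probability matrix."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    cum /= cum[:, -1][:, None]
    return (u[:, None] > cum).sum(axis=1).astype(np.int8)


def simulate_recipient(
    f_a: np.ndarray, e_g: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Recipient true genotype classes under Hardy-Weinberg and the observed
    (array-measured) classes after the genotyping-error kernel."""
    f_b = 1.0 - f_a
    hw = np.stack([f_a * f_a, 2 * f_a * f_b, f_b * f_b], axis=1)
    true = _categorical(hw, rng)
    G = genotype_emission_matrix(e_g)  # G[obs, true]
    obs = _categorical(G.T[true], rng)
    return true, obs


def simulate_ibd_path(
    blocks: BlockPartition, p_ibd_1: float, p_ibd_2: float, rng: np.random.Generator
) -> np.ndarray:
    """Sample the joint IBD path over blocks; returns the IBD count per
    block. Each haploid pair follows its own two-state chain (stationary
    start per chromosome); ``p_ibd = 0`` pins a pair to the non-IBD state."""
    out = np.zeros(blocks.n_blocks, dtype=np.int8)
    for p in (p_ibd_1, p_ibd_2):
        if p <= 0.0:
            continue
        m = meioses_from_pibd(p)
        for blk_slice, l_cm in blocks.chrom_chains():
            n = blk_slice.stop - blk_slice.start
            theta = recomb_prob(np.asarray(l_cm, dtype=float))
            stay, enter = _stay_enter(theta, m)
            states = np.empty(n, dtype=np.int8)
            states[0] = rng.random() < stationary_distribution(m)[1]
            u = rng.random(max(n - 1, 0))
            for b in range(1, n):
                p_ibd_next = stay[b - 1] if states[b - 1] else enter[b - 1]
                states[b] = u[b - 1] < p_ibd_next
            out[blk_slice] += states
    return out


def simulate_donor(
    recipient_true: np.ndarray,
    f_a: np.ndarray,
    ibd_count_snp: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Donor genotype classes given the recipient truth and per-SNP IBD
    count, using the IBD-conditional genotype prior (population draw at IBD
    0, one shared haploid at IBD 1, identical genotype at IBD 2)."""
    f_b = 1.0 - f_a
    probs = np.stack([f_a * f_a, 2 * f_a * f_b, f_b * f_b], axis=1)
    one = ibd_count_snp == 1
    if one.any():
        r = recipient_true[one]
        fa1, fb1 = f_a[one], f_b[one]
        t = np.empty((one.sum(), 3))
        t[r == 0] = np.stack([fa1, fb1, np.zeros_like(fa1)], axis=1)[r == 0]
        t[r == 1] = np.stack([0.5 * fa1, np.full_like(fa1, 0.5), 0.5 * fb1], axis=1)[r == 1]
        t[r == 2] = np.stack([np.zeros_like(fa1), fa1, fb1], axis=1)[r == 2]
        probs[one] = t
    two = ibd_count_snp == 2
    if two.any():
        ident = np.zeros((two.sum(), 3))
        ident[np.arange(two.sum()), recipient_true[two]] = 1.0
        probs[two] = ident
    return _categorical(probs, rng)


def simulate_counts(
    recipient_true: np.ndarray,
    donor_true: np.ndarray,
    d_true: float,
    coverage: float,
    e_s: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """cfDNA allele counts per SNP.

    Coverage is Poisson per SNP; each fragment is donor-origin with
    probability ``d_true``, carries the allele of a uniformly chosen
    chromosome of its genome of origin, and is mis-read with probability
    ``e_s``. Returns (count_a, count_b, n_donor_reads).
    """
    n = recipient_true.shape[0]
    K = rng.poisson(coverage, size=n)
    n_donor = rng.binomial(K, d_true)
    dose_a = np.array([1.0, 0.5, 0.0])
    pa_donor = dose_a[donor_true] * (1 - 2 * e_s) + e_s
    pa_recip = dose_a[recipient_true] * (1 - 2 * e_s) + e_s
    count_a = rng.binomial(n_donor, pa_donor) + rng.binomial(K - n_donor, pa_recip)
    return count_a.astype(np.int64), (K - count_a).astype(np.int64), n_donor.astype(np.int64)


def downsample_snps_topk(
    alt_freq: np.ndarray, block_of: np.ndarray, k: int
) -> np.ndarray:
    """Boolean mask keeping, per block, the ``k`` SNPs with the highest
    alternative-allele frequency (ties broken by position order); blocks
    with fewer than ``k`` SNPs are kept whole."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = pd.DataFrame({"block": block_of, "alt": alt_freq})
    df["idx"] = np.arange(len(df))
    ranked = df.sort_values(["block", "alt", "idx"], ascending=[True, False, True])
    rank = ranked.groupby("block").cumcount()
    keep = np.zeros(len(df), dtype=bool)
    keep[ranked["idx"].to_numpy()[rank.to_numpy() < k]] = True
    return keep


def downsample_coverage(
    count_a: np.ndarray,
    count_b: np.ndarray,
    target_coverage: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Binomially thin reads so the mean coverage drops to ``target_coverage``
    (each read kept independently with probability target/current)."""
    current = (count_a.sum() + count_b.sum()) / count_a.shape[0]
    if target_coverage > current:
        raise ValueError(
            f"target coverage {target_coverage} exceeds current mean {current:.3f}"
        )
    p = target_coverage / current
    if p >= 1.0:
        return count_a.copy(), count_b.copy()
    return rng.binomial(count_a, p), rng.binomial(count_b, p)


def filter_genotype_error_snps(
    obs_class: np.ndarray,
    count_a: np.ndarray,
    count_b: np.ndarray,
    min_reads: int = 4,
    min_absent: int = 1,
) -> np.ndarray:
    """Mask of SNPs flagged as clear genotyping errors: homozygous observed
    genotype with at least ``min_absent`` reads of the absent allele among
    at least ``min_reads`` covering reads. Heterozygous SNPs are never
    flagged. Intended for pure (pre-transplant) recipient reads."""
    K = count_a + count_b
    absent = np.where(obs_class == 0, count_b, np.where(obs_class == 2, count_a, 0))
    return (obs_class != 1) & (K >= min_reads) & (absent >= min_absent)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generative pipeline for one replicate.

    Identical configs (including seed) produce bit-identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    snps, map_df = synthetic_genome(
        config.n_snps, config.n_chrom, config.total_cm, config.cm_per_mb, rng
    )
    blocks = build_blocks(map_df, snps, target_cm=config.block_cm)
    freqs = simulate_frequencies(
        config.n_snps, config.n_pops, rng,
        low=config.freq_low, high=config.freq_high, divergence=config.divergence,
    )
    f0 = freqs[:, 0]
    recip_true, recip_obs = simulate_recipient(f0, config.e_g_true, rng)
    ibd_block = simulate_ibd_path(blocks, config.p_ibd_1, config.p_ibd_2, rng)
    ibd_snp = ibd_block[blocks.snp_block]
    donor_true = simulate_donor(recip_true, f0, ibd_snp, rng)
    count_a, count_b, n_donor = simulate_counts(
        recip_true, donor_true, config.d_true, config.coverage, config.e_s_true, rng
    )
    keep = np.ones(config.n_snps, dtype=bool)
    if config.top_k is not None:
        keep &= downsample_snps_topk(1.0 - f0, blocks.snp_block, config.top_k)
    return SimulatedDataset(
        config=config,
        snps=snps,
        map_df=map_df,
        blocks=blocks,
        freqs=freqs,
        pop_names=[f"pop{j + 1}" for j in range(config.n_pops)],
        recipient_true=recip_true,
        recipient_obs=recip_obs,
        donor_true=donor_true,
        ibd_block_count=ibd_block,
        count_a=count_a,
        count_b=count_b,
        n_donor_reads=n_donor,
        keep=keep,
    )
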