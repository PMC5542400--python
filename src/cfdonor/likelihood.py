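"""Aligned numeric workspace shared by the genome-wide likelihood fitters.

A :class:`Workspace` aligns the recipient genotypes, cfDNA allele counts,
and one population's allele frequencies on a common SNP set, encodes them as
numpy arrays and caches everything that does not depend on the fitted
parameters (donor-prior arrays, zero-coverage class counts, the SNP-to-block
assignment for the IBD HMM). SNPs with a missing recipient genotype are
dropped and counted; SNPs without covering reads contribute a closed-form
genotype-emission term and are excluded from the vectorized read loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emissions import (
    donor_prior_arrays, genotype_emission_matrix, genotype_marginal_logprob,
    per_snp_loglik, zero_coverage_loglik,
)
from .model import F_MIN

_GCLASS = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}


@dataclass
class Workspace:
    """Aligned per-SNP arrays plus the likelihood dispatch.

    ``recipient_prior`` selects the prior over true recipient genotypes:
    "hw" (default) uses the population Hardy-Weinberg masses per SNP, which
    matches how genotypes arise in the population; "uniform" is the printed
    simplification (1/4 per ordered pair).
    """

    obs: np.ndarray          # (N,) int8 observed recipient class, covered SNPs only
    count_a: np.ndarray      # (N,) float64
    count_b: np.ndarray      # (N,) float64
    f_a: np.ndarray          # (N,) float64, clamped allele-A frequency
    zero_obs_counts: np.ndarray   # (3,) counts of zero-coverage SNPs per class
    pop: str = "pop"
    block_of: np.ndarray | None = None   # (N,) int64 global block index
    n_blocks: int = 0
    n_missing_genotype: int = 0
    recipient_prior: str = "hw"
    _dp: tuple[np.ndarray, np.ndarray] = field(init=False, repr=False)
    _obs_counts: np.ndarray = field(init=False, repr=False)
    _block_obs_counts: np.ndarray | None = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.recipient_prior not in ("hw", "uniform"):
            raise ValueError(f"unknown recipient_prior {self.recipient_prior!r}")
        self._dp = donor_prior_arrays(self.f_a)
        self._obs_counts = np.bincount(self.obs, minlength=3).astype(np.float64)
        if self.block_of is not None:
            self._block_obs_counts = np.stack(
                [
                    np.bincount(
                        self.block_of[self.obs == o], minlength=self.n_blocks
                    ).astype(np.float64)
                    for o in range(3)
                ],
                axis=1,
            )
        else:
            self._block_obs_counts = None

    @property
    def n_snps_used(self) -> int:
        return int(self.obs.shape[0] + self.zero_obs_counts.sum())

    # -- construction -------------------------------------------------------

    @classmethod
    def from_arrays(
        cls,
        obs: np.ndarray,
        count_a: np.ndarray,
        count_b: np.ndarray,
        f_a: np.ndarray,
        pop: str = "pop",
        block_of: np.ndarray | None = None,
        n_blocks: int = 0,
        recipient_prior: str = "hw",
    ) -> "Workspace":
        """Build from already-aligned arrays; ``obs`` may contain -1 for
        missing genotypes, which are dropped (and counted)."""
        obs = np.asarray(obs, dtype=np.int8)
        count_a = np.asarray(count_a, dtype=np.float64)
        count_b = np.asarray(count_b, dtype=np.float64)
        f_a = np.clip(np.asarray(f_a, dtype=np.float64), F_MIN, 1.0 - F_MIN)
        valid = obs >= 0
        n_missing = int((~valid).sum())
        obs, count_a, count_b, f_a = (
            a[valid] for a in (obs, count_a, count_b, f_a)
        )
        if block_of is not None:
            block_of = np.asarray(block_of, dtype=np.int64)[valid]
        covered = (count_a + count_b) > 0
        zero_counts = np.bincount(obs[~covered], minlength=3).astype(np.int64)
        ws = cls(
            obs=obs[covered],
            count_a=count_a[covered],
            count_b=count_b[covered],
            f_a=f_a[covered],
            zero_obs_counts=zero_counts,
            pop=pop,
            block_of=None if block_of is None else block_of[covered],
            n_blocks=n_blocks,
            n_missing_genotype=n_missing,
            recipient_prior=recipient_prior,
        )
        return ws

    @classmethod
    def from_tables(
        cls,
        genotypes: pd.DataFrame,
        counts: pd.DataFrame,
        freqs: pd.DataFrame,
        pop: str,
        block_of: pd.Series | np.ndarray | None = None,
        n_blocks: int = 0,
        recipient_prior: str = "hw",
    ) -> "Workspace":
        """Align the three input tables on (chrom, pos) and build a workspace.

        ``genotypes`` needs columns chrom, pos, genotype; ``counts`` columns
        chrom, pos, count_a, count_b; ``freqs`` columns chrom, pos and one
        column per population. Only SNPs present in all three tables enter
        the likelihood.
        """
        key = ["chrom", "pos"]
        g = genotypes[key + ["genotype"]]
        c = counts[key + ["count_a", "count_b"]]
        fcols = key + [pop]
        f = freqs[fcols]
        merged = g.merge(c, on=key, how="inner").merge(f, on=key, how="inner")
        obs = (
            merged["genotype"]
            .map(lambda s: _GCLASS.get(s, -1) if isinstance(s, str) else -1)
            .to_numpy(dtype=np.int8)
        )
        blk = None
        if block_of is not None:
            blk_map = pd.Series(
                np.asarray(block_of),
                index=pd.MultiIndex.from_frame(genotypes[key]),
            )
            blk = blk_map.loc[pd.MultiIndex.from_frame(merged[key])].to_numpy()
        return cls.from_arrays(
            obs,
            merged["count_a"].to_numpy(),
            merged["count_b"].to_numpy(),
            merged[pop].to_numpy(),
            pop=pop,
            block_of=blk,
            n_blocks=n_blocks,
            recipient_prior=recipient_prior,
        )

    # -- likelihood ---------------------------------------------------------

    def snp_logliks(self, d: float, e_s: float, e_g: float,
                    states: tuple[int, ...] = (0,)) -> np.ndarray:
        """Per-covered-SNP log-likelihoods, shape (len(states), N)."""
        rw = self._dp[0] if self.recipient_prior == "hw" else None
        return per_snp_loglik(
            self.obs, self.count_a, self.count_b, self.f_a,
            d, e_s, e_g, states=states, dp=self._dp, recipient_weights=rw,
        )

    def _log_genotype_marginal(self, e_g: float) -> np.ndarray:
        """Per-covered-SNP log P(R* | e_g) under the workspace's recipient
        prior (the normalizer of the conditional likelihood)."""
        G = genotype_emission_matrix(e_g)
        if self.recipient_prior == "uniform":
            return genotype_marginal_logprob(e_g)[self.obs]
        return np.log((G[self.obs, :] * self._dp[0].T).sum(axis=1))

    def zero_loglik(self, e_g: float) -> float:
        """Closed-form contribution of zero-coverage SNPs (state-independent)."""
        return zero_coverage_loglik(self.zero_obs_counts, e_g)

    def loglik_unrelated(
        self, d: float, e_s: float, e_g: float, conditional: bool = True
    ) -> float:
        """Genome log-likelihood under the unrelated-donor model.

        With ``conditional=True`` (default) the likelihood is conditioned on
        the measured recipient genotype, P(C* | R*; theta); with False it is
        the joint P(R*, C* | theta), which adds the genotype-emission
        marginal (the only term zero-coverage SNPs contribute to).
        """
        if self.n_snps_used == 0:
            raise ValueError("no usable SNPs in workspace")
        ll = float(self.snp_logliks(d, e_s, e_g, states=(0,)).sum())
        if conditional:
            if self.recipient_prior == "uniform":
                return ll - float(self._obs_counts @ genotype_marginal_logprob(e_g))
            return ll - float(self._log_genotype_marginal(e_g).sum())
        if self.recipient_prior != "uniform":
            raise ValueError(
                "the joint likelihood is defined for the uniform recipient "
                "prior only (zero-coverage SNPs carry no stored frequency)"
            )
        return ll + self.zero_loglik(e_g)

    def block_logliks(
        self, d: float, e_s: float, e_g: float, conditional: bool = True
    ) -> np.ndarray:
        """Per-block emission log-likelihoods for IBD states 0/1/2, shape
        (n_blocks, 3). Zero-coverage SNPs are state-independent; under the
        conditional likelihood they contribute exactly zero, under the joint
        their marginal is a global constant added by the caller."""
        if self.block_of is None:
            raise ValueError("workspace has no block assignment")
        ll = self.snp_logliks(d, e_s, e_g, states=(0, 1, 2))
        out = np.empty((self.n_blocks, 3))
        for s in range(3):
            out[:, s] = np.bincount(
                self.block_of, weights=ll[s], minlength=self.n_blocks
            )
        if conditional:
            if self.recipient_prior == "uniform":
                out -= (self._block_obs_counts @ genotype_marginal_logprob(e_g))[:, None]
            else:
                marg = np.bincount(
                    self.block_of,
                    weights=self._log_genotype_marginal(e_g),
                    minlength=self.n_blocks,
                )
                out -= marg[:, None]
        elif self.recipient_prior != "uniform":
            raise ValueError(
                "the joint likelihood is defined for the uniform recipient prior only"
            )
        return out
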