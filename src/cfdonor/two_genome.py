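"""Simplified two-genomes estimator, used as an independent cross-check.

The conventional approach to donor-derived cfDNA quantification genotypes
both the recipient and the donor and counts reads at SNPs where the two are
homozygous for different alleles: at such sites every donor fragment shows
the donor allele and every recipient fragment the recipient allele, so the
pooled donor-allele read fraction is a binomial estimate of d. Sequencing
error can be measured at SNPs where both genomes are homozygous for the
same allele and subtracted as a background. This module is a minimal
reference estimator for validating one-genome fits on synthetic mixtures,
not a reimplementation of the full clinical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_HOM = {"AA", "BB"}


@dataclass
class DiscriminatingSnpSet:
    """SNPs where recipient and donor are homozygous for opposite alleles.

    ``table`` has columns chrom, pos, donor_allele ("A" or "B")."""

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


def _aligned(recipient: pd.DataFrame, donor: pd.DataFrame) -> pd.DataFrame:
    key = ["chrom", "pos"]
    return recipient[key + ["genotype"]].merge(
        donor[key + ["genotype"]], on=key, suffixes=("_r", "_d"), how="inner"
    )


def select_discriminating_snps(
    recipient: pd.DataFrame, donor: pd.DataFrame
) -> DiscriminatingSnpSet:
    """SNPs homozygous in both genomes but for different alleles."""
    m = _aligned(recipient, donor)
    keep = (
        m["genotype_r"].isin(_HOM)
        & m["genotype_d"].isin(_HOM)
        & (m["genotype_r"] != m["genotype_d"])
    )
    sel = m[keep]
    if sel.empty:
        raise ValueError(
            "no discriminating SNPs: recipient and donor share all homozygous "
            "genotypes (insufficient informative sites)"
        )
    out = sel[["chrom", "pos"]].copy()
    out["donor_allele"] = np.where(sel["genotype_d"] == "AA", "A", "B")
    return DiscriminatingSnpSet(out.reset_index(drop=True))


def matched_homozygous_snps(
    recipient: pd.DataFrame, donor: pd.DataFrame
) -> pd.DataFrame:
    """SNPs homozygous for the same allele in both genomes (chrom, pos,
    absent_allele); reads carrying the absent allele can only be errors."""
    m = _aligned(recipient, donor)
    keep = (
        m["genotype_r"].isin(_HOM)
        & m["genotype_d"].isin(_HOM)
        & (m["genotype_r"] == m["genotype_d"])
    )
    sel = m[keep]
    out = sel[["chrom", "pos"]].copy()
    out["absent_allele"] = np.where(sel["genotype_r"] == "AA", "B", "A")
    return out.reset_index(drop=True)


def background_error_rate(counts: pd.DataFrame, matched: pd.DataFrame) -> float:
    """Fraction of reads carrying the absent allele over matched homozygous
    SNPs — an empirical per-read error rate."""
    if matched.empty:
        raise ValueError("matched homozygous set is empty")
    m = matched.merge(counts, on=["chrom", "pos"], how="inner")
    absent = np.where(m["absent_allele"] == "A", m["count_a"], m["count_b"])
    total = (m["count_a"] + m["count_b"]).sum()
    if total == 0:
        raise ValueError("zero coverage over matched homozygous SNPs")
    return float(absent.sum() / total)


def estimate_two_genome(
    counts: pd.DataFrame,
    snp_set: DiscriminatingSnpSet,
    error_correction: float | None = None,
) -> float:
    """Pooled donor-allele read fraction over the discriminating set.

    With ``error_correction`` (a background per-read error rate), the
    estimate is debiased as (raw - e) / (1 - 2 e), clipped at 0: errors move
    reads symmetrically between the two alleles, so the expected raw
    fraction is d (1 - 2 e) + e.
    """
    m = snp_set.table.merge(counts, on=["chrom", "pos"], how="inner")
    total = (m["count_a"] + m["count_b"]).sum()
    if total == 0:
        raise ValueError("zero coverage over discriminating SNPs")
    donor_reads = np.where(m["donor_allele"] == "A", m["count_a"], m["count_b"]).sum()
    d_hat = float(donor_reads / total)
    if error_correction is not None:
        d_hat = max(0.0, (d_hat - error_correction) / (1.0 - 2.0 * error_correction))
    return d_hat
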