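"""Genetic blocks: ~2 cM partitions of the SNP set along each chromosome.

IBD-state transitions in the related-donor model are only allowed between
pre-computed genetic blocks, which keeps the HMM short and damps linkage
disequilibrium within a block. Blocks are built greedily left-to-right per
chromosome from a cumulative genetic map: a new block starts once the
current block spans at least the target length (default 2 cM). The
inter-block distance used by the transition model is the distance between
block cM midpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BlockPartition:
    """Assignment of SNPs to genetic blocks.

    Attributes
    ----------
    snp_block
        Global block index per SNP, following the SNP order of the input.
    blocks
        One row per block: chrom, start_pos, end_pos, cm_start, cm_end,
        cm_mid, n_snps.
    target_cm
        The block-length target used at construction.
    """

    snp_block: np.ndarray
    blocks: pd.DataFrame
    target_cm: float = 2.0

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def chrom_chains(self) -> list[tuple[slice, np.ndarray]]:
        """Per-chromosome HMM segments.

        Returns a list of ``(block_slice, l_cm)`` pairs, one per chromosome
        in block order; ``l_cm`` holds the midpoint-to-midpoint genetic
        distances between consecutive blocks (length ``n_blocks - 1`` within
        the chromosome). The IBD chain restarts at each chromosome.
        """
        chains = []
        chroms = self.blocks["chrom"].to_numpy()
        mids = self.blocks["cm_mid"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                l_cm = np.maximum(np.diff(mids[start:i]), 0.0)
                chains.append((slice(start, i), l_cm))
                start = i
        return chains


def interpolate_cm(
    map_df: pd.DataFrame, chrom: str, pos: np.ndarray
) -> np.ndarray:
    """Cumulative cM of positions on one chromosome by linear interpolation.

    Positions outside the map span take the nearest map point's cumulative
    value (constant extrapolation).
    """
    m = map_df[map_df["chrom"] == chrom]
    if m.empty:
        raise ValueError(f"genetic map has no entries for chromosome {chrom!r}")
    return np.interp(pos, m["pos"].to_numpy(dtype=float), m["cm"].to_numpy(dtype=float))


def build_blocks(
    map_df: pd.DataFrame, snps: pd.DataFrame, target_cm: float = 2.0
) -> BlockPartition:
    """Partition SNPs into ~``target_cm`` genetic blocks per chromosome.

    Parameters
    ----------
    map_df
        Genetic map with columns chrom, pos, cm (cumulative, authoritative).
    snps
        SNP table with columns chrom, pos, in genomic order per chromosome.
    """
    if target_cm <= 0:
        raise ValueError("target_cm must be positive")
    snps = snps.reset_index(drop=True)
    snp_block = np.empty(len(snps), dtype=np.int64)
    rows = []
    next_block = 0
    for chrom, idx in snps.groupby("chrom", sort=False).groups.items():
        pos = snps.loc[idx, "pos"].to_numpy(dtype=float)
        order = np.argsort(pos, kind="stable")
        cm = interpolate_cm(map_df, chrom, pos[order])
        block_ids = np.empty(len(pos), dtype=np.int64)
        start = 0
        for j in range(len(pos)):
            if cm[j] - cm[start] >= target_cm:
                rows.append(_block_row(chrom, pos[order], cm, start, j, next_block))
                next_block += 1
                start = j
            block_ids[j] = next_block
        rows.append(_block_row(chrom, pos[order], cm, start, len(pos), next_block))
        next_block += 1
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        snp_block[np.asarray(idx)] = block_ids[inv]
    blocks = pd.DataFrame(
        rows,
        columns=["chrom", "start_pos", "end_pos", "cm_start", "cm_end", "cm_mid", "n_snps"],
    )
    return BlockPartition(snp_block=snp_block, blocks=blocks, target_cm=target_cm)


def _block_row(chrom, pos, cm, start, stop, block_id):
    c0, c1 = cm[start], cm[stop - 1]
    return (chrom, int(pos[start]), int(pos[stop - 1]), c0, c1, 0.5 * (c0 + c1), stop - start)
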