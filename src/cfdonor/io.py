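"""Readers and writers for the tabular inputs of the dd-cfDNA model.

Four inputs are consumed:

* recipient (and optionally donor) genotypes — VCF or 5-column TSV
  (chrom, pos, allele_a, allele_b, genotype);
* per-SNP cfDNA allele counts — TSV (chrom, pos, allele_a, allele_b,
  count_a, count_b), typically derived from ``samtools mpileup`` output;
* population allele-frequency tables — TSV with one column per candidate
  population giving the allele-A frequency;
* a genetic map in the common 4-column format (chrom, pos, rate cM/Mb,
  cumulative cM), the cumulative column being authoritative.

All TSVs are tab-separated with a header row; lines starting with '#' are
comments. Coordinates are 1-based, matching VCF. Genotype strings at the
I/O boundary are unordered ("AG" == "GA"); they are normalized to the
AA/AB/BB classes used internally.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import F_MIN
from .blocks import BlockPartition, build_blocks  # re-exported for convenience

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes", "read_allele_counts", "read_population_frequencies",
    "read_genetic_map", "read_pileup", "build_blocks", "BlockPartition",
    "write_table", "write_blocks",
]

_MISSING = {".", "..", "./.", ".|.", "NA", "NN", "", "nan", "None"}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})


def _normalize_genotype(raw: str, allele_a: str, allele_b: str, line: str) -> str | None:
    """Map a two-letter genotype over the SNP's alleles to AA/AB/BB."""
    raw = str(raw).strip()
    if raw in _MISSING:
        return None
    if raw in ("AA", "AB", "BA", "BB") and {allele_a, allele_b} != {"A", "B"}:
        # Already in internal notation.
        return "AB" if raw in ("AB", "BA") else raw
    if len(raw) != 2:
        raise ValueError(f"malformed genotype {raw!r} at {line}")
    codes = []
    for ch in raw:
        if ch == allele_a:
            codes.append("A")
        elif ch == allele_b:
            codes.append("B")
        else:
            raise ValueError(
                f"genotype {raw!r} uses an allele outside {{{allele_a},{allele_b}}} at {line}"
            )
    codes.sort()
    return "".join(codes)


def read_genotypes(path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a genotype table from VCF (``.vcf``/``.vcf.gz``) or TSV.

    Returns columns chrom, pos, allele_a, allele_b, genotype where genotype
    is "AA"/"AB"/"BB" or NaN for missing. Only bi-allelic SNP records are
    kept; multi-allelic and non-SNP records are dropped with a logged count.
    """
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_genotypes_vcf(p, sample_id)
    df = _read_tsv(path)
    need = ["chrom", "pos", "allele_a", "allele_b", "genotype"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"genotype TSV missing columns {missing}")
    out = df[need].copy()
    out["genotype"] = [
        _normalize_genotype(g, a, b, f"{c}:{pos}")
        for g, a, b, c, pos in zip(
            out["genotype"], out["allele_a"], out["allele_b"], out["chrom"], out["pos"]
        )
    ]
    return out


def _read_genotypes_vcf(path: str, sample_id: str | None) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if sample_id is None:
        if len(samples) != 1:
            raise ValueError(
                f"VCF has {len(samples)} samples; pass sample_id to pick one"
            )
        sidx = 0
    else:
        if sample_id not in samples:
            raise ValueError(f"sample {sample_id!r} not in VCF (has {samples})")
        sidx = samples.index(sample_id)
    rows = []
    n_dropped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_dropped += 1
            continue
        a1, a2 = v.genotypes[sidx][0], v.genotypes[sidx][1]
        if a1 < 0 or a2 < 0:
            geno = None
        else:
            geno = "".join(sorted("A" if a == 0 else "B" for a in (a1, a2)))
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], geno))
    if n_dropped:
        logger.info("read_genotypes: dropped %d multi-allelic/non-SNP records", n_dropped)
    df = pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b", "genotype"])
    df.attrs["n_dropped_non_biallelic"] = n_dropped
    return df


def read_allele_counts(path) -> pd.DataFrame:
    """Read a per-SNP allele-count TSV (chrom, pos, allele_a, allele_b,
    count_a, count_b). Zero-coverage rows are allowed; negative counts and
    duplicate (chrom, pos) records are errors."""
    df = _read_tsv(path)
    need = ["chrom", "pos", "allele_a", "allele_b", "count_a", "count_b"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"allele-count TSV missing columns {missing}")
    df = df[need].copy()
    for c in ("count_a", "count_b"):
        df[c] = df[c].astype(np.int64)
        if (df[c] < 0).any():
            bad = df[df[c] < 0].iloc[0]
            raise ValueError(f"negative {c} at {bad['chrom']}:{bad['pos']}")
    dup = df.duplicated(["chrom", "pos"])
    if dup.any():
        bad = df[dup].iloc[0]
        raise ValueError(f"duplicate SNP record at {bad['chrom']}:{bad['pos']}")
    return df


def read_population_frequencies(path) -> pd.DataFrame:
    """Read a population allele-A frequency table.

    Columns: chrom, pos, allele_a, allele_b, then one frequency column per
    population. Frequencies must lie in [0, 1] and are clamped into
    [F_MIN, 1 - F_MIN] so monomorphic sites stay usable in the likelihood.
    """
    df = _read_tsv(path)
    fixed = ["chrom", "pos", "allele_a", "allele_b"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ValueError(f"frequency TSV missing columns {missing}")
    pops = [c for c in df.columns if c not in fixed]
    if not pops:
        raise ValueError("frequency TSV has no population columns")
    for c in pops:
        vals = df[c].astype(float)
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"frequency outside [0, 1] in population column {c!r}")
        df[c] = vals.clip(F_MIN, 1.0 - F_MIN)
    return df[fixed + pops]


def read_genetic_map(path) -> pd.DataFrame:
    """Read a genetic map; expects 4 columns (chrom, pos, rate in cM/Mb,
    cumulative cM) with arbitrary header names — the cumulative column is
    authoritative. Returns columns chrom, pos, cm."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 4:
        raise ValueError("genetic map needs 4 columns: chrom, pos, rate, cumulative cM")
    df = df.iloc[:, [0, 1, 3]].copy()
    df.columns = ["chrom", "pos", "cm"]
    df["chrom"] = df["chrom"].astype(str)
    for chrom, grp in df.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        cm = grp["cm"].to_numpy()
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"map positions not strictly increasing on {chrom}")
        if (np.diff(cm) < -1e-9).any():
            raise ValueError(f"cumulative cM decreases on {chrom}")
    return df


def read_pileup(path, snps: pd.DataFrame) -> pd.DataFrame:
    """Convert ``samtools mpileup`` text output to an allele-count table.

    ``snps`` supplies the alleles (columns chrom, pos, allele_a, allele_b).
    Pileup base symbols matching neither allele are dropped and counted in
    ``DataFrame.attrs['n_other_bases']``. Positions absent from the pileup
    get zero counts.
    """
    alleles = {
        (c, p): (a, b)
        for c, p, a, b in zip(snps["chrom"], snps["pos"], snps["allele_a"], snps["allele_b"])
    }
    counts = {k: [0, 0] for k in alleles}
    n_other = 0
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            chrom, pos, ref = parts[0], int(parts[1]), parts[2].upper()
            key = (chrom, pos)
            if key not in alleles:
                continue
            a, b = alleles[key]
            for base in _iter_pileup_bases(parts[4], ref):
                if base == a:
                    counts[key][0] += 1
                elif base == b:
                    counts[key][1] += 1
                else:
                    n_other += 1
    out = snps[["chrom", "pos", "allele_a", "allele_b"]].copy()
    out["count_a"] = [counts[(c, p)][0] for c, p in zip(out["chrom"], out["pos"])]
    out["count_b"] = [counts[(c, p)][1] for c, p in zip(out["chrom"], out["pos"])]
    out.attrs["n_other_bases"] = n_other
    return out


def _iter_pileup_bases(bases: str, ref: str):
    """Yield upper-case base calls from a pileup base string, skipping
    mapping-quality markers, indels and read ends."""
    i = 0
    n = len(bases)
    while i < n:
        ch = bases[i]
        if ch == "^":
            i += 2
        elif ch == "$":
            i += 1
        elif ch in "+-":
            i += 1
            num = ""
            while i < n and bases[i].isdigit():
                num += bases[i]
                i += 1
            i += int(num or 0)
        elif ch in ".,":
            yield ref
            i += 1
        elif ch in "*<>":
            i += 1
        else:
            yield ch.upper()
            i += 1


def write_table(df: pd.DataFrame, path) -> None:
    """Write any of the tabular formats back to TSV (round-trip safe)."""
    df.to_csv(path, sep="\t", index=False)


def write_blocks(partition: BlockPartition, path) -> None:
    partition.blocks.to_csv(path, sep="\t", index=False)
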