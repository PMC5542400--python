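"""Named benchmark designs for the simulation study.

Each builder returns ``(grid, base_config)`` pairs consumable by
:func:`cfdonor.benchmark.run_benchmark`. The designs mirror the published
simulation study: dd-cfDNA fractions spanning stated ranges,
donor-recipient relatedness in {unrelated, half-sibling-like, sibling},
and coverage/SNP-count reductions.

Fraction levels are spaced several error standard deviations apart —
wider at the bottom of the range, where the absolute error floor makes
near-equal fractions statistically indistinguishable — so that rank-based
accuracy metrics measure monotone recovery rather than noise between
unresolvable neighbours. Where several relatedness levels share a sweep,
every level sweeps the same fractions and rank correlations are computed
per relatedness level (truths repeat across levels, so a pooled rank
correlation would be tie-limited by construction).

Problem sizes (``n_snps``) are arguments: the full-scale study uses the
600K-SNP genotyping-array scale, while test-scale runs shrink the SNP count
and rely on the error scaling with the number of sequenced reads.
"""

from __future__ import annotations

import numpy as np

from .simulate import SimulationConfig

RELATEDNESS = {
    "unrelated": (0.0, 0.0),
    "half": (0.25, 0.25),
    "sibling": (0.5, 0.5),
}

#: Fraction levels for the full-coverage accuracy sweep (0.01%-25%).
ACCURACY_LEVELS = (
    1e-4, 1e-3, 2.5e-3, 5e-3, 0.01, 0.02, 0.04, 0.07, 0.12, 0.18, 0.25,
)

#: Fraction levels for the low-coverage arms (0.1%-25%, marrow-like range).
LOW_COVERAGE_LEVELS = (
    1e-3, 2e-3, 4e-3, 7e-3, 0.012, 0.02, 0.032, 0.05, 0.07, 0.09,
    0.115, 0.14, 0.17, 0.2, 0.225, 0.25,
)

#: Fraction levels for the reduced-input arms (clinical 0.2%-10% range).
REDUCED_INPUT_LEVELS = (
    2e-3, 3e-3, 4.5e-3, 6.5e-3, 9.5e-3, 0.014, 0.02, 0.03, 0.045, 0.065, 0.08, 0.10,
)

def accuracy_sweep(
    n_snps: int = 600_000,
    coverage: float = 1.75,
    levels: tuple[float, ...] = ACCURACY_LEVELS,
    relatedness: tuple[str, ...] = ("unrelated", "half", "sibling"),
) -> tuple[list[dict], SimulationConfig]:
    """Recovery accuracy across relatedness at full coverage; each
    relatedness level sweeps every fraction level (33 grid points)."""
    grid = []
    for name in relatedness:
        p1, p2 = RELATEDNESS[name]
        for d in levels:
            grid.append({"d_true": float(d), "p_ibd_1": p1, "p_ibd_2": p2})
    return grid, SimulationConfig(n_snps=n_snps, coverage=coverage)


def low_coverage_sweep(
    arm: str,
    n_snps: int = 600_000,
    levels: tuple[float, ...] = LOW_COVERAGE_LEVELS,
) -> tuple[list[dict], SimulationConfig]:
    """Lowest-coverage arms: 0.1x for unrelated pairs, 1x for siblings."""
    if arm == "unrelated":
        coverage, (p1, p2) = 0.1, RELATEDNESS["unrelated"]
    elif arm == "sibling":
        coverage, (p1, p2) = 1.0, RELATEDNESS["sibling"]
    else:
        raise ValueError(f"unknown arm {arm!r}")
    grid = [{"d_true": float(d), "p_ibd_1": p1, "p_ibd_2": p2} for d in levels]
    return grid, SimulationConfig(n_snps=n_snps, coverage=coverage)


def reduced_input_sweep(
    arm: str,
    n_snps_few_snps: int = 150_000,
    n_snps_low_cov: int = 600_000,
    levels: tuple[float, ...] = REDUCED_INPUT_LEVELS,
) -> tuple[list[dict], SimulationConfig]:
    """Reduced-input arms over the clinically relevant 0.2%-10% range:
    either ~150K genotyped SNPs at 1x, or full SNPs at 0.33x sequencing."""
    if arm == "few_snps":
        base = SimulationConfig(n_snps=n_snps_few_snps, coverage=1.0)
    elif arm == "low_coverage":
        base = SimulationConfig(n_snps=n_snps_low_cov, coverage=0.33)
    else:
        raise ValueError(f"unknown arm {arm!r}")
    grid = [{"d_true": float(d)} for d in levels]
    return grid, base


def ultra_low_fraction_sweep(
    n_snps: int = 600_000,
    coverage: float = 1.75,
    replicates_per_point: int = 3,
    fractions: tuple[float, ...] = (1e-4, 2e-4, 5e-4, 8e-4),
    relatedness: tuple[str, ...] = ("unrelated", "sibling"),
) -> tuple[list[dict], SimulationConfig]:
    """Fractions below 0.1%, where the absolute error floor is probed.

    Replication is expressed by repeating grid points (each gets its own
    spawned seed in the benchmark runner).
    """
    grid = []
    for d in fractions:
        for name in relatedness:
            p1, p2 = RELATEDNESS[name]
            for _ in range(replicates_per_point):
                grid.append({"d_true": float(d), "p_ibd_1": p1, "p_ibd_2": p2})
    return grid, SimulationConfig(n_snps=n_snps, coverage=coverage)
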