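"""Model parameters, bounds and fit results for dd-cfDNA estimation.

The model has one parameter of interest, ``d`` (fraction of plasma cfDNA
fragments that are donor-derived), and nuisance parameters: sequencing error
rate ``e_s`` (which also absorbs PCR amplification error), genotyping error
rate ``e_g``, the donor's ancestral population, and — for related
donor-recipient pairs — two marginal identity-by-descent probabilities
``p_ibd_1`` and ``p_ibd_2``, one per haploid pair of the duo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

# Error-rate bounds restrict the nuisance parameters to a technically
# realistic range; the IBD probability cap of 0.5 excludes parent-child
# relationships (which would need exactly one pair fully IBD).
E_S_MIN, E_S_MAX = 1e-9, 1e-2
E_G_MIN, E_G_MAX = 1e-9, 1e-3
P_IBD_MIN, P_IBD_MAX = 1e-6, 0.5

#: Population allele frequencies are clamped into [F_MIN, 1 - F_MIN] so that
#: monomorphic sites cannot produce -inf log-likelihoods.
F_MIN = 1e-4

#: Meiosis count m = 1 - log2(p_ibd); bounds implied by the p_ibd bounds.
M_MIN = 2.0
M_MAX = 1.0 - math.log2(P_IBD_MIN)


def meioses_from_pibd(p_ibd: float) -> float:
    """Number of meioses separating a haploid pair, ``m = 1 - log2(p_ibd)``.

    ``p_ibd`` is the marginal probability of the pair being IBD at a locus;
    siblings have p_ibd = 0.5 per pair, hence m = 2 (one meiosis down to the
    shared parent and one back up... counted as two meiosis events through
    the most recent common diploid ancestor).
    """
    if not (0.0 < p_ibd <= P_IBD_MAX):
        raise ValueError(f"p_ibd must be in (0, {P_IBD_MAX}], got {p_ibd}")
    return 1.0 - math.log2(p_ibd)


def pibd_from_meioses(m: float) -> float:
    """Inverse of :func:`meioses_from_pibd`: ``p_ibd = 2**(1 - m)``."""
    if m < M_MIN:
        raise ValueError(f"meiosis count must be >= {M_MIN}, got {m}")
    return 2.0 ** (1.0 - m)


@dataclass(frozen=True)
class ModelParams:
    """A full parameter point θ = (d, e_s, e_g, pop[, p_ibd_1, p_ibd_2])."""

    d: float
    e_s: float = 1e-3
    e_g: float = 1e-4
    pop: str | None = None
    p_ibd_1: float | None = None
    p_ibd_2: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.d <= 1.0):
            raise ValueError(f"d must be in [0, 1], got {self.d}")
        if not (E_S_MIN <= self.e_s <= E_S_MAX):
            raise ValueError(f"e_s must be in [{E_S_MIN}, {E_S_MAX}], got {self.e_s}")
        if not (E_G_MIN <= self.e_g <= E_G_MAX):
            raise ValueError(f"e_g must be in [{E_G_MIN}, {E_G_MAX}], got {self.e_g}")
        for name in ("p_ibd_1", "p_ibd_2"):
            p = getattr(self, name)
            if p is not None and not (P_IBD_MIN <= p <= P_IBD_MAX):
                raise ValueError(
                    f"{name} must be in [{P_IBD_MIN}, {P_IBD_MAX}], got {p}"
                )

    @property
    def related(self) -> bool:
        return self.p_ibd_1 is not None and self.p_ibd_2 is not None


@dataclass
class FitOptions:
    """Optimizer controls for the maximum-likelihood fits.

    ``init="multi"`` runs one bounded L-BFGS-B minimization per starting
    value of d and keeps the best; ``init="grid"`` first scans a coarse grid
    of (d, relatedness) points and launches a single minimization from the
    best grid point — cheaper when many fits are run in a sweep.
    """

    d_starts: tuple[float, ...] = (0.001, 0.05, 0.3)
    e_s0: float = 1e-3
    e_g0: float = 1e-4
    m0: float = 3.0
    init: str = "multi"  # "multi" | "grid"
    #: Condition the likelihood on the measured recipient genotype (default)
    #: rather than maximizing the joint genotype-and-reads likelihood.
    conditional: bool = True
    #: Pin a parameter instead of estimating it (e.g. error rates calibrated
    #: from a pre-transplant sample, or d = 0 when fitting such a sample).
    fixed_d: float | None = None
    fixed_e_s: float | None = None
    fixed_e_g: float | None = None
    ftol: float = 1e-12
    gtol: float = 1e-7
    maxiter: int = 200


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``d_hat`` is the estimated dd-cfDNA fraction; the remaining fields carry
    the fitted nuisance parameters, the attained log-likelihood, and
    bookkeeping (which population won the scan, how many SNPs entered the
    likelihood, optimizer metadata).
    """

    d_hat: float
    e_s_hat: float
    e_g_hat: float
    pop_hat: str
    loglik: float
    converged: bool
    n_snps_used: int
    p_ibd_1_hat: float | None = None
    p_ibd_2_hat: float | None = None
    mode: str = "unrelated"
    metadata: dict = field(default_factory=dict)

    def params(self) -> ModelParams:
        return ModelParams(
            d=self.d_hat,
            e_s=self.e_s_hat,
            e_g=self.e_g_hat,
            pop=self.pop_hat,
            p_ibd_1=self.p_ibd_1_hat,
            p_ibd_2=self.p_ibd_2_hat,
        )

    def to_dict(self) -> dict:
        return asdict(self)
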