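"""Identity-by-descent HMM for related donor-recipient pairs.

Each of the two haploid pairs of a donor-recipient duo follows an
independent two-state chain (not-IBD / IBD) along the genetic blocks.
Transitions between neighbouring blocks at genetic distance ``l`` cM use the
probability of an odd number of crossovers theta = (1 - exp(-2 l / 100)) / 2
and the number of meioses ``m`` separating the pair via its most recent
common diploid ancestor, with m = 1 - log2(P_IBD). With

    y1 = (1 - theta)^(m - 2)      and      y2 = (1 - theta)^2 + theta^2

the chain stays IBD with probability y1 * y2 and enters IBD from not-IBD
with probability (1 - y1 * y2) / (2^(m-1) - 1), which makes the stationary
IBD mass exactly 2^(1-m) = P_IBD. The joint chain over both pairs has four
states; emissions depend only on the IBD count (0, 1 or 2), so the two
single-IBD joint states share an emission.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .blocks import BlockPartition
from .likelihood import Workspace
from .model import (
    E_G_MAX, E_G_MIN, E_S_MAX, E_S_MIN, M_MAX, M_MIN,
    FitOptions, FitResult, meioses_from_pibd, pibd_from_meioses,
)

#: IBD count of each joint state (pair-I status, pair-II status) with state
#: index s = 2 * s1 + s2.
JOINT_IBD_COUNT = np.array([0, 1, 1, 2])

__all__ = [
    "meioses_from_pibd", "pibd_from_meioses", "recomb_prob",
    "haploid_pair_transition", "joint_transition", "stationary_distribution",
    "forward_loglik", "posterior_ibd", "fit_related",
]


def recomb_prob(l_cm: float | np.ndarray) -> float | np.ndarray:
    """Probability of an odd number of recombinations across ``l_cm`` cM,
    theta = (1 - exp(-2 l / 100)) / 2 (Haldane map function)."""
    l_cm = np.asarray(l_cm, dtype=float)
    if np.any(l_cm < 0):
        raise ValueError("genetic distance must be non-negative")
    theta = 0.5 * -np.expm1(-2.0 * l_cm / 100.0)
    return float(theta) if theta.ndim == 0 else theta


def _stay_enter(theta: np.ndarray, m: float) -> tuple[np.ndarray, np.ndarray]:
    y1 = (1.0 - theta) ** (m - 2.0)
    y2 = (1.0 - theta) ** 2 + theta**2
    stay = y1 * y2
    enter = (1.0 - stay) / (2.0 ** (m - 1.0) - 1.0)
    return stay, enter


def haploid_pair_transition(theta: float, m: float) -> np.ndarray:
    """2x2 transition matrix over (not-IBD, IBD) for one haploid pair."""
    if not (0.0 <= theta < 0.5):
        raise ValueError(f"theta must be in [0, 0.5), got {theta}")
    if m < M_MIN:
        raise ValueError(f"meiosis count must be >= {M_MIN}, got {m}")
    stay, enter = _stay_enter(np.asarray(theta, dtype=float), m)
    return np.array([[1.0 - enter, enter], [1.0 - stay, stay]])


def joint_transition(t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """4x4 joint transition matrix of two independent haploid-pair chains
    (Kronecker product; state index s = 2 * s1 + s2)."""
    return np.kron(t1, t2)


def stationary_distribution(m: float) -> np.ndarray:
    """Stationary distribution (not-IBD, IBD) of a haploid pair: the
    marginal IBD probability is 2^(1-m) = P_IBD."""
    p = pibd_from_meioses(m)
    return np.array([1.0 - p, p])


def _chain_matrices(l_cm: np.ndarray, m1: float, m2: float) -> tuple[np.ndarray, np.ndarray]:
    """Initial distribution (4,) and per-boundary transition stack (B-1, 4, 4)
    for one chromosome."""
    pi = np.kron(stationary_distribution(m1), stationary_distribution(m2))
    theta = recomb_prob(np.asarray(l_cm, dtype=float))
    stay1, enter1 = _stay_enter(theta, m1)
    stay2, enter2 = _stay_enter(theta, m2)
    n = theta.shape[0]
    T1 = np.empty((n, 2, 2))
    T1[:, 0, 1] = enter1
    T1[:, 0, 0] = 1.0 - enter1
    T1[:, 1, 1] = stay1
    T1[:, 1, 0] = 1.0 - stay1
    T2 = np.empty((n, 2, 2))
    T2[:, 0, 1] = enter2
    T2[:, 0, 0] = 1.0 - enter2
    T2[:, 1, 1] = stay2
    T2[:, 1, 0] = 1.0 - stay2
    T = np.einsum("bij,bkl->bikjl", T1, T2).reshape(n, 4, 4)
    return pi, T


def forward_loglik(
    blocks: BlockPartition,
    block_logliks: np.ndarray,
    p_ibd_1: float | None = None,
    p_ibd_2: float | None = None,
    m1: float | None = None,
    m2: float | None = None,
) -> float:
    """Marginal log-likelihood of the block emissions under the joint IBD
    chain (forward algorithm, scaled; the chain restarts at each chromosome).

    ``block_logliks`` has shape (n_blocks, 3) with one emission
    log-likelihood per IBD count. Relatedness may be given either as
    marginal IBD probabilities or directly as meiosis counts.
    """
    if m1 is None:
        m1 = meioses_from_pibd(p_ibd_1)
    if m2 is None:
        m2 = meioses_from_pibd(p_ibd_2)
    total = 0.0
    for blk_slice, l_cm in blocks.chrom_chains():
        logE = block_logliks[blk_slice][:, JOINT_IBD_COUNT]  # (B, 4)
        pi, T = _chain_matrices(l_cm, m1, m2)
        shift = logE.max(axis=1)
        E = np.exp(logE - shift[:, None])
        alpha = pi * E[0]
        c = alpha.sum()
        total += math.log(c) + shift[0]
        alpha /= c
        for b in range(1, logE.shape[0]):
            alpha = (alpha @ T[b - 1]) * E[b]
            c = alpha.sum()
            total += math.log(c) + shift[b]
            alpha /= c
    return float(total)


def posterior_ibd(
    blocks: BlockPartition,
    block_logliks: np.ndarray,
    p_ibd_1: float | None = None,
    p_ibd_2: float | None = None,
    m1: float | None = None,
    m2: float | None = None,
) -> np.ndarray:
    """Per-block posterior over IBD counts (forward-backward), shape
    (n_blocks, 3); rows sum to one."""
    if m1 is None:
        m1 = meioses_from_pibd(p_ibd_1)
    if m2 is None:
        m2 = meioses_from_pibd(p_ibd_2)
    out = np.empty((blocks.n_blocks, 3))
    for blk_slice, l_cm in blocks.chrom_chains():
        logE = block_logliks[blk_slice][:, JOINT_IBD_COUNT]
        pi, T = _chain_matrices(l_cm, m1, m2)
        B = logE.shape[0]
        E = np.exp(logE - logE.max(axis=1)[:, None])
        alphas = np.empty((B, 4))
        alpha = pi * E[0]
        alphas[0] = alpha / alpha.sum()
        for b in range(1, B):
            alpha = (alphas[b - 1] @ T[b - 1]) * E[b]
            alphas[b] = alpha / alpha.sum()
        beta = np.ones(4)
        gammas = np.empty((B, 4))
        gammas[-1] = alphas[-1]
        for b in range(B - 2, -1, -1):
            beta = T[b] @ (E[b + 1] * beta)
            beta /= beta.max()
            g = alphas[b] * beta
            gammas[b] = g / g.sum()
        joint = gammas
        post3 = np.stack(
            [joint[:, JOINT_IBD_COUNT == k].sum(axis=1) for k in range(3)], axis=1
        )
        out[blk_slice] = post3
    return out


# ---------------------------------------------------------------------------
# related-model fit
# ---------------------------------------------------------------------------

_ZD_LO, _ZD_HI = logit(1e-7), logit(1.0 - 1e-7)


class _RelatedObjective:
    """Negative forward log-likelihood with block-emission caching.

    Block emissions depend on (d, e_s, e_g) only, so coordinate
    perturbations of the relatedness parameters during finite-difference
    gradients reuse the cached emission table.
    """

    def __init__(self, ws: Workspace, blocks: BlockPartition, conditional: bool = True):
        self.ws = ws
        self.blocks = blocks
        self.conditional = conditional
        self._key: tuple | None = None
        self._block_ll: np.ndarray | None = None
        self.n_evals = 0

    def _emissions(self, d: float, e_s: float, e_g: float) -> np.ndarray:
        key = (d, e_s, e_g)
        if key != self._key:
            self._block_ll = self.ws.block_logliks(
                d, e_s, e_g, conditional=self.conditional
            )
            self._key = key
        return self._block_ll

    def value(self, d: float, e_s: float, e_g: float, m1: float, m2: float) -> float:
        self.n_evals += 1
        block_ll = self._emissions(d, e_s, e_g)
        ll = forward_loglik(self.blocks, block_ll, m1=m1, m2=m2)
        if not self.conditional:
            ll += self.ws.zero_loglik(e_g)
        return ll

    def __call__(self, x: np.ndarray) -> float:
        d = float(expit(x[0]))
        e_s, e_g = 10.0 ** x[1], 10.0 ** x[2]
        return -self.value(d, e_s, e_g, x[3], x[4])


def fit_related(
    genotypes,
    counts,
    freqs,
    populations: list[str] | None = None,
    blocks: BlockPartition | None = None,
    options: FitOptions | None = None,
    workspaces: dict[str, Workspace] | None = None,
) -> FitResult:
    """Maximum-likelihood fit of the related-donor model.

    Maximizes the forward-algorithm likelihood over (d, e_s, e_g, p_ibd_1,
    p_ibd_2) for each candidate population and returns the best population's
    result (ties broken by listing order). The two IBD probabilities are
    optimized through the meiosis-count parameterization m = 1 - log2(p_ibd)
    and canonicalized so that p_ibd_1 >= p_ibd_2 in the report.

    Either pass the three tables plus ``blocks``, or prebuilt per-population
    ``workspaces`` carrying a block assignment.
    """
    options = options or FitOptions()
    if workspaces is None:
        if blocks is None:
            raise ValueError("fit_related requires a BlockPartition")
        populations = populations or [
            c for c in freqs.columns if c not in ("chrom", "pos", "allele_a", "allele_b", "snp_id")
        ]
        workspaces = {
            pop: Workspace.from_tables(
                genotypes, counts, freqs, pop,
                block_of=blocks.snp_block, n_blocks=blocks.n_blocks,
            )
            for pop in populations
        }
        ws_blocks = {pop: blocks for pop in workspaces}
    else:
        if blocks is None:
            raise ValueError("fit_related requires a BlockPartition")
        ws_blocks = {pop: blocks for pop in workspaces}

    best: FitResult | None = None
    for pop, ws in workspaces.items():
        res = _fit_related_single(ws, ws_blocks[pop], options)
        if best is None or res.loglik > best.loglik:
            best = res
    if best is None:
        raise ValueError("no candidate populations")
    return best


def _fit_related_single(ws: Workspace, blocks: BlockPartition, options: FitOptions) -> FitResult:
    from .unrelated import _theta_mask, _THETA_BOUNDS

    obj = _RelatedObjective(ws, blocks, conditional=options.conditional)
    theta_free, theta_unpack = _theta_mask(options)

    def full_objective(x: np.ndarray) -> float:
        d, e_s, e_g = theta_unpack(x[:-2])
        return -obj.value(d, e_s, e_g, float(x[-2]), float(x[-1]))

    bounds = [_THETA_BOUNDS[i] for i in theta_free] + [(M_MIN, M_MAX), (M_MIN, M_MAX)]
    ls0, lg0 = math.log10(options.e_s0), math.log10(options.e_g0)
    if options.init == "grid":
        starts = _grid_starts(obj, options, theta_free)
    else:
        full0 = [0.0, ls0, lg0]
        starts = []
        for d0 in options.d_starts if options.fixed_d is None else [options.fixed_d]:
            full0[0] = logit(min(max(d0, 1e-7), 1 - 1e-7))
            starts.append(
                np.array([full0[i] for i in theta_free] + [options.m0, options.m0 + 0.2])
            )
    best = None
    for x0 in starts:
        res = minimize(
            full_objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": options.ftol, "gtol": options.gtol, "maxiter": options.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    # L-BFGS-B can return bound values off by one ulp
    p1 = pibd_from_meioses(max(M_MIN, float(best.x[-2])))
    p2 = pibd_from_meioses(max(M_MIN, float(best.x[-1])))
    p1, p2 = max(p1, p2), min(p1, p2)
    d_hat, e_s_hat, e_g_hat = theta_unpack(best.x[:-2])
    return FitResult(
        d_hat=d_hat,
        e_s_hat=e_s_hat,
        e_g_hat=e_g_hat,
        pop_hat=ws.pop,
        loglik=float(-best.fun),
        converged=bool(best.success),
        n_snps_used=ws.n_snps_used,
        p_ibd_1_hat=p1,
        p_ibd_2_hat=p2,
        mode="related",
        metadata={
            "optimizer": "L-BFGS-B",
            "init": options.init,
            "likelihood": "conditional" if options.conditional else "joint",
            "n_starts": len(starts),
            "n_evals": obj.n_evals,
            "n_missing_genotype": ws.n_missing_genotype,
        },
    )


def _grid_starts(
    obj: _RelatedObjective, options: FitOptions, theta_free: list[int]
) -> list[np.ndarray]:
    """Coarse scan over (d, shared meiosis count), then one warm start per
    relatedness regime.

    The likelihood has a ridge coupling d with the IBD probabilities (IBD
    segments hide donor signal, so "more related + larger d" can mimic
    "less related + smaller d"); refining only the single best grid cell can
    strand the optimizer in the wrong regime. One start is taken from the
    best related cell (m < m_max) and one from the best unrelated-limit
    cell, and the better final optimum wins.
    """
    if options.fixed_d is not None:
        d_grid = np.array([options.fixed_d])
    else:
        d_grid = np.array(
            [1e-4, 5e-4, 2e-3, 8e-3, 0.03, 0.1, 0.25, 0.5, 0.75, 0.92, 0.99]
        )
    m_grid = (2.0, 3.0, M_MAX)
    e_s0 = options.fixed_e_s if options.fixed_e_s is not None else options.e_s0
    e_g0 = options.fixed_e_g if options.fixed_e_g is not None else options.e_g0
    full0 = [0.0, math.log10(e_s0), math.log10(e_g0)]
    best: dict[bool, tuple[float, np.ndarray]] = {}
    for d0 in d_grid:
        for m0 in m_grid:
            val = -obj.value(d0, e_s0, e_g0, m0, m0)
            related = m0 < M_MAX
            if related not in best or val < best[related][0]:
                # nudge the two meiosis counts apart so coordinate-wise
                # gradients can leave the symmetric diagonal
                m0b = min(m0 + 0.2, M_MAX)
                full0[0] = logit(min(max(d0, 1e-7), 1 - 1e-7))
                x0 = np.array([full0[i] for i in theta_free] + [m0, m0b])
                best[related] = (val, x0)
    return [x for _, x in best.values()]
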