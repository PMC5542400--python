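"""Per-SNP probability kernels for the one-genome dd-cfDNA likelihood.

Genotypes are over two alleles A and B. Ordered genotypes are the strings
"AA", "AB", "BA", "BB"; unordered (observed) genotypes are "AA", "AB", "BB".
Internally genotype classes are encoded by B-allele dosage: 0 = AA, 1 = AB,
2 = BB.

The per-SNP likelihood marginalizes, for each SNP i with observed recipient
genotype R*_i and cfDNA allele counts (k_A, k_B):

    P_i = sum_{r} P(r) P(R*_i | r; e_g)
          sum_{dd} P(dd | prior) prod_reads P(C* | r, dd; d, e_s)

where r runs over ordered recipient genotypes with a uniform 1/4 prior, dd
over ordered donor genotypes with either the Hardy-Weinberg population prior
(unrelated donor / IBD 0) or the IBD-conditional prior (IBD 1 or 2), and
each read contributes a Bernoulli factor in the mixture allele probability
passed through the sequencing-error channel. Because every factor depends
on genotypes only through dosage, the sum collapses to 3x3 unordered
classes with multiplicity weights, which is what the vectorized driver
:func:`per_snp_loglik` computes.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParams

ORDERED_GENOTYPES = ("AA", "AB", "BA", "BB")
UNORDERED_GENOTYPES = ("AA", "AB", "BB")

#: B-allele dosage of each genotype string.
_BDOSE = {"AA": 0, "AB": 1, "BA": 1, "BB": 2}

#: Uniform prior over ordered recipient genotypes (1/4 each) collapsed onto
#: unordered classes: AA 1/4, AB(+BA) 1/2, BB 1/4.
UNORDERED_PRIOR = np.array([0.25, 0.5, 0.25])


# ---------------------------------------------------------------------------
# scalar reference kernels
# ---------------------------------------------------------------------------

def genotype_emission_prob(observed: str, true: str, e_g: float) -> float:
    """P(observed array genotype | true genotype; e_g).

    The homozygous observations follow the printed error kernel
    P(AA* | true) = (1-e_g)^2 1{AA} + 2 e_g (1-e_g) 1{het} + e_g^2 1{BB}
    (and its allele mirror for BB*); the heterozygous observation receives
    the normalizing remainder, so the three observations sum to one for any
    true genotype.
    """
    if observed not in UNORDERED_GENOTYPES:
        raise ValueError(f"observed genotype must be unordered, got {observed!r}")
    t = _BDOSE[true]
    hom_a = ((1 - e_g) ** 2, 2 * e_g * (1 - e_g), e_g**2)
    if observed == "AA":
        return hom_a[t]
    if observed == "BB":
        return hom_a[2 - t]
    return 1.0 - hom_a[t] - hom_a[2 - t]


def genotype_emission_matrix(e_g: float) -> np.ndarray:
    """3x3 matrix G[o, t] = P(observed class o | true class t; e_g)."""
    q = (1 - e_g) ** 2
    h = 2 * e_g * (1 - e_g)
    s = e_g**2
    return np.array(
        [
            [q, h, s],
            [1 - q - s, 1 - 2 * h, 1 - q - s],
            [s, h, q],
        ]
    )


def sequencing_emission_prob(observed_allele: str, true_allele: str, e_s: float) -> float:
    """P(observed read allele | true fragment allele; e_s)."""
    if observed_allele not in ("A", "B") or true_allele not in ("A", "B"):
        raise ValueError("alleles must be 'A' or 'B'")
    return 1.0 - e_s if observed_allele == true_allele else e_s


def donor_prior_unrelated(f_a: float) -> dict[str, float]:
    """Hardy-Weinberg prior over ordered donor genotypes for allele-A
    frequency ``f_a``: P(d1, d2) = f_{d1} f_{d2}."""
    f_b = 1.0 - f_a
    return {"AA": f_a * f_a, "AB": f_a * f_b, "BA": f_b * f_a, "BB": f_b * f_b}


def donor_prior_given_ibd(recipient: str, ibd_count: int, f_a: float) -> dict[str, float]:
    """Donor genotype prior conditional on the recipient genotype and the
    local IBD count (0, 1 or 2 shared haploid pairs).

    IBD 0 reduces to the unconditional Hardy-Weinberg prior; IBD 1 keeps one
    donor haploid identical to a random recipient haploid and draws the
    other from the population; IBD 2 copies the recipient genotype.
    Unordered masses are split evenly between AB and BA.
    """
    if ibd_count not in (0, 1, 2):
        raise ValueError(f"ibd_count must be 0, 1 or 2, got {ibd_count}")
    if ibd_count == 0:
        return donor_prior_unrelated(f_a)
    r = _BDOSE[recipient]
    f_b = 1.0 - f_a
    if ibd_count == 2:
        unordered = [0.0, 0.0, 0.0]
        unordered[r] = 1.0
    else:
        table2 = {
            0: (f_a, f_b, 0.0),
            1: (0.5 * f_a, 0.5 * f_a + 0.5 * f_b, 0.5 * f_b),
            2: (0.0, f_a, f_b),
        }
        unordered = list(table2[r])
    return {
        "AA": unordered[0],
        "AB": unordered[1] / 2.0,
        "BA": unordered[1] / 2.0,
        "BB": unordered[2],
    }


def mixture_allele_prob(recipient: str, donor: str, d: float) -> float:
    """P(a cfDNA fragment carries allele A | genotypes, dd-cfDNA fraction d).

    A fragment is donor-derived with probability d and carries allele A with
    probability equal to half the A-dosage of its genome of origin.
    """
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"d must be in [0, 1], got {d}")
    a_donor = (2 - _BDOSE[donor]) / 2.0
    a_recip = (2 - _BDOSE[recipient]) / 2.0
    return d * a_donor + (1.0 - d) * a_recip


def snp_loglik(
    observed_genotype: str,
    count_a: int,
    count_b: int,
    params: ModelParams,
    f_a: float,
    ibd_count: int | None = None,
) -> float:
    """Log marginal likelihood of one SNP's observations.

    Marginalizes over ordered recipient and donor genotypes; the per-read
    factors share a common allele probability, so the read product is
    p_A*^count_a * (1 - p_A*)^count_b computed once per genotype pair.
    Scalar reference implementation — the fitters use :func:`per_snp_loglik`.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("allele counts must be non-negative")
    total = 0.0
    for r in ORDERED_GENOTYPES:
        g_emit = 0.25 * genotype_emission_prob(observed_genotype, r, params.e_g)
        if ibd_count is None:
            prior = donor_prior_unrelated(f_a)
        else:
            prior = donor_prior_given_ibd(r, ibd_count, f_a)
        inner = 0.0
        for dd, p_dd in prior.items():
            p = mixture_allele_prob(r, dd, params.d)
            p_obs_a = p * (1 - params.e_s) + (1 - p) * params.e_s
            p_obs_b = (1 - p) * (1 - params.e_s) + p * params.e_s
            inner += p_dd * p_obs_a**count_a * p_obs_b**count_b
        total += g_emit * inner
    out = float(np.log(total))
    if not np.isfinite(out):
        raise FloatingPointError("non-finite per-SNP log-likelihood")
    return out


# ---------------------------------------------------------------------------
# vectorized driver
# ---------------------------------------------------------------------------

def donor_prior_arrays(f_a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Precompute unordered donor-prior masses as arrays over SNPs.

    Returns ``(dp0, dp1)`` where ``dp0[dg, i]`` is the Hardy-Weinberg mass of
    donor class dg at SNP i and ``dp1[rg, dg, i]`` the IBD-1 conditional mass
    given recipient class rg. The IBD-2 prior is the identity and needs no
    storage.
    """
    f_a = np.asarray(f_a, dtype=np.float64)
    f_b = 1.0 - f_a
    dp0 = np.stack([f_a * f_a, 2.0 * f_a * f_b, f_b * f_b])
    half = np.full_like(f_a, 0.5)
    zero = np.zeros_like(f_a)
    dp1 = np.stack(
        [
            np.stack([f_a, f_b, zero]),
            np.stack([0.5 * f_a, half, 0.5 * f_b]),
            np.stack([zero, f_a, f_b]),
        ]
    )
    return dp0, dp1


def per_snp_loglik(
    obs: np.ndarray,
    count_a: np.ndarray,
    count_b: np.ndarray,
    f_a: np.ndarray,
    d: float,
    e_s: float,
    e_g: float,
    states: tuple[int, ...] = (0,),
    dp: tuple[np.ndarray, np.ndarray] | None = None,
    recipient_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Per-SNP log-likelihood, vectorized over SNPs and IBD states.

    Parameters
    ----------
    obs
        Observed recipient genotype class per SNP (0 = AA, 1 = AB, 2 = BB).
    count_a, count_b
        Reads supporting allele A / allele B per SNP.
    f_a
        Allele-A population frequency per SNP (already clamped).
    states
        IBD counts to evaluate; returns an array of shape (len(states), N).
    dp
        Optional precomputed donor-prior arrays from :func:`donor_prior_arrays`.
    recipient_weights
        Optional (3, N) prior masses over unordered true recipient genotypes
        per SNP (e.g. Hardy-Weinberg masses from the population frequency).
        Defaults to the uniform ordered-pair prior (1/4, 1/2, 1/4).
    """
    obs = np.asarray(obs)
    ka = np.asarray(count_a, dtype=np.float64)
    kb = np.asarray(count_b, dtype=np.float64)
    f_a = np.asarray(f_a, dtype=np.float64)
    if dp is None:
        dp = donor_prior_arrays(f_a)
    dp0, dp1 = dp

    # 3x3 allele-A read probability per (recipient class, donor class), after
    # the sequencing-error channel; classes are B-dosage 0..2.
    dose_a = np.array([1.0, 0.5, 0.0])
    p_mix = d * dose_a[None, :] + (1.0 - d) * dose_a[:, None]
    p_read_a = p_mix * (1.0 - 2.0 * e_s) + e_s
    p_read_b = (1.0 - p_mix) * (1.0 - 2.0 * e_s) + e_s
    log_pa = np.log(p_read_a)
    log_pb = np.log(p_read_b)
    G = genotype_emission_matrix(e_g)
    W = G * UNORDERED_PRIOR[None, :]

    if _NUMBA_KERNEL is not None:
        want = np.zeros(3, dtype=np.bool_)
        for s in states:
            if s not in (0, 1, 2):
                raise ValueError(f"invalid IBD state {s}")
            want[s] = True
        rw = np.empty((0, 0)) if recipient_weights is None else np.ascontiguousarray(recipient_weights)
        full = _NUMBA_KERNEL(
            np.ascontiguousarray(obs, dtype=np.int8),
            ka, kb,
            np.ascontiguousarray(dp0), np.ascontiguousarray(dp1),
            W, G, rw, log_pa.ravel(), log_pb.ravel(), want,
        )
        return full[list(states), :]

    # Read-product exponents, shifted by the per-SNP max for stability.
    X = log_pa.reshape(9, 1) * ka[None, :] + log_pb.reshape(9, 1) * kb[None, :]
    M = X.max(axis=0)
    E = np.exp(X - M[None, :])  # (9, N), rows indexed by rg * 3 + dg

    # weight of each true recipient class given the observation
    if recipient_weights is None:
        Wg = W[obs, :]  # (N, 3)
    else:
        Wg = G[obs, :] * recipient_weights.T

    out = np.empty((len(states), obs.shape[0]))
    for si, state in enumerate(states):
        S = np.zeros_like(M)
        for rg in range(3):
            if state == 0:
                inner = (
                    dp0[0] * E[rg * 3 + 0]
                    + dp0[1] * E[rg * 3 + 1]
                    + dp0[2] * E[rg * 3 + 2]
                )
            elif state == 1:
                inner = (
                    dp1[rg, 0] * E[rg * 3 + 0]
                    + dp1[rg, 1] * E[rg * 3 + 1]
                    + dp1[rg, 2] * E[rg * 3 + 2]
                )
            elif state == 2:
                inner = E[rg * 3 + rg]
            else:
                raise ValueError(f"invalid IBD state {state}")
            S += Wg[:, rg] * inner
        out[si] = M + np.log(S)
    return out


def genotype_marginal_logprob(e_g: float) -> np.ndarray:
    """Log marginal probability of each observed genotype class under the
    uniform ordered-genotype prior, log sum_r P(r) P(R* = o | r; e_g)."""
    W = genotype_emission_matrix(e_g) * UNORDERED_PRIOR[None, :]
    return np.log(W.sum(axis=1))


def zero_coverage_loglik(obs_counts: np.ndarray, e_g: float) -> float:
    """Total log-likelihood of SNPs with no covering reads.

    With an empty read product the per-SNP likelihood reduces to the
    genotype-emission marginal sum_r P(r) P(R* | r; e_g), identical across
    IBD states (donor priors integrate to one). ``obs_counts`` holds the
    number of zero-coverage SNPs per observed class.
    """
    W = genotype_emission_matrix(e_g) * UNORDERED_PRIOR[None, :]
    marg = W.sum(axis=1)
    return float(np.dot(np.asarray(obs_counts, dtype=float), np.log(marg)))


# ---------------------------------------------------------------------------
# optional compiled kernel (identical math; numpy path kept as reference)
# ---------------------------------------------------------------------------

def _build_numba_kernel():
    try:
        import numba
    except ImportError:  # pragma: no cover - numba present in supported envs
        return None

    @numba.njit(cache=True, fastmath=True)
    def kernel(obs, ka, kb, dp0, dp1, W, G, rw, U, V, want):  # pragma: no cover
        n = obs.shape[0]
        use_rw = rw.shape[0] == 3
        out = np.zeros((3, n))
        x = np.empty(9)
        e = np.empty(9)
        w = np.empty(3)
        for i in range(n):
            m = -np.inf
            for c in range(9):
                x[c] = ka[i] * U[c] + kb[i] * V[c]
                if x[c] > m:
                    m = x[c]
            for c in range(9):
                e[c] = np.exp(x[c] - m)
            o = obs[i]
            for rg in range(3):
                w[rg] = G[o, rg] * rw[rg, i] if use_rw else W[o, rg]
            if want[0]:
                s = 0.0
                for rg in range(3):
                    s += w[rg] * (
                        dp0[0, i] * e[rg * 3]
                        + dp0[1, i] * e[rg * 3 + 1]
                        + dp0[2, i] * e[rg * 3 + 2]
                    )
                out[0, i] = m + np.log(s)
            if want[1]:
                s = 0.0
                for rg in range(3):
                    s += w[rg] * (
                        dp1[rg, 0, i] * e[rg * 3]
                        + dp1[rg, 1, i] * e[rg * 3 + 1]
                        + dp1[rg, 2, i] * e[rg * 3 + 2]
                    )
                out[1, i] = m + np.log(s)
            if want[2]:
                s = 0.0
                for rg in range(3):
                    s += w[rg] * e[rg * 3 + rg]
                out[2, i] = m + np.log(s)
        return out

    return kernel


_NUMBA_KERNEL = _build_numba_kernel()
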