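"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by exhaustive enumeration with
plain Python loops, sharing no code with the package's vectorized or
log-space implementations.
"""

import itertools
import math

import numpy as np

ALLELES = ("A", "B")
ORDERED = ("AA", "AB", "BA", "BB")


def geno_emission(observed, true, e_g):
    """Printed genotyping-error kernel; heterozygous observation by
    normalization."""
    n_a = true.count("A")
    if observed == "AA":
        return {2: (1 - e_g) ** 2, 1: 2 * e_g * (1 - e_g), 0: e_g**2}[n_a]
    if observed == "BB":
        return {0: (1 - e_g) ** 2, 1: 2 * e_g * (1 - e_g), 2: e_g**2}[n_a]
    return 1.0 - geno_emission("AA", true, e_g) - geno_emission("BB", true, e_g)


def donor_prior(r, dd, ibd, f_a):
    """Ordered donor-genotype prior given ordered recipient genotype and IBD
    count, from the conditional tables (ordered AB/BA split evenly)."""
    f = {"A": f_a, "B": 1 - f_a}
    if ibd == 0:
        return f[dd[0]] * f[dd[1]]
    unordered_r = "".join(sorted(r))
    unordered_d = "".join(sorted(dd))
    if ibd == 2:
        mass = 1.0 if unordered_d == unordered_r else 0.0
    else:
        table2 = {
            "AA": {"AA": f["A"], "AB": f["B"], "BB": 0.0},
            "AB": {"AA": 0.5 * f["A"], "AB": 0.5, "BB": 0.5 * f["B"]},
            "BB": {"AA": 0.0, "AB": f["A"], "BB": f["B"]},
        }
        mass = table2[unordered_r][unordered_d]
    return mass / 2.0 if unordered_d == "AB" else mass


def snp_lik_bruteforce(observed, reads, d, e_s, e_g, f_a, ibd=None,
                       recipient_prior="uniform"):
    """Per-SNP likelihood by full enumeration over ordered recipient and
    donor genotypes and, per read, the true fragment allele. ``reads`` is a
    sequence of observed alleles like "AABA"."""
    total = 0.0
    for r in ORDERED:
        if recipient_prior == "hw":
            prior_r = (f_a if r[0] == "A" else 1 - f_a) * (
                f_a if r[1] == "A" else 1 - f_a
            )
        else:
            prior_r = 0.25
        p_r = prior_r * geno_emission(observed, r, e_g)
        for dd in ORDERED:
            p_d = donor_prior(r, dd, 0 if ibd is None else ibd, f_a)
            lik_reads = 1.0
            for obs_allele in reads:
                s = 0.0
                for c in ALLELES:
                    p_c = d * (dd.count(c) / 2.0) + (1 - d) * (r.count(c) / 2.0)
                    p_seq = (1 - e_s) if obs_allele == c else e_s
                    s += p_seq * p_c
                lik_reads *= s
            total += p_r * p_d * lik_reads
    return total


def forward_bruteforce(pi, transitions, log_emissions):
    """HMM marginal likelihood by explicit summation over all state paths.

    ``transitions`` is a list of (S, S) matrices (one per boundary),
    ``log_emissions`` an (n_blocks, S) array.
    """
    n, S = log_emissions.shape
    total = 0.0
    for path in itertools.product(range(S), repeat=n):
        p = pi[path[0]] * math.exp(log_emissions[0, path[0]])
        for b in range(1, n):
            p *= transitions[b - 1][path[b - 1], path[b]] * math.exp(
                log_emissions[b, path[b]]
            )
        total += p
    return math.log(total)


def spearman_by_hand(x, y):
    """Spearman rho via the Pearson correlation of midranks."""
    def midranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
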