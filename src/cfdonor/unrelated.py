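"""Genome-wide likelihood and ML fit for unrelated donor-recipient pairs.

The donor is modeled as a random draw from a candidate ancestral population
(Hardy-Weinberg genotype prior from that population's allele frequencies).
SNPs are treated as independent, so the genome log-likelihood is the sum of
per-SNP marginals; the fit minimizes the negative log-likelihood with
bounded L-BFGS-B over (d, e_s, e_g) for each candidate population and keeps
the population attaining the best likelihood.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .likelihood import Workspace
from .model import E_G_MAX, E_G_MIN, E_S_MAX, E_S_MIN, FitOptions, FitResult, ModelParams

_ZD_LO, _ZD_HI = logit(1e-7), logit(1.0 - 1e-7)


def genome_loglik(
    genotypes,
    counts,
    freqs,
    params: ModelParams,
    workspace: Workspace | None = None,
    conditional: bool = True,
    recipient_prior: str = "hw",
) -> float:
    """Genome-wide log-likelihood at a parameter point (unrelated model);
    sum of per-SNP marginals over all usable SNPs."""
    ws = workspace or Workspace.from_tables(
        genotypes, counts, freqs, params.pop, recipient_prior=recipient_prior
    )
    return ws.loglik_unrelated(params.d, params.e_s, params.e_g, conditional=conditional)


def fit_unrelated(
    genotypes,
    counts,
    freqs,
    populations: list[str] | None = None,
    options: FitOptions | None = None,
    workspaces: dict[str, Workspace] | None = None,
    double_for_parent_child: bool = False,
) -> FitResult:
    """Maximum-likelihood estimate of the dd-cfDNA fraction, unrelated model.

    Parameters
    ----------
    populations
        Candidate population columns of ``freqs`` to scan; defaults to all
        non-coordinate columns. Ties are broken by listing order.
    workspaces
        Optional prebuilt per-population workspaces (skips table alignment).
    double_for_parent_child
        If True, report 2 * d_hat in ``metadata["d_hat_parent_child"]``: a
        parent-child donor shares exactly one haploid genome-wide, so the
        unrelated model sees only half of the donor signal. Never applied
        automatically to ``d_hat``.
    """
    options = options or FitOptions()
    if workspaces is None:
        populations = populations or [
            c for c in freqs.columns if c not in ("chrom", "pos", "allele_a", "allele_b", "snp_id")
        ]
        if not populations:
            raise ValueError("no candidate population columns")
        workspaces = {
            pop: Workspace.from_tables(genotypes, counts, freqs, pop)
            for pop in populations
        }
    best: FitResult | None = None
    for pop, ws in workspaces.items():
        res = _fit_single(ws, options)
        if best is None or res.loglik > best.loglik:
            best = res
    if best is None:
        raise ValueError("no candidate populations")
    if double_for_parent_child:
        best.metadata["d_hat_parent_child"] = min(1.0, 2.0 * best.d_hat)
    return best


def _theta_mask(options: FitOptions):
    """(d, e_s, e_g) packing with optional fixed entries.

    Returns (free_idx, unpack) where ``unpack`` maps the free sub-vector in
    transformed coordinates (logit d, log10 errors) to the full triple.
    """
    fixed = (options.fixed_d, options.fixed_e_s, options.fixed_e_g)
    free_idx = [i for i, v in enumerate(fixed) if v is None]

    def unpack(xfree: np.ndarray) -> tuple[float, float, float]:
        out = list(fixed)
        for j, i in enumerate(free_idx):
            out[i] = float(expit(xfree[j])) if i == 0 else float(10.0 ** xfree[j])
        return tuple(out)

    return free_idx, unpack


_THETA_BOUNDS = [
    (_ZD_LO, _ZD_HI),
    (math.log10(E_S_MIN), math.log10(E_S_MAX)),
    (math.log10(E_G_MIN), math.log10(E_G_MAX)),
]


def _theta_start(d0: float, options: FitOptions, free_idx: list[int]) -> np.ndarray:
    full = [logit(min(max(d0, 1e-7), 1 - 1e-7)),
            math.log10(options.e_s0), math.log10(options.e_g0)]
    return np.array([full[i] for i in free_idx])


def _fit_single(ws: Workspace, options: FitOptions) -> FitResult:
    if ws.n_snps_used == 0:
        raise ValueError("no usable SNPs")
    n_evals = 0
    free_idx, unpack = _theta_mask(options)

    def objective(xfree: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        d, e_s, e_g = unpack(xfree)
        return -ws.loglik_unrelated(d, e_s, e_g, conditional=options.conditional)

    bounds = [_THETA_BOUNDS[i] for i in free_idx]
    if options.init == "grid" and options.fixed_d is None:
        d_grid = np.array(
            [1e-4, 5e-4, 2e-3, 8e-3, 0.03, 0.1, 0.25, 0.5, 0.75, 0.92, 0.99]
        )
        vals = [objective(_theta_start(d0, options, free_idx)) for d0 in d_grid]
        starts = [_theta_start(d_grid[int(np.argmin(vals))], options, free_idx)]
    elif options.fixed_d is not None:
        starts = [_theta_start(options.fixed_d, options, free_idx)]
    else:
        starts = [_theta_start(d0, options, free_idx) for d0 in options.d_starts]
    best = None
    for x0 in starts:
        if len(x0) == 0:
            raise ValueError("all parameters fixed; nothing to optimize")
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": options.ftol, "gtol": options.gtol, "maxiter": options.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    d_hat, e_s_hat, e_g_hat = unpack(best.x)
    return FitResult(
        d_hat=d_hat,
        e_s_hat=e_s_hat,
        e_g_hat=e_g_hat,
        pop_hat=ws.pop,
        loglik=float(-best.fun),
        converged=bool(best.success),
        n_snps_used=ws.n_snps_used,
        mode="unrelated",
        metadata={
            "optimizer": "L-BFGS-B",
            "init": options.init,
            "likelihood": "conditional" if options.conditional else "joint",
            "fixed": {"d": options.fixed_d, "e_s": options.fixed_e_s,
                      "e_g": options.fixed_e_g},
            "n_starts": len(starts),
            "n_evals": n_evals,
            "n_missing_genotype": ws.n_missing_genotype,
        },
    )


def calibrate_error_rates(
    workspace: Workspace, options: FitOptions | None = None
) -> tuple[float, float]:
    """Estimate (e_s, e_g) from a pure (pre-transplant) cfDNA sample.

    Fits the unrelated model with the donor fraction pinned at zero, so the
    error rates are identified from the reads alone — the analog of
    measuring the assay background at homozygous sites. The returned rates
    can be passed as ``fixed_e_s`` / ``fixed_e_g`` when fitting the
    post-transplant sample, which removes the error-rate/donor-fraction
    trade-off that inflates d at very low coverage.
    """
    options = options or FitOptions()
    from dataclasses import replace

    fit = _fit_single(workspace, replace(options, fixed_d=0.0, init="multi"))
    return fit.e_s_hat, fit.e_g_hat
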