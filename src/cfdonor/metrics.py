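"""Accuracy metrics for simulated-vs-estimated dd-cfDNA comparisons."""

from __future__ import annotations

import numpy as np
from scipy import stats


def accuracy_metrics(d_true, d_hat) -> dict[str, float]:
    """Summary accuracy of estimates against simulated truth.

    Returns Spearman rank correlation, squared Pearson correlation, mean
    and median absolute error, and the median relative absolute error
    |d_hat - d| / d over strictly positive truths. Correlations of constant
    vectors are undefined and reported as NaN.
    """
    d_true = np.asarray(d_true, dtype=float)
    d_hat = np.asarray(d_hat, dtype=float)
    if d_true.shape != d_hat.shape or d_true.ndim != 1:
        raise ValueError("d_true and d_hat must be equal-length 1-D vectors")
    if d_true.size < 3:
        raise ValueError("need at least 3 points")
    abs_err = np.abs(d_hat - d_true)
    pos = d_true > 0
    out = {
        "mae": float(abs_err.mean()),
        "median_abs_error": float(np.median(abs_err)),
        "max_abs_error": float(abs_err.max()),
        "median_rel_abs_error": float(np.median(abs_err[pos] / d_true[pos]))
        if pos.any()
        else float("nan"),
        "n": int(d_true.size),
    }
    if np.ptp(d_true) == 0 or np.ptp(d_hat) == 0:
        out["spearman_rho"] = float("nan")
        out["pearson_r2"] = float("nan")
    else:
        out["spearman_rho"] = float(stats.spearmanr(d_true, d_hat).statistic)
        out["pearson_r2"] = float(stats.pearsonr(d_true, d_hat).statistic ** 2)
    return out


def chimerism_divergence(plasma_fit, cellular_fit) -> float:
    """Signed difference of recipient-derived fractions between the plasma
    (cell-free) and cellular compartments of the same subject:
    (1 - d_plasma) - (1 - d_cellular). Positive values flag excess
    recipient-derived cfDNA relative to blood cells (tissue-injury-like
    pattern); this is a number, not a diagnosis."""
    return float((1.0 - plasma_fit.d_hat) - (1.0 - cellular_fit.d_hat))
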