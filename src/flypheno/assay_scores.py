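"""Organism-level assay scores: SING climbing, seizure percentage, OLS correlation.

The startle-induced negative geotaxis (SING) score summarizes climbing
performance of a tapped-down fly group distributed over five stacked tubes
(tube 1 = bottom):

    score = (N1*0 + N2*1 + N3*2 + N4*3 + N5*4) / (4 * sum(N))

so all flies at the bottom score 0 and all at the top score 1.  Scores are
normalized to the control group's mean.  Seizure assays report the
percentage of flies without seizure-like behavior after mechanical
hyper-stimulation.  Genotype-level associations between assays are plain
OLS fits with R^2, a slope p-value and a 95% confidence band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm


def sing_score(counts) -> float:
    """Climbing score in [0, 1] from the five per-tube fly counts."""
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (5,):
        raise ValueError("expected counts for exactly 5 tubes")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("no flies counted")
    return float(np.dot(counts, np.arange(5)) / (4.0 * total))


def normalize_score(score: float, control_scores) -> float:
    """Score relative to the mean control score."""
    control_mean = float(np.mean(control_scores))
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    return float(score) / control_mean


def seizure_free_pct(n_without: int, n_total: int) -> float:
    """Percentage of flies without seizure-like behavior."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_without <= n_total:
        raise ValueError("n_without must lie in [0, n_total]")
    return 100.0 * n_without / n_total


def genotype_correlation(x, y, conf: float = 0.95) -> dict:
    """OLS of per-genotype means y on x with R^2, slope p and confidence band.

    Returns a dict with keys ``r2, p_value, slope, intercept, band`` where
    ``band`` is a DataFrame (x, fit, lower, upper) on a 100-point grid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x/y with at least 3 genotypes")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 100)
    pred = fit.get_prediction(sm.add_constant(grid)).summary_frame(alpha=1 - conf)
    band = pd.DataFrame({"x": grid, "fit": pred["mean"],
                         "lower": pred["mean_ci_lower"],
                         "upper": pred["mean_ci_upper"]})
    return {"r2": float(fit.rsquared), "p_value": float(fit.pvalues[1]),
            "slope": float(fit.params[1]), "intercept": float(fit.params[0]),
            "band": band}
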