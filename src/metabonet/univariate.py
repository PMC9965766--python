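"""Per-metabolite two-group Student's t-tests with BH-FDR control."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import AbundanceMatrix, GroupPair

__all__ = ["UnivariateResult", "t_test_all", "benjamini_hochberg"]

FDR_ALPHA = 0.05


@dataclass
class UnivariateResult:
    metabolite: str
    pair: GroupPair
    t_statistic: float
    p_value: float
    q_value: float
    significant: bool
    mean_a: float
    mean_b: float


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if not np.isfinite(p).all() or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must be finite and within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def t_test_all(
    data: AbundanceMatrix,
    pair: GroupPair,
    *,
    welch: bool = False,
    alpha: float = FDR_ALPHA,
) -> list[UnivariateResult]:
    """Two-sided t-test per metabolite, BH-adjusted within the comparison.

    Pooled-variance Student's t by default (``welch=True`` switches to
    Welch).  Metabolites with zero pooled variance get t=0, p=1 with a
    warning rather than NaN.  The BH family is all metabolites of this
    single pairwise comparison.
    """
    pair.validate_in(data)
    a = data.group_values(pair.group_a)
    b = data.group_values(pair.group_b)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("each group needs at least 3 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        names = [m for m, d in zip(data.metabolite_names, degenerate) if d]
        warnings.warn(f"zero pooled variance; p set to 1 for: {names}")
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    q = benjamini_hochberg(p)
    mean_a = a.mean(axis=0)
    mean_b = b.mean(axis=0)
    return [
        UnivariateResult(
            metabolite=m,
            pair=pair,
            t_statistic=float(t[j]),
            p_value=float(p[j]),
            q_value=float(q[j]),
            significant=bool(q[j] < alpha),
            mean_a=float(mean_a[j]),
            mean_b=float(mean_b[j]),
        )
        for j, m in enumerate(data.metabolite_names)
    ]
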