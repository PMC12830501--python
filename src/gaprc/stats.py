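"""Paired nonparametric comparison statistics.

Per-lesion percentage changes between reconstructions are screened for
normality with the D'Agostino-Pearson omnibus test and compared with the
two-sided Wilcoxon signed-rank test; p-values are Bonferroni-adjusted at a
family-wise significance level of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PairedChangeResult",
    "percent_change",
    "dagostino_pearson",
    "wilcoxon_signed_rank",
    "bonferroni",
    "paired_change_test",
]

ALPHA = 0.05


@dataclass
class PairedChangeResult:
    """Outcome of one paired percentage-change comparison."""

    metric: str
    comparison: str
    changes: np.ndarray  # per-lesion percent changes
    median_change: float
    p_value: float
    p_adjusted: float
    n_comparisons: int
    significant: bool
    normality_p: float = float("nan")

    def __post_init__(self):
        self.changes = np.asarray(self.changes, dtype=np.float64)
        if not np.isfinite(self.changes).all():
            raise ValueError("percent changes must be finite")


def percent_change(new: float, ref: float):
    """100 * (new - ref) / ref; ``ref`` must be nonzero (elementwise)."""
    new = np.asarray(new, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if np.any(ref == 0):
        raise ValueError("reference value must be nonzero")
    out = 100.0 * (new - ref) / ref
    return float(out) if out.ndim == 0 else out


def dagostino_pearson(values) -> float:
    """D'Agostino-Pearson omnibus normality p-value (K^2 vs chi^2, 2 df).

    Requires n >= 8 for the skewness/kurtosis component tests.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 8:
        raise ValueError("D'Agostino-Pearson requires n >= 8")
    return float(sstats.normaltest(values).pvalue)


def wilcoxon_signed_rank(diffs, pairs=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value.

    Accepts either differences or two paired samples. Zero differences are
    dropped before ranking (Wilcoxon's original procedure); the exact null
    distribution is used for n <= 25 without ties, the tie-corrected normal
    approximation otherwise.
    """
    if pairs is not None:
        diffs = np.asarray(diffs, dtype=np.float64) - np.asarray(
            pairs, dtype=np.float64)
    else:
        diffs = np.asarray(diffs, dtype=np.float64)
    diffs = diffs[diffs != 0.0]
    if diffs.size < 1:
        raise ValueError("no nonzero differences")
    has_ties = np.unique(np.abs(diffs)).size < diffs.size
    method = "exact" if (diffs.size <= 25 and not has_ties) else "approx"
    res = sstats.wilcoxon(diffs, alternative="two-sided", method=method,
                          correction=(method == "approx"),
                          zero_method="wilcox")
    return float(res.pvalue)


def bonferroni(p_values, m: int):
    """Bonferroni adjustment: p * m clipped at 1."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(p_values, dtype=np.float64)
    out = np.minimum(p * m, 1.0)
    return float(out) if out.ndim == 0 else out


def paired_change_test(
    new_values,
    ref_values,
    metric: str,
    comparison: str,
    n_comparisons: int = 1,
    alpha: float = ALPHA,
) -> PairedChangeResult:
    """Percentage changes of paired metric values plus signed-rank inference."""
    new_values = np.asarray(new_values, dtype=np.float64)
    ref_values = np.asarray(ref_values, dtype=np.float64)
    changes = percent_change(new_values, ref_values)
    changes = np.atleast_1d(changes)
    try:
        norm_p = dagostino_pearson(changes)
    except ValueError:
        norm_p = float("nan")
    if np.all(changes == 0):
        p = 1.0
    else:
        p = wilcoxon_signed_rank(changes)
    p_adj = bonferroni(p, n_comparisons)
    return PairedChangeResult(
        metric=metric,
        comparison=comparison,
        changes=changes,
        median_change=float(np.median(changes)),
        p_value=p,
        p_adjusted=p_adj,
        n_comparisons=n_comparisons,
        significant=bool(p_adj < alpha),
        normality_p=norm_p,
    )
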