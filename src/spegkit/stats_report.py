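"""Statistical surface: fold changes, normalization, one-tailed Wilcoxon
signed-rank test, and median/IQR summaries.

Conventions follow the original analyses: frequencies are normalized to the
regular-pegRNA condition (set to 1), comparisons use the one-tailed Wilcoxon
signed-rank test (default alternative: engineered guide greater than
control), zero differences are dropped before ranking, and summaries report
the median with the interquartile range. The exact p-value is computed from
the full null distribution of the signed-rank sum (equivalent to
enumerating all 2^m sign assignments) when m <= 25 and the absolute
differences are untied; otherwise a normal approximation with tie and
continuity corrections is used.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .errors import DegenerateTestError, UndefinedFoldError, ValidationError


def fold_change(treated: float, control: float, floor: float | None = None) -> float:
    """treated / control, with an optional floor on the control value.

    The floor documents arithmetic such as 49.76% / 0.01% = 4976-fold when a
    near-zero control is reported at its printed precision.
    """
    if treated < 0:
        raise ValidationError("treated value must be >= 0")
    denom = control if floor is None else max(control, floor)
    if denom <= 0:
        raise UndefinedFoldError("control is <= 0 and no floor is set")
    return treated / denom


def normalize_to_reference(values: Sequence[float], reference_values: Sequence[float],
                           floor: float | None = None) -> np.ndarray:
    """Element-wise value / reference (reference condition normalized to 1)."""
    values = np.asarray(values, dtype=float)
    refs = np.asarray(reference_values, dtype=float)
    if values.shape != refs.shape:
        raise ValidationError("values and references must have equal length")
    return np.array([fold_change(v, r, floor) for v, r in zip(values, refs)])


def _signed_rank_null_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of sign assignments per positive-rank sum (generating-poly DP)."""
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_one_tailed(pairs: Iterable[tuple[float, float]],
                                    alternative: str = "greater") -> float:
    """One-tailed Wilcoxon signed-rank p-value for paired measurements.

    `alternative='greater'` tests whether the first member of each pair
    exceeds the second. Zero differences are dropped (Wilcoxon's original
    treatment); tied absolute differences get mid-ranks.
    """
    if alternative not in ("greater", "less"):
        raise ValidationError("alternative must be 'greater' or 'less'")
    pairs = list(pairs)
    diffs = np.array([a - b for a, b in pairs], dtype=float)
    diffs = diffs[diffs != 0]
    m = len(diffs)
    if m == 0:
        raise DegenerateTestError("all paired differences are zero")
    absd = np.abs(diffs)
    ranks = _scipy_stats.rankdata(absd)
    w_plus = float(ranks[diffs > 0].sum())
    has_ties = len(np.unique(absd)) < m
    if m <= 25 and not has_ties:
        counts = _signed_rank_null_counts(ranks)
        total = counts.sum()  # == 2^m
        w = int(round(w_plus))
        if alternative == "greater":
            return float(counts[w:].sum() / total)
        return float(counts[:w + 1].sum() / total)
    mean = m * (m + 1) / 4.0
    tie_sizes = np.array([np.sum(absd == u) for u in np.unique(absd)])
    var = m * (m + 1) * (2 * m + 1) / 24.0 - np.sum(tie_sizes ** 3 - tie_sizes) / 48.0
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        return float(_scipy_stats.norm.sf(z))
    z = (w_plus - mean + 0.5) / sd
    return float(_scipy_stats.norm.cdf(z))


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("median_iqr needs at least one value")
    med, q1, q3 = np.percentile(values, [50, 25, 75])
    return float(med), float(q1), float(q3)


def comparison_summary(control: Sequence[float], treated: Sequence[float],
                       floor: float | None = None,
                       alternative: str = "greater") -> dict:
    """Normalized frequencies, fold change summary and signed-rank p-value."""
    normalized = normalize_to_reference(treated, control, floor)
    med, q1, q3 = median_iqr(normalized)
    p = wilcoxon_signed_rank_one_tailed(zip(treated, control), alternative)
    return {
        "n": len(normalized),
        "normalized": normalized.tolist(),
        "median_fold": med,
        "iqr": (q1, q3),
        "mean_fold": float(np.mean(normalized)),
        "p_value": p,
        "alternative": alternative,
    }
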