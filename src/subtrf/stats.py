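"""Group-level statistics for predictor comparisons.

Wave V SNRs across participants are skewed (the 0 dB floor creates ties and
zeros), so pairwise predictor contrasts use two-tailed Wilcoxon signed-rank
tests — reporting T, the rank sum of positive differences — with
Holm-Bonferroni correction over the family of contrasts actually run.
Consistency of per-participant metrics across predictors is quantified with
Pearson correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class StatTestResult:
    pair: tuple
    T: float
    p_raw: float
    p_holm: float | None
    n_subjects: int
    degenerate: bool = False


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test on paired samples.

    Returns ``(T, p)`` where T is the sum of the ranks of the positive
    differences ``a - b`` (zero differences dropped, ties given average
    ranks).  The p-value is exact for n <= 25 without ties, otherwise a
    normal approximation is used.  If every difference is zero, returns
    ``(nan, 1.0)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return float("nan"), 1.0
    ranks = sps.rankdata(np.abs(d))
    t_plus = float(ranks[d > 0].sum())
    method = "exact" if (d.size <= 25 and np.unique(np.abs(d)).size == d.size) else "approx"
    res = sps.wilcoxon(d, alternative="two-sided", method=method)
    return t_plus, float(res.pvalue)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for k, idx in enumerate(order):
        running = max(running, min(1.0, (m - k) * p[idx]))
        adjusted[idx] = running
    return adjusted


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-tailed p-value (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def pairwise_predictor_tests(
    metric_by_kind: dict, contrasts: list[tuple[str, str]]
) -> list[StatTestResult]:
    """Wilcoxon tests for each contrast, Holm-corrected over the family.

    ``metric_by_kind`` maps predictor kind -> per-participant metric array;
    participants must be aligned across kinds (exclude incomplete ones
    upstream).
    """
    results = []
    for ka, kb in contrasts:
        a, b = np.asarray(metric_by_kind[ka]), np.asarray(metric_by_kind[kb])
        t, p = wilcoxon_signed_rank(a, b)
        results.append(
            StatTestResult(
                pair=(ka, kb),
                T=t,
                p_raw=p,
                p_holm=None,
                n_subjects=int(a.size),
                degenerate=np.isnan(t),
            )
        )
    adj = holm_bonferroni([r.p_raw for r in results])
    for r, pa in zip(results, adj):
        r.p_holm = float(pa)
    return results
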