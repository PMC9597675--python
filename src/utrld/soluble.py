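"""Nonparametric and parametric statistics for soluble HLA-G and clinical data.

Soluble HLA-G plasma levels are right-skewed, so groups are summarized by
the median with a distribution-free Hodges–Lehmann 95% confidence interval
(order statistics of the Walsh averages at ranks from the signed-rank
null) and compared with the Wilcoxon rank-sum test. Correlations with
biochemical markers use Kendall's tau-b. Clinical baseline tables compare
continuous variables with Student's t-test (mean +/- SD, t-based CI) and
categorical variables with Fisher's exact test (n (%), normal-approximation
CI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import SubjectRecord

_EXACT_RANKSUM_MAX = 25  # exact rank-sum null up to this combined n, no ties
_EXACT_SIGNRANK_MAX = 50  # exact signed-rank null for the Hodges–Lehmann CI


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) P value.

    Exact null distribution when the combined sample size is small and tie
    free; otherwise the normal approximation with tie and continuity
    corrections. Two identical constant samples give P = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0.0:
        return 1.0
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= _EXACT_RANKSUM_MAX and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass(frozen=True)
class MedianSummary:
    median: float
    ci_low: float | None
    ci_high: float | None
    n: int


def _signed_rank_cdf(n: int) -> np.ndarray:
    """Exact null CDF of the one-sample signed-rank statistic W+ for size n."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1, dtype=float)
    counts[0] = 1.0
    for i in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[i:] = counts[:-i] if i > 0 else counts
        counts = counts + shifted
    return np.cumsum(counts) / 2.0**n


def _hl_rank(n: int, alpha: float) -> int:
    """Largest k with P0(W+ <= k) <= alpha/2; -1 if even k=0 exceeds it."""
    if n <= _EXACT_SIGNRANK_MAX:
        cdf = _signed_rank_cdf(n)
        k = int(np.searchsorted(cdf, alpha / 2.0, side="right")) - 1
        return k
    mean = n * (n + 1) / 4.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = stats.norm.ppf(alpha / 2.0)
    return max(-1, int(math.floor(mean + z * sd - 0.5)))


def walsh_averages(x: Sequence[float]) -> np.ndarray:
    """Sorted pairwise means (x_i + x_j)/2 over i <= j: n(n+1)/2 values."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    sums = np.add.outer(x, x) / 2.0
    iu = np.triu_indices(n)
    return np.sort(sums[iu])


def hodges_lehmann_ci(x: Sequence[float], alpha: float = 0.05) -> MedianSummary:
    """Sample median with the Hodges–Lehmann (1-alpha) confidence interval.

    The interval endpoints are order statistics of the Walsh averages at the
    ranks given by the signed-rank null distribution (exact for n <= 50,
    normal approximation above). The summary point is the sample median.
    A single observation yields no interval.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 1:
        raise ValueError("sample must be non-empty")
    med = float(np.median(x))
    if n < 2:
        return MedianSummary(med, None, None, n)
    w = walsh_averages(x)
    m = len(w)
    k = _hl_rank(n, alpha)
    if k < 0:
        # n too small for the requested confidence: widest attainable interval
        return MedianSummary(med, float(w[0]), float(w[-1]), n)
    return MedianSummary(med, float(w[k]), float(w[m - 1 - k]), n)


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None]:
    """Kendall's tau-b with two-sided P (exact for small tie-free samples).

    A constant margin leaves tau undefined; (None, None) is returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("paired samples of equal length >= 3 required")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return None, None
    no_ties = len(np.unique(x)) == len(x) and len(np.unique(y)) == len(y)
    method = "exact" if (len(x) <= 10 and no_ties) else "asymptotic"
    res = stats.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Group-comparison report (clinical baseline table shape)


@dataclass
class GroupCompareRow:
    variable: str
    kind: str  # "continuous" | "categorical" | "shlag"
    n1: int
    summary1: str
    ci1: str
    n2: int
    summary2: str
    ci2: str
    p: float | None
    test: str
    note: str | None = None


def _t_ci(values: np.ndarray, alpha: float) -> tuple[float, float]:
    n = len(values)
    mean = values.mean()
    if n < 2:
        return mean, mean
    half = stats.t.ppf(1 - alpha / 2.0, n - 1) * values.std(ddof=1) / math.sqrt(n)
    return mean - half, mean + half


def _prop_ci(k: int, n: int, alpha: float) -> tuple[float, float]:
    p = k / n
    half = stats.norm.ppf(1 - alpha / 2.0) * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def _is_binary(values: list) -> bool:
    return all(isinstance(v, (bool, np.bool_)) or v in (0, 1) for v in values)


GROUPINGS: dict[str, Callable[[SubjectRecord], bool | None]] = {
    # severe-inflammation patients vs all remaining patients
    "severe_vs_rest": lambda s: (s.inflammation == "severe") if s.cohort == "patient" else None,
    "patient_vs_control": lambda s: s.cohort == "patient",
    "utr1": lambda s: s.utr1_carrier,
}


def group_compare(
    records: Iterable[SubjectRecord],
    grouping: str | Callable[[SubjectRecord], bool | None] = "severe_vs_rest",
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
    equal_var: bool = True,
    missing_warn_fraction: float = 0.5,
) -> pd.DataFrame:
    """Two-group clinical comparison table.

    The grouping selector maps each subject to True (group 1), False
    (group 2) or None (excluded). Continuous variables get mean +/- SD, a
    t-based CI of the mean and a two-sided t-test; binary variables get
    n (%), a normal-approximation CI and Fisher's exact test; soluble HLA-G
    additionally gets a median with Hodges–Lehmann CI and a Wilcoxon P.
    Variables missing in more than half of a group are flagged.
    """
    selector = GROUPINGS[grouping] if isinstance(grouping, str) else grouping
    records = list(records)
    g1 = [s for s in records if selector(s) is True]
    g2 = [s for s in records if selector(s) is False]
    if not g1 or not g2:
        raise ValueError("grouping must yield two non-empty groups")

    if variables is None:
        seen: dict[str, None] = {}
        for s in g1 + g2:
            for v in s.clinical:
                seen.setdefault(v)
        variables = list(seen)

    rows: list[GroupCompareRow] = []

    def _pull(group: list[SubjectRecord], var: str) -> list:
        return [s.clinical[var] for s in group if s.clinical.get(var) is not None]

    # soluble HLA-G row first, mirroring its prominence in the study table
    sh1 = np.array([s.shlag for s in g1 if s.shlag is not None], dtype=float)
    sh2 = np.array([s.shlag for s in g2 if s.shlag is not None], dtype=float)
    if len(sh1) and len(sh2):
        hl1 = hodges_lehmann_ci(sh1, alpha)
        hl2 = hodges_lehmann_ci(sh2, alpha)
        rows.append(
            GroupCompareRow(
                "sHLA_G", "shlag",
                len(sh1),
                f"{sh1.mean():.2f} ± {sh1.std(ddof=1):.2f}; median {hl1.median:.1f}",
                f"{hl1.ci_low:.1f} – {hl1.ci_high:.1f}",
                len(sh2),
                f"{sh2.mean():.2f} ± {sh2.std(ddof=1):.2f}; median {hl2.median:.1f}",
                f"{hl2.ci_low:.1f} – {hl2.ci_high:.1f}",
                wilcoxon_rank_sum(sh1, sh2),
                "wilcoxon",
            )
        )

    for var in variables:
        v1 = _pull(g1, var)
        v2 = _pull(g2, var)
        note = None
        if len(v1) < len(g1) * missing_warn_fraction or len(v2) < len(g2) * missing_warn_fraction:
            note = "missing in >50% of a group"
        if not v1 or not v2:
            rows.append(GroupCompareRow(var, "missing", len(v1), "", "", len(v2), "", "",
                                        None, "none", note or "no data"))
            continue
        if _is_binary(v1 + v2):
            k1, k2 = sum(map(bool, v1)), sum(map(bool, v2))
            lo1, hi1 = _prop_ci(k1, len(v1), alpha)
            lo2, hi2 = _prop_ci(k2, len(v2), alpha)
            table = [[k1, len(v1) - k1], [k2, len(v2) - k2]]
            p = float(stats.fisher_exact(table).pvalue)
            rows.append(
                GroupCompareRow(
                    var, "categorical",
                    len(v1), f"{k1} ({100 * k1 / len(v1):.1f})", f"{100 * lo1:.1f} – {100 * hi1:.1f}",
                    len(v2), f"{k2} ({100 * k2 / len(v2):.1f})", f"{100 * lo2:.1f} – {100 * hi2:.1f}",
                    p, "fisher", note,
                )
            )
        else:
            a1 = np.asarray(v1, dtype=float)
            a2 = np.asarray(v2, dtype=float)
            lo1, hi1 = _t_ci(a1, alpha)
            lo2, hi2 = _t_ci(a2, alpha)
            if np.ptp(np.concatenate([a1, a2])) == 0.0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(a1, a2, equal_var=equal_var).pvalue)
            sd1 = a1.std(ddof=1) if len(a1) > 1 else 0.0
            sd2 = a2.std(ddof=1) if len(a2) > 1 else 0.0
            rows.append(
                GroupCompareRow(
                    var, "continuous",
                    len(a1), f"{a1.mean():.1f} ± {sd1:.1f}", f"{lo1:.1f} – {hi1:.1f}",
                    len(a2), f"{a2.mean():.1f} ± {sd2:.1f}", f"{lo2:.1f} – {hi2:.1f}",
                    p, "t-test" if equal_var else "welch", note,
                )
            )

    return pd.DataFrame([r.__dict__ for r in rows])
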