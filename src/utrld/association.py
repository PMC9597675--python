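"""Two-cohort haplotype/allele association statistics.

For each haplotype key the two cohorts contribute a 2x2 table of carrier
chromosomes vs the rest (columns a, b = 2N1-a in group 1 and c, d = 2N2-c
in group 2). The module reports frequencies, a two-sided P value, the odds
ratio with a 95% confidence interval, and a Bonferroni-corrected P.

Two P-value conventions are provided. ``fisher_two_sided`` is the exact
Fisher test with the point-probability two-sided rule. ``two_proportion_z``
is the pooled two-proportion z-test with 0.5 added to empty cells; this is
the convention that reproduces the published frequency tables digit for
digit and is therefore the default in :func:`associate` ("as-published").

Odds ratios default to the sample OR with Woolf's logit confidence
interval; empty cells receive +0.5 (the zero cells only, not all four —
the all-cell Haldane–Anscombe variant does not reproduce the published
zero-cell row). An exact conditional-MLE OR with its exact interval (the
convention of R's ``fisher.test``) is available as ``method="conditional"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from scipy import stats

from .haplotypes import CohortHaplotypeTable

Z975 = stats.norm.ppf  # used with 1 - alpha/2


class ContingencyCounts(NamedTuple):
    """2x2 counts: a/b = group 1 with/without the feature, c/d = group 2."""

    a: int
    b: int
    c: int
    d: int

    def validate(self) -> "ContingencyCounts":
        if any(x < 0 or int(x) != x for x in self):
            raise ValueError(f"counts must be non-negative integers: {self}")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError(f"each group must contain at least one chromosome: {self}")
        return self


def fisher_two_sided(t: ContingencyCounts) -> float:
    """Exact Fisher two-sided P (point-probability rule).

    Sums the probabilities of all tables with the observed margins whose
    hypergeometric probability does not exceed that of the observed table.
    Degenerate feature margins (a+c = 0 or b+d = 0) give P = 1 by convention.
    """
    a, b, c, d = ContingencyCounts(*t).validate()
    if a + c == 0 or b + d == 0:
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)


def two_proportion_z(t: ContingencyCounts, pooled: bool = True) -> float:
    """Two-sided pooled two-proportion z-test P with the 0.5 zero-cell rule.

    Empty cells are replaced by 0.5 in the numerators (group sizes are kept
    as observed). Identical proportions give P = 1.
    """
    a, b, c, d = ContingencyCounts(*t).validate()
    n1 = a + b
    n2 = c + d
    a_adj = a if a > 0 else 0.5
    c_adj = c if c > 0 else 0.5
    if b == 0:
        a_adj = n1 - 0.5
    if d == 0:
        c_adj = n2 - 0.5
    p1 = a_adj / n1
    p2 = c_adj / n2
    if pooled:
        p = (a_adj + c_adj) / (n1 + n2)
        var = p * (1.0 - p) * (1.0 / n1 + 1.0 / n2)
    else:
        var = p1 * (1.0 - p1) / n1 + p2 * (1.0 - p2) / n2
    if var == 0.0:
        return 1.0
    z = (p1 - p2) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class OddsRatioCI:
    or_est: float | None
    ci_low: float | None
    ci_high: float | None
    note: str | None = None


def odds_ratio_ci(
    t: ContingencyCounts, alpha: float = 0.05, method: str = "woolf"
) -> OddsRatioCI:
    """Odds ratio (group-1 odds over group-2 odds) with a (1-alpha) CI.

    method="woolf": sample OR with the log-scale Woolf interval,
    exp(ln OR +/- z * sqrt(1/a+1/b+1/c+1/d)); cells equal to zero receive
    +0.5 (zero cells only) in both the estimate and the variance.

    method="conditional": conditional maximum-likelihood OR with the exact
    interval from the noncentral hypergeometric distribution.

    Two zero cells on a diagonal leave the OR undefined; the result then
    carries a diagnostic note instead of numbers.
    """
    a, b, c, d = ContingencyCounts(*t).validate()
    if (a == 0 and d == 0) or (b == 0 and c == 0):
        return OddsRatioCI(None, None, None, note="two zero cells on a diagonal: OR undefined")
    if method == "conditional":
        res = stats.contingency.odds_ratio([[a, b], [c, d]], kind="conditional")
        ci = res.confidence_interval(1.0 - alpha)
        return OddsRatioCI(float(res.statistic), float(ci.low), float(ci.high))
    if method != "woolf":
        raise ValueError(f"unknown odds-ratio method {method!r}")
    aa, bb, cc, dd = (x if x > 0 else 0.5 for x in (a, b, c, d))
    or_est = (aa * dd) / (bb * cc)
    se = math.sqrt(1.0 / aa + 1.0 / bb + 1.0 / cc + 1.0 / dd)
    z = float(Z975(1.0 - alpha / 2.0))
    log_or = math.log(or_est)
    return OddsRatioCI(or_est, math.exp(log_or - z * se), math.exp(log_or + z * se))


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m*p)."""
    if m < 1:
        raise ValueError(f"test count m must be >= 1, got {m}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be a probability, got {p}")
    return min(1.0, m * p)


@dataclass
class AssociationRow:
    """One haplotype key's two-cohort association summary."""

    key: object
    n1: int
    f1: float
    n2: int
    f2: float
    p: float
    or_est: float | None
    ci_low: float | None
    ci_high: float | None
    pc: float | None = None
    note: str | None = None


def _auto_m(keys: Iterable[object], t1: CohortHaplotypeTable, t2: CohortHaplotypeTable) -> int:
    return sum(1 for k in keys if t1.counts.get(k, 0) > 0 and t2.counts.get(k, 0) > 0)


def associate(
    table1: CohortHaplotypeTable,
    table2: CohortHaplotypeTable,
    m: int | str = "shared_nonzero",
    alpha: float = 0.05,
    p_method: str = "as_published",
    or_method: str = "woolf",
    pc_policy: str = "printed",
) -> list[AssociationRow]:
    """Associate every haplotype key across two cohorts.

    The key universe is the union of both tables (absent keys count 0); rows
    are sorted by descending cohort-1 count. The odds ratio is oriented as
    cohort-2 odds over cohort-1 odds (in the published layout cohort 1 is
    the control panel, so OR < 1 means rarer in patients).

    Bonferroni multiplier ``m``: "shared_nonzero" counts keys non-zero in
    BOTH cohorts (the factor used for the UTR haplotype table),
    "all_rows" counts every row (the factor used for the extended-haplotype
    table), or pass an explicit integer. The corrected P is reported only
    for rows with p < alpha. pc_policy="printed" multiplies the P rounded
    to 3 decimals (matching the published corrected values); "exact"
    multiplies the raw P.
    """
    keys = sorted(
        set(table1.counts) | set(table2.counts),
        key=lambda k: (-table1.counts.get(k, 0), -table2.counts.get(k, 0), str(k)),
    )
    if isinstance(m, str):
        if m == "shared_nonzero":
            m_val = _auto_m(keys, table1, table2)
        elif m == "all_rows":
            m_val = len(keys)
        else:
            raise ValueError(f"unknown Bonferroni mode {m!r}")
    else:
        m_val = int(m)

    rows: list[AssociationRow] = []
    for k in keys:
        n1 = table1.counts.get(k, 0)
        n2 = table2.counts.get(k, 0)
        counts = ContingencyCounts(n2, table2.two_n - n2, n1, table1.two_n - n1)
        if p_method == "as_published":
            p = two_proportion_z(counts)
        elif p_method == "fisher":
            p = fisher_two_sided(counts)
        else:
            raise ValueError(f"unknown p-value method {p_method!r}")
        orci = odds_ratio_ci(counts, alpha=alpha, method=or_method)
        pc = None
        if m_val >= 1 and p < alpha:
            p_for_pc = round(p, 3) if pc_policy == "printed" else p
            pc = bonferroni(p_for_pc, m_val)
        rows.append(
            AssociationRow(
                key=k,
                n1=n1,
                f1=n1 / table1.two_n,
                n2=n2,
                f2=n2 / table2.two_n,
                p=p,
                or_est=orci.or_est,
                ci_low=orci.ci_low,
                ci_high=orci.ci_high,
                pc=pc,
                note=orci.note,
            )
        )
    return rows
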