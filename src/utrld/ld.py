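"""Two-locus linkage disequilibrium and the two-cohort LD contrast.

For a marker pair (A, B) on the same chromosome, D is the difference
between the observed joint frequency and the product of the within-cohort
marginal frequencies, and D' is D normalized by its margin-constrained
maximum (Lewontin), so -1 <= D' <= 1.

Each cohort's departure from linkage equilibrium is summarized by a
Yates-continuity-corrected chi-square comparing the observed joint count
against the expected count (the expected frequency times 2N, rounded to
the nearest integer) in a 2x2 layout of [joint, rest] x [observed,
expected]. The two cohorts are then contrasted "as published": the
difference of the two 1-df statistics is referred to a chi-square with two
degrees of freedom. That reference distribution is not a standard result
for a difference of chi-square variables, so a seeded permutation contrast
(cohort-label shuffling) is offered as a statistically defensible
alternative; see docs/methods.md.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .records import Chromosome, SubjectRecord


@dataclass(frozen=True)
class TwoLocusObservation:
    """Per-cohort margins and joint count for one marker pair."""

    two_n: int
    p_a: float
    p_b: float
    n_ab: int

    def __post_init__(self) -> None:
        if self.two_n <= 0:
            raise ValueError("2N must be positive")
        if not (0.0 <= self.p_a <= 1.0 and 0.0 <= self.p_b <= 1.0):
            raise ValueError(f"marginal frequencies must lie in [0,1]: {self.p_a}, {self.p_b}")
        if not 0 <= self.n_ab <= self.two_n:
            raise ValueError(f"joint count {self.n_ab} outside [0, {self.two_n}]")

    @property
    def f_ab_obs(self) -> float:
        return self.n_ab / self.two_n


@dataclass(frozen=True)
class LDResult:
    """One cohort's LD summary for a marker pair."""

    f_ab_exp: float
    n_exp: int
    d: float
    d_prime: float | None
    chi2: float | None
    note: str | None = None


@dataclass(frozen=True)
class LDContrast:
    """Cross-cohort contrast of the two per-cohort chi-square statistics."""

    chi2_1: float
    chi2_2: float
    delta: float
    p: float
    negative_delta: bool = False


def lewontin_d(p_a: float, p_b: float, f_ab: float) -> tuple[float, float | None]:
    """Lewontin's D and D' for a two-locus haplotype.

    D = f_AB - p_A*p_B. D' divides D by its maximum attainable magnitude
    given the margins: min(p_A(1-p_B), (1-p_A)p_B) for D > 0 and
    min(p_A*p_B, (1-p_A)(1-p_B)) for D < 0. D = 0 gives D' = 0. Fixed
    margins (p in {0,1}) make D' undefined (returned as None) unless D = 0.
    """
    if not (0.0 <= p_a <= 1.0 and 0.0 <= p_b <= 1.0):
        raise ValueError("marginal frequencies must lie in [0,1]")
    if f_ab > min(p_a, p_b) + 1e-9 or f_ab < max(0.0, p_a + p_b - 1.0) - 1e-9:
        raise ValueError(
            f"joint frequency {f_ab} incompatible with margins ({p_a}, {p_b})"
        )
    d = f_ab - p_a * p_b
    if d == 0.0:
        return 0.0, 0.0
    if d > 0:
        d_max = min(p_a * (1.0 - p_b), (1.0 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1.0 - p_a) * (1.0 - p_b))
    if d_max <= 0.0:
        return d, None
    return d, d / d_max


def cohort_chi2(n_obs: int, f_exp: float, two_n: int) -> float:
    """Yates-corrected chi-square of observed vs expected joint counts.

    The expected count is round(f_exp * 2N) to the nearest integer; the
    statistic is the continuity-corrected chi-square of the 2x2 table
    [[n_obs, 2N-n_obs], [n_exp, 2N-n_exp]]. An expected count of 0 or 2N
    leaves the statistic undefined (ValueError).
    """
    if not 0 <= n_obs <= two_n:
        raise ValueError(f"observed count {n_obs} outside [0, {two_n}]")
    if not 0.0 <= f_exp <= 1.0:
        raise ValueError(f"expected frequency {f_exp} outside [0, 1]")
    n_exp = expected_count(f_exp, two_n)
    if n_exp in (0, two_n):
        raise ValueError(
            f"expected count {n_exp} of {two_n} leaves the chi-square undefined"
        )
    if n_obs == n_exp:
        return 0.0
    table = [[n_obs, two_n - n_obs], [n_exp, two_n - n_exp]]
    return float(stats.chi2_contingency(table, correction=True).statistic)


def expected_count(f_exp: float, two_n: int) -> int:
    """Expected joint count, rounded to the nearest integer (half away from zero)."""
    return int(math.floor(f_exp * two_n + 0.5))


def ld_contrast(chi2_controls: float, chi2_patients: float) -> LDContrast:
    """As-published contrast: delta referred to a 2-df chi-square upper tail.

    A non-positive delta (patients' statistic not larger) gives P = 1 with
    a direction flag.
    """
    if chi2_controls < 0 or chi2_patients < 0:
        raise ValueError("chi-square statistics must be non-negative")
    delta = chi2_patients - chi2_controls
    if delta <= 0:
        return LDContrast(chi2_controls, chi2_patients, delta, 1.0, negative_delta=delta < 0)
    return LDContrast(chi2_controls, chi2_patients, delta, float(stats.chi2.sf(delta, df=2)))


def ld_result(obs: TwoLocusObservation) -> LDResult:
    """Full per-cohort LD summary from margins and the joint count."""
    f_exp = obs.p_a * obs.p_b
    n_exp = expected_count(f_exp, obs.two_n)
    d, d_prime = lewontin_d(obs.p_a, obs.p_b, obs.f_ab_obs)
    try:
        chi2 = cohort_chi2(obs.n_ab, f_exp, obs.two_n)
        note = None
    except ValueError as err:
        chi2 = None
        note = str(err)
    return LDResult(f_ab_exp=f_exp, n_exp=n_exp, d=d, d_prime=d_prime, chi2=chi2, note=note)


# ---------------------------------------------------------------------------
# Cohort-level driver


def _marker_b_subsets(
    loci: Sequence[str], alleles: dict[str, str]
) -> list[tuple[tuple[str, str], ...]]:
    """Complete haplotype, every partial haplotype down to pairs, then singles."""
    pairs = tuple((locus, alleles[locus]) for locus in loci)
    subsets: list[tuple[tuple[str, str], ...]] = []
    for size in range(len(pairs), 1, -1):
        subsets.extend(itertools.combinations(pairs, size))
    subsets.extend((p,) for p in pairs)
    return subsets


def _observe(
    subjects: Sequence[SubjectRecord],
    marker_a: str,
    marker_b: dict[str, str],
) -> TwoLocusObservation:
    chroms: list[Chromosome] = [ch for s in subjects for ch in s.chromosomes]
    two_n = len(chroms)
    n_a = sum(1 for ch in chroms if ch.utr_label == marker_a)
    n_b = sum(1 for ch in chroms if ch.carries(marker_b))
    n_ab = sum(1 for ch in chroms if ch.utr_label == marker_a and ch.carries(marker_b))
    return TwoLocusObservation(two_n=two_n, p_a=n_a / two_n, p_b=n_b / two_n, n_ab=n_ab)


@dataclass
class LDPairReport:
    """One marker pair's two-cohort LD report."""

    pair: tuple[tuple[str, str], ...]
    obs1: TwoLocusObservation
    obs2: TwoLocusObservation
    res1: LDResult
    res2: LDResult
    contrast: LDContrast | None
    note: str | None = None


def _permutation_contrast(
    subjects1: Sequence[SubjectRecord],
    subjects2: Sequence[SubjectRecord],
    marker_a: str,
    marker_b: dict[str, str],
    observed_delta: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """Cohort-label shuffling null for |delta|; includes the observed table."""
    pool = list(subjects1) + list(subjects2)
    n1 = len(subjects1)
    hits = 0
    idx = np.arange(len(pool))
    for _ in range(n_perm):
        rng.shuffle(idx)
        g1 = [pool[i] for i in idx[:n1]]
        g2 = [pool[i] for i in idx[n1:]]
        try:
            r1 = ld_result(_observe(g1, marker_a, marker_b))
            r2 = ld_result(_observe(g2, marker_a, marker_b))
        except ValueError:
            continue
        if r1.chi2 is None or r2.chi2 is None:
            continue
        if abs(r2.chi2 - r1.chi2) >= abs(observed_delta):
            hits += 1
    return (1 + hits) / (1 + n_perm)


def ld_table(
    cohort1: Sequence[SubjectRecord],
    cohort2: Sequence[SubjectRecord],
    marker_a: str = "UTR-1",
    marker_b_alleles: dict[str, str] | None = None,
    loci: Sequence[str] = ("A", "B", "C", "DRB1"),
    contrast: str = "as-published",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[LDPairReport]:
    """LD between a UTR haplotype and a set of classical-HLA markers.

    For the complete multi-locus haplotype, every partial haplotype and
    every single allele built from ``marker_b_alleles`` over ``loci``,
    computes each cohort's observation, LD summary, and the cross-cohort
    contrast. Marker B absent from a cohort yields a diagnostic row with no
    contrast. Requires per-chromosome phase between the UTR haplotype and
    the classical alleles.
    """
    if marker_b_alleles is None:
        # Ancestral Sardinian extended haplotype used in the study.
        marker_b_alleles = {"A": "30:02", "B": "18:01", "C": "05:01", "DRB1": "03:01"}
    missing = [locus for locus in loci if locus not in marker_b_alleles]
    if missing:
        raise ValueError(f"no marker-B allele given for loci {missing}")
    if contrast not in ("as-published", "permutation"):
        raise ValueError(f"unknown contrast mode {contrast!r}")
    rng = np.random.default_rng(seed)

    reports: list[LDPairReport] = []
    for pair in _marker_b_subsets(tuple(loci), marker_b_alleles):
        marker_b = dict(pair)
        obs1 = _observe(cohort1, marker_a, marker_b)
        obs2 = _observe(cohort2, marker_a, marker_b)
        if obs1.p_b == 0.0 or obs2.p_b == 0.0:
            reports.append(
                LDPairReport(
                    pair, obs1, obs2,
                    ld_result(obs1), ld_result(obs2), None,
                    note="marker B absent from at least one cohort",
                )
            )
            continue
        res1 = ld_result(obs1)
        res2 = ld_result(obs2)
        if res1.chi2 is None or res2.chi2 is None:
            reports.append(
                LDPairReport(pair, obs1, obs2, res1, res2, None,
                             note="per-cohort chi-square undefined")
            )
            continue
        ctr = ld_contrast(res1.chi2, res2.chi2)
        if contrast == "permutation":
            p_perm = _permutation_contrast(
                cohort1, cohort2, marker_a, marker_b, ctr.delta, n_perm, rng
            )
            ctr = LDContrast(ctr.chi2_1, ctr.chi2_2, ctr.delta, p_perm, ctr.negative_delta)
        reports.append(LDPairReport(pair, obs1, obs2, res1, res2, ctr))
    return reports
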