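"""Rank-sum, Hodges–Lehmann, Kendall tau and the group-comparison report."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from utrld.records import SubjectRecord, Chromosome
from utrld.soluble import (
    group_compare,
    hodges_lehmann_ci,
    kendall_tau,
    walsh_averages,
    wilcoxon_rank_sum,
)


def ranksum_oracle(x, y):
    """Exact two-sided Mann–Whitney P by enumerating all group assignments."""
    nx = len(x)
    pooled = sorted(x + y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    us = []
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(sum(1 for xi in xs for yj in ys if xi > yj))
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


@pytest.mark.parametrize(
    "x, y",
    [
        ([1, 2, 3, 4], [10, 11, 12, 13]),
        ([1, 5, 9], [2, 3, 4, 6]),
        ([0.5, 2.5, 7.0, 8.0, 9.0], [1.0, 3.0, 4.0]),
        ([10, 20], [1, 2, 3, 30]),
    ],
)
def test_rank_sum_matches_enumeration(x, y):
    assert wilcoxon_rank_sum(x, y) == pytest.approx(ranksum_oracle(x, y), abs=1e-12)


def test_rank_sum_identical_samples():
    assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0
    assert wilcoxon_rank_sum([5] * 4, [5] * 6) == 1.0


def test_rank_sum_separated_samples_exact_value():
    # complete separation of 4 vs 4: the two most extreme of C(8,4)=70 splits
    assert wilcoxon_rank_sum([1, 2, 3, 4], [10, 11, 12, 13]) == pytest.approx(2 / 70)


@given(
    data=st.lists(
        st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 2)),
        min_size=8, max_size=14, unique=True,
    )
)
def test_rank_sum_invariant_under_monotone_transform(data):
    x, y = data[: len(data) // 2], data[len(data) // 2:]
    p1 = wilcoxon_rank_sum(x, y)
    f = lambda v: math.exp(v / 25.0)
    p2 = wilcoxon_rank_sum([f(v) for v in x], [f(v) for v in y])
    assert p1 == pytest.approx(p2, abs=1e-12)


def test_walsh_averages_enumeration():
    w = walsh_averages([1.0, 2.0, 5.0])
    assert list(w) == [1.0, 1.5, 2.0, 3.0, 3.5, 5.0]


def test_hodges_lehmann_constant_sample():
    res = hodges_lehmann_ci([5.0] * 10)
    assert (res.median, res.ci_low, res.ci_high) == (5.0, 5.0, 5.0)


def test_hodges_lehmann_matches_independent_reference():
    """Frozen intervals cross-checked against R's wilcox.test(conf.int=TRUE)."""
    res = hodges_lehmann_ci([1, 2, 3, 4, 5], alpha=0.2)
    assert (res.ci_low, res.ci_high) == (2.0, 4.0)
    res = hodges_lehmann_ci([1, 2, 3, 4, 5], alpha=0.05)
    assert (res.ci_low, res.ci_high) == (1.0, 5.0)
    res = hodges_lehmann_ci([2.3, 5.1, 0.7, 9.4, 3.3, 4.8, 1.2, 6.6], alpha=0.05)
    assert (res.ci_low, res.ci_high) == (1.5, 7.1)
    x20 = [14.113, 8.306, 11.089, 11.899, 11.213, 9.682, 14.535, 9.716, 16.055,
           9.812, 13.915, 16.86, 5.833, 9.164, 9.6, 11.908, 9.147, 2.031, 2.679, 13.96]
    res = hodges_lehmann_ci(x20, alpha=0.05)
    assert (round(res.ci_low, 3), round(res.ci_high, 3)) == (9.011, 12.601)


def test_hodges_lehmann_n5_signed_rank_inversion_oracle():
    """CI bounds equal the order statistics at the exact signed-rank rank."""
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    w = sorted(walsh_averages(x))
    # exact null of W+ at n=5 by enumerating all 32 sign vectors
    ranks = [1, 2, 3, 4, 5]
    dist = [sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([0, 1], repeat=5)]
    cdf = lambda k: sum(1 for v in dist if v <= k) / 32
    alpha = 0.2
    k = max(kk for kk in range(-1, 16) if kk < 0 or cdf(kk) <= alpha / 2)
    res = hodges_lehmann_ci(x, alpha=alpha)
    assert res.ci_low == w[k]
    assert res.ci_high == w[len(w) - 1 - k]


def test_hodges_lehmann_mirror_symmetry():
    x = [0.4, 1.9, 2.2, 3.8, 7.7, 9.1]
    res = hodges_lehmann_ci(x)
    neg = hodges_lehmann_ci([-v for v in x])
    assert neg.ci_low == -res.ci_high
    assert neg.ci_high == -res.ci_low
    assert neg.median == -res.median


def test_hodges_lehmann_single_observation_has_no_interval():
    res = hodges_lehmann_ci([3.0])
    assert res.median == 3.0 and res.ci_low is None and res.ci_high is None


def kendall_oracle(x, y):
    """Tau-b from direct pair counting; exact P by permutation enumeration."""
    def tau_b(xs, ys):
        c = d = tx = ty = 0
        for (i, j) in itertools.combinations(range(len(xs)), 2):
            dx = xs[i] - xs[j]
            dy = ys[i] - ys[j]
            if dx * dy > 0:
                c += 1
            elif dx * dy < 0:
                d += 1
            elif dx == 0 and dy != 0:
                tx += 1
            elif dy == 0 and dx != 0:
                ty += 1
        return (c - d) / math.sqrt((c + d + tx) * (c + d + ty))

    t_obs = tau_b(x, y)
    perms = [tau_b(x, list(p)) for p in itertools.permutations(y)]
    p = sum(1 for t in perms if abs(t) >= abs(t_obs) - 1e-12) / len(perms)
    return t_obs, p


@pytest.mark.parametrize(
    "x, y",
    [
        ([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]),
        ([1, 2, 3, 4, 5], [5, 3, 1, 4, 2]),
        ([3, 1, 4, 1, 5], [2, 7, 1, 8, 2]),  # ties in both margins
    ],
)
def test_kendall_matches_pair_counting_oracle(x, y):
    tau, p = kendall_tau(x, y)
    t_ref, p_ref = kendall_oracle(x, y)
    assert tau == pytest.approx(t_ref, abs=1e-12)
    if len(set(x)) == len(x) and len(set(y)) == len(y):  # exact P only tie-free
        assert p == pytest.approx(p_ref, abs=1e-12)


def test_kendall_perfect_and_degenerate():
    assert kendall_tau([1, 2, 3, 4], [10, 20, 30, 40])[0] == pytest.approx(1.0)
    assert kendall_tau([1, 2, 3, 4], [40, 30, 20, 10])[0] == pytest.approx(-1.0)
    assert kendall_tau([1, 1, 1], [1, 2, 3]) == (None, None)


def _subject(sid, cohort, shlag=None, inflammation=None, clinical=None):
    chroms = (Chromosome(utr_labels=("UTR-1",)), Chromosome(utr_labels=("UTR-2",)))
    return SubjectRecord(subject_id=sid, cohort=cohort, chromosomes=chroms,
                         shlag=shlag, inflammation=inflammation,
                         biopsied=inflammation is not None,
                         clinical=clinical or {})


def test_group_compare_identical_groups_all_p_one():
    records = []
    for i in range(12):
        grade = "severe" if i % 2 == 0 else "mild"
        records.append(_subject(f"p{i}", "patient", shlag=10.0 + (i % 3),
                                inflammation=grade,
                                clinical={"ALT": 50.0 + (i % 3), "ANA": i % 4 < 2}))
    # both groups see the same value multiset
    df = group_compare(records, "severe_vs_rest")
    for _, row in df.iterrows():
        if row["p"] is not None:
            assert row["p"] == pytest.approx(1.0)


def test_group_compare_percentage_formatting():
    # 23 of 28 positive prints as 82.1%
    records = [
        _subject(f"s{i}", "patient", shlag=5.0, inflammation="severe",
                 clinical={"female": i < 23})
        for i in range(28)
    ] + [
        _subject(f"r{i}", "patient", shlag=5.0, inflammation="mild",
                 clinical={"female": True})
        for i in range(10)
    ]
    df = group_compare(records, "severe_vs_rest")
    row = df[df["variable"] == "female"].iloc[0]
    assert row["summary1"] == "23 (82.1)"


def test_group_compare_detects_shifted_continuous_variable():
    rng = np.random.default_rng(5)
    records = []
    for i in range(30):
        records.append(_subject(f"a{i}", "patient", shlag=8.0, inflammation="severe",
                                clinical={"ALT": float(rng.normal(200, 30))}))
    for i in range(30):
        records.append(_subject(f"b{i}", "patient", shlag=30.0, inflammation="mild",
                                clinical={"ALT": float(rng.normal(80, 30))}))
    df = group_compare(records, "severe_vs_rest")
    alt = df[df["variable"] == "ALT"].iloc[0]
    assert alt["p"] < 1e-6
    sh = df[df["variable"] == "sHLA_G"].iloc[0]
    assert sh["test"] == "wilcoxon" and sh["p"] < 1e-6


def test_group_compare_flags_heavy_missingness():
    records = [
        _subject(f"a{i}", "patient", shlag=5.0, inflammation="severe",
                 clinical={"ALT": 100.0} if i == 0 else {})
        for i in range(6)
    ] + [
        _subject(f"b{i}", "patient", shlag=5.0, inflammation="mild",
                 clinical={"ALT": 90.0 + i})
        for i in range(6)
    ]
    df = group_compare(records, "severe_vs_rest")
    alt = df[df["variable"] == "ALT"].iloc[0]
    assert "missing" in (alt["note"] or "")


def test_group_compare_requires_two_groups():
    records = [_subject("a", "patient", shlag=5.0)]
    with pytest.raises(ValueError, match="non-empty"):
        group_compare(records, "patient_vs_control")
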