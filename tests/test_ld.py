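"""Lewontin D/D', per-cohort chi-square, and the cross-cohort LD contrast."""

import math

import numpy as np
import pytest

from utrld.haplotypes import tabulate, key_utr
from utrld.ld import (
    TwoLocusObservation,
    cohort_chi2,
    expected_count,
    ld_contrast,
    ld_result,
    ld_table,
    lewontin_d,
)
from utrld.records import Chromosome, SubjectRecord
from utrld.synthetic import SimulationConfig, simulate


def dmax_oracle(p_a, p_b, sign):
    """Margin-constrained |D| maximum found by scanning joint frequencies."""
    f_lo = max(0.0, p_a + p_b - 1.0)
    f_hi = min(p_a, p_b)
    grid = np.linspace(f_lo, f_hi, 20001)
    d = grid - p_a * p_b
    return d.max() if sign > 0 else -d.min()


def test_lewontin_matches_margin_scan_oracle():
    for p_a in np.arange(0.05, 1.0, 0.05):
        for p_b in np.arange(0.05, 1.0, 0.05):
            for sign in (+1, -1):
                d_max = dmax_oracle(p_a, p_b, sign)
                f = p_a * p_b + sign * 0.5 * d_max
                d, d_prime = lewontin_d(p_a, p_b, f)
                assert d == pytest.approx(sign * 0.5 * d_max, abs=1e-9)
                assert d_prime == pytest.approx(sign * 0.5, abs=1e-3)


@pytest.mark.parametrize(
    "p_a, p_b, f_ab, d_exp, dp_exp",
    [
        (0.4024, 0.388, 0.3683, 0.2122, 0.92),  # patients UTR-1 x DRB1*03:01
        (0.3429, 0.2167, 0.1452, 0.0709, 0.50),  # controls
    ],
)
def test_lewontin_published_rows(p_a, p_b, f_ab, d_exp, dp_exp):
    d, d_prime = lewontin_d(p_a, p_b, f_ab)
    assert round(d, 4) == d_exp
    assert round(d_prime, 2) == dp_exp


def test_lewontin_equilibrium_and_complete_ld():
    assert lewontin_d(0.3, 0.7, 0.21) == (0.0, 0.0)
    # joint frequency at its margin-constrained maximum gives D' = 1 exactly
    d, d_prime = lewontin_d(165 / 410, 89 / 410, 89 / 410)
    assert d_prime == pytest.approx(1.0)


def test_lewontin_fixed_margin_undefined():
    d, d_prime = lewontin_d(1.0, 0.4, 0.4)
    assert d == 0.0 and d_prime == 0.0


def yates_oracle(table):
    """Textbook Yates chi-square from margins, computed by hand."""
    (a, b), (c, d) = table
    n = a + b + c + d
    total = 0.0
    for obs, row, col in ((a, a + b, a + c), (b, a + b, b + d),
                          (c, c + d, a + c), (d, c + d, b + d)):
        exp = row * col / n
        total += (max(abs(obs - exp) - 0.5, 0.0)) ** 2 / exp
    return total


@pytest.mark.parametrize(
    "n_obs, f_exp, two_n, expected",
    [
        (151, 0.1561, 410, 46.62),
        (61, 0.0743, 420, 10.27),
        (89, 0.0874, 410, 25.52),
    ],
)
def test_cohort_chi2_published_values(n_obs, f_exp, two_n, expected):
    assert round(cohort_chi2(n_obs, f_exp, two_n), 2) == expected


def test_cohort_chi2_equals_hand_computed_yates():
    # controls' complete extended haplotype: observed 42, expected 15 of 420
    assert cohort_chi2(42, 15 / 420, 420) == pytest.approx(
        yates_oracle([[42, 378], [15, 405]]), abs=1e-9
    )
    assert round(cohort_chi2(42, 15 / 420, 420), 2) == 12.72


def test_cohort_chi2_degenerate():
    assert cohort_chi2(50, 50 / 100, 100) == 0.0
    with pytest.raises(ValueError, match="undefined"):
        cohort_chi2(5, 0.0, 100)


def test_expected_count_rounds_to_nearest():
    assert expected_count(0.1561, 410) == 64
    assert expected_count(0.0743, 420) == 31


def test_ld_contrast_published_and_closed_form():
    assert float(f"{ld_contrast(10.27, 46.62).p:.1e}") == pytest.approx(1.3e-8)
    assert round(ld_contrast(12.72, 25.52).p, 3) == 0.002
    # 2-df chi-square survival has the closed form exp(-delta/2)
    delta = 36.35
    assert ld_contrast(0.0, delta).p == pytest.approx(math.exp(-delta / 2.0), rel=1e-12)
    assert ld_contrast(5.0, 5.0).p == 1.0
    assert ld_contrast(7.0, 3.0).negative_delta and ld_contrast(7.0, 3.0).p == 1.0


def test_ld_contrast_monotone_in_delta():
    ps = [ld_contrast(0.0, d).p for d in (1.0, 5.0, 10.0, 20.0, 40.0)]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_ld_result_full_summary():
    # patients UTR-1 x DRB1*03:01 from the published counts
    obs = TwoLocusObservation(two_n=410, p_a=165 / 410, p_b=159 / 410, n_ab=151)
    res = ld_result(obs)
    assert round(100 * res.f_ab_exp, 2) == 15.61
    assert res.n_exp == 64
    assert round(100 * res.d, 2) == 21.22
    assert round(res.d_prime, 2) == 0.92
    assert round(res.chi2, 2) == 46.62


def _chromosome(label, drb1):
    return Chromosome(utr_labels=(label,) if label else (),
                      alleles={"DRB1": drb1})


def _cohort(pairs, cohort):
    return [
        SubjectRecord(subject_id=f"{cohort}{i}", cohort=cohort,
                      chromosomes=(a, b))
        for i, (a, b) in enumerate(pairs)
    ]


def test_ld_table_identical_cohorts_contrast_is_one():
    chroms = [
        (_chromosome("UTR-1", "03:01"), _chromosome("UTR-2", "04:05")),
        (_chromosome("UTR-1", "03:01"), _chromosome("UTR-1", "04:05")),
        (_chromosome("UTR-2", "04:05"), _chromosome("UTR-2", "03:01")),
    ] * 10
    c1 = _cohort(chroms, "a")
    c2 = _cohort(chroms, "b")
    reports = ld_table(c1, c2, marker_a="UTR-1",
                       marker_b_alleles={"DRB1": "03:01"}, loci=("DRB1",))
    assert len(reports) == 1
    assert reports[0].contrast.delta == 0.0
    assert reports[0].contrast.p == 1.0


def test_ld_table_enumerates_fifteen_marker_subsets(default_dataset):
    subjects = default_dataset.subjects
    c1 = [s for s in subjects if s.cohort == "control"]
    c2 = [s for s in subjects if s.cohort == "patient"]
    reports = ld_table(c1, c2)
    # 1 complete + 4 triples + 6 pairs + 4 singles
    assert len(reports) == 15
    sizes = [len(r.pair) for r in reports]
    assert sizes == [4, 3, 3, 3, 3, 2, 2, 2, 2, 2, 2, 1, 1, 1, 1]


def test_ld_table_absent_marker_reports_diagnostic():
    chroms = [(_chromosome("UTR-1", "03:01"), _chromosome("UTR-2", "04:05"))] * 10
    c1 = _cohort(chroms, "a")
    c2 = _cohort([(_chromosome("UTR-1", "07:01"), _chromosome("UTR-2", "04:05"))] * 10, "b")
    reports = ld_table(c1, c2, marker_a="UTR-1",
                       marker_b_alleles={"DRB1": "03:01"}, loci=("DRB1",))
    assert reports[0].contrast is None
    assert "absent" in reports[0].note


def test_no_ld_generator_stays_near_zero_dprime():
    """Cohorts simulated at D' = 0 estimate |D'| below the 2N=400 sampling bound."""
    cfg = SimulationConfig()
    cfg.d_prime = {"control": 0.0, "patient": 0.0}
    worst = 0.0
    for seed in range(5):
        ds = simulate(cfg, seed=seed)
        for cohort in ("control", "patient"):
            chroms = [ch for s in ds.subjects if s.cohort == cohort for ch in s.chromosomes]
            two_n = len(chroms)
            n_a = sum(1 for ch in chroms if ch.utr_label == "UTR-1")
            n_b = sum(1 for ch in chroms if ch.alleles.get("DRB1") == "03:01")
            n_ab = sum(1 for ch in chroms
                       if ch.utr_label == "UTR-1" and ch.alleles.get("DRB1") == "03:01")
            _, d_prime = lewontin_d(n_a / two_n, n_b / two_n, n_ab / two_n)
            worst = max(worst, abs(d_prime))
    assert worst < 0.15


def test_permutation_contrast_agrees_in_direction(default_dataset):
    subjects = default_dataset.subjects
    c1 = [s for s in subjects if s.cohort == "control"]
    c2 = [s for s in subjects if s.cohort == "patient"]
    reports = ld_table(c1, c2, marker_b_alleles={"DRB1": "03:01"}, loci=("DRB1",),
                       contrast="permutation", n_perm=200, seed=3)
    assert reports[0].contrast.p < 0.05  # strong configured LD difference
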