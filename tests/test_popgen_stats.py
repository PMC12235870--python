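"""Exact binomial intervals, enumeration Fisher test, cohort comparison."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

from cside.popgen_stats import (
    CohortTable,
    allele_freq_codominant,
    clopper_pearson_ci,
    compare_cohorts,
    fisher_exact,
    hwe_dominant_allele_freq,
    presence_freq_dominant,
    round_half_up,
    survey_report,
)


# --- independent Fisher oracle (kept deliberately naive) -------------------


def oracle_fisher(table):
    """Brute-force two-sided conditional exact test.

    Enumerates all tables with the observed margins by direct iteration over
    cell values and computes each probability with exact integer factorials.
    Written independently of the package implementation (math.factorial and
    Fractions of integers, no shared helpers).
    """
    from fractions import Fraction

    table = [list(map(int, row)) for row in table]
    row_sums = [sum(r) for r in table]
    col_sums = [sum(c) for c in zip(*table)]
    n = sum(row_sums)

    def prob(cells):
        num = Fraction(1)
        for s in row_sums + col_sums:
            num *= math.factorial(s)
        den = Fraction(math.factorial(n))
        for v in cells:
            den *= math.factorial(v)
        return num / den

    r, c = len(table), len(table[0])
    free_rows = r - 1
    observed_p = prob([v for row in table for v in row])

    total = Fraction(0)
    ranges = [range(min(row_sums[i], col_sums[j]) + 1)
              for i in range(free_rows) for j in range(c - 1)]
    for combo in itertools.product(*ranges):
        cells = []
        ok = True
        col_used = [0] * c
        idx = 0
        for i in range(free_rows):
            row = list(combo[idx : idx + (c - 1)])
            idx += c - 1
            last = row_sums[i] - sum(row)
            if last < 0:
                ok = False
                break
            row.append(last)
            for j, v in enumerate(row):
                col_used[j] += v
                if col_used[j] > col_sums[j]:
                    ok = False
                    break
            if not ok:
                break
            cells.extend(row)
        if not ok:
            continue
        last_row = [col_sums[j] - col_used[j] for j in range(c)]
        if any(v < 0 for v in last_row):
            continue
        cells.extend(last_row)
        p = prob(cells)
        if p <= observed_p:
            total += p
    return float(total)


# --- Clopper-Pearson -------------------------------------------------------


@pytest.mark.parametrize(
    "k, n, expected",
    [
        (6, 40, (0.06, 0.30)),
        (0, 10, (0.00, 0.31)),
        (28, 50, (0.41, 0.70)),
        (12, 18, (0.41, 0.87)),
        (10, 25, (0.21, 0.61)),
    ],
)
def test_clopper_pearson_published_intervals(k, n, expected):
    """Survey-table intervals reproduce to the printed 2-decimal rounding."""
    low, high = clopper_pearson_ci(k, n, 0.95)
    assert (round_half_up(low), round_half_up(high)) == expected


def test_zero_successes_upper_bound_closed_form():
    # P(X = 0 | n, p) = (1-p)^n = alpha/2  =>  p = 1 - (alpha/2)^(1/n)
    low, high = clopper_pearson_ci(0, 10, 0.95)
    assert low == 0.0
    assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-10)


def test_all_successes_bounds():
    low, high = clopper_pearson_ci(7, 7, 0.95)
    assert high == 1.0
    assert low == pytest.approx(0.025 ** (1 / 7), abs=1e-10)


def test_interval_inverts_exact_binomial_tails():
    k, n = 9, 32
    low, high = clopper_pearson_ci(k, n, 0.95)
    assert scipy.stats.binom.sf(k - 1, n, low) == pytest.approx(0.025, abs=1e-9)
    assert scipy.stats.binom.cdf(k, n, high) == pytest.approx(0.025, abs=1e-9)


def test_widening_level_widens_interval():
    narrow = clopper_pearson_ci(6, 40, 0.90)
    wide = clopper_pearson_ci(6, 40, 0.99)
    assert wide[0] < narrow[0] < narrow[1] < wide[1]


def test_invalid_arguments_rejected():
    with pytest.raises(ValueError):
        clopper_pearson_ci(5, 4)
    with pytest.raises(ValueError):
        clopper_pearson_ci(1, 10, level=1.0)


def test_ci_coverage_is_conservative():
    """Exact intervals cover the true p in >= 95% of draws on a small grid."""
    rng = np.random.default_rng(2024)
    for n in (10, 25, 60):
        for p in (0.1, 0.4, 0.7):
            ks = rng.binomial(n, p, size=2_000)
            covered = 0
            for k, count in zip(*np.unique(ks, return_counts=True)):
                low, high = clopper_pearson_ci(int(k), n, 0.95)
                covered += count * (low <= p <= high)
            assert covered / 2_000 >= 0.95


# --- frequency estimators --------------------------------------------------


def test_codominant_allele_frequency_counts_alleles():
    est = allele_freq_codominant(0, 6, 14)
    assert (est.point, est.k, est.n_trials) == (0.15, 6, 40)
    est = allele_freq_codominant(5, 8, 17)  # the sequenced-cohort counts
    assert est.point == pytest.approx(0.30)
    assert allele_freq_codominant(25, 0, 0).point == 1.0
    with pytest.raises(ValueError):
        allele_freq_codominant(0, 0, 0)


def test_dominant_presence_frequency():
    assert presence_freq_dominant(10, 25).point == 0.40
    assert presence_freq_dominant(0, 10).display() == "0.00 (0.00-0.31)"
    assert presence_freq_dominant(7, 7).point == 1.0
    with pytest.raises(ValueError):
        presence_freq_dominant(1, 0)


def test_display_rounds_half_away_from_zero():
    assert round_half_up(0.125) == 0.13
    assert round_half_up(0.294999) == 0.29
    est = allele_freq_codominant(0, 6, 14)
    assert est.display() == "0.15 (0.06-0.30)"


def test_hwe_dominant_estimator():
    q = 0.3
    assert hwe_dominant_allele_freq(1 - (1 - q) ** 2) == pytest.approx(q)
    assert hwe_dominant_allele_freq(0.0) == 0.0
    assert hwe_dominant_allele_freq(1.0) == 1.0


# --- Fisher exact test -----------------------------------------------------


def test_fisher_2x2_known_value():
    assert fisher_exact([[3, 1], [1, 3]]) == pytest.approx(34 / 70, rel=1e-9)


def test_fisher_identical_rows_give_p_one():
    assert fisher_exact([[4, 6], [4, 6]]) == pytest.approx(1.0)
    assert fisher_exact([[2, 3, 5], [2, 3, 5]]) == pytest.approx(1.0)


def test_fisher_2x2_matches_scipy():
    rng = np.random.default_rng(11)
    for _ in range(50):
        table = rng.integers(0, 12, size=(2, 2))
        if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (
            table.sum(axis=1) == 0
        ).any():
            continue
        expected = scipy.stats.fisher_exact(table, alternative="two-sided")[1]
        assert fisher_exact(table) == pytest.approx(expected, rel=1e-7)


@pytest.mark.parametrize("shape", [(2, 2), (2, 3)])
def test_fisher_matches_independent_enumeration_oracle(shape):
    rng = np.random.default_rng(sum(shape))
    for _ in range(40):
        table = rng.integers(0, 8, size=shape)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            continue
        assert fisher_exact(table) == pytest.approx(oracle_fisher(table), rel=1e-9)


def test_fisher_probabilities_sum_to_one():
    from cside.popgen_stats import _enumerate_tables, _log_table_prob
    from scipy.special import gammaln

    obs = np.array([[3, 2, 4], [1, 5, 2]])
    logfact_n = float(gammaln(obs.sum() + 1))
    total = sum(
        float(np.exp(_log_table_prob(t, logfact_n)))
        for t in _enumerate_tables(obs.sum(axis=1), obs.sum(axis=0), 10**6)
    )
    assert total == pytest.approx(1.0, abs=1e-9)


def test_fisher_input_validation_and_cap():
    with pytest.raises(ValueError, match="non-negative"):
        fisher_exact([[1, -1], [2, 3]])
    with pytest.raises(ValueError, match="integers"):
        fisher_exact([[1.5, 1], [2, 3]])
    with pytest.raises(ValueError, match="Monte-Carlo"):
        fisher_exact([[50, 60, 70], [80, 90, 100]], max_tables=100)


# --- cohort comparison -----------------------------------------------------


def test_identical_cohorts_compare_as_equal():
    a = CohortTable("a", {"hom": 5, "het": 8, "non-carrier": 17})
    b = CohortTable("b", {"hom": 5, "het": 8, "non-carrier": 17})
    result = compare_cohorts(a, b)
    assert result.fisher_p == pytest.approx(1.0)
    assert result.cis_overlap
    assert result.estimate_a == result.estimate_b


def test_mismatched_classes_rejected():
    a = CohortTable("a", {"hom": 1, "het": 2, "non-carrier": 3})
    b = CohortTable("b", {"positive": 4, "negative": 5})
    with pytest.raises(ValueError, match="classes"):
        compare_cohorts(a, b)


def test_fisher_type_one_error_near_nominal():
    """Simulated equal-frequency cohorts are rejected at alpha=0.05 at a
    rate no higher than nominal (the exact test is conservative)."""
    rng = np.random.default_rng(99)
    rejections = 0
    n_rep = 400
    for _ in range(n_rep):
        counts_a = rng.multinomial(25, [0.3, 0.5, 0.2])
        counts_b = rng.multinomial(60, [0.3, 0.5, 0.2])
        a = CohortTable("a", dict(zip(("hom", "het", "non-carrier"), counts_a)))
        b = CohortTable("b", dict(zip(("hom", "het", "non-carrier"), counts_b)))
        rejections += compare_cohorts(a, b).fisher_p < 0.05
    rate = rejections / n_rep
    assert rate <= 0.05 + 1.5 * np.sqrt(0.05 * 0.95 / n_rep) + 0.015


def test_power_is_modest_at_survey_sample_sizes():
    """At allele frequencies 0.56 vs 0.44 with n=25 vs 60 the Fisher test
    rarely reaches significance — consistent with overlapping CIs."""
    rng = np.random.default_rng(7)
    rejections = 0
    n_rep = 200
    for _ in range(n_rep):
        def draw(n, p):
            hom = het = wt = 0
            for _ in range(n):
                k = rng.binomial(2, p)
                hom += k == 2
                het += k == 1
                wt += k == 0
            return {"hom": hom, "het": het, "non-carrier": wt}

        a = CohortTable("old", draw(25, 0.56))
        b = CohortTable("new", draw(60, 0.44))
        rejections += compare_cohorts(a, b).fisher_p < 0.05
    assert rejections / n_rep < 0.6  # power well below 1


def test_survey_report_matches_published_table(capsys):
    from cside.datasets import SWEDISH_COHORTS

    report = survey_report(SWEDISH_COHORTS)
    displays = dict(zip(report["cohort"], report["cs29_display"]))
    assert displays["Fjällnära 2023-2024"] == "0.15 (0.06-0.30)"
    assert displays["Swedish Mountain 1990s-2015"] == "0.56 (0.41-0.70)"
    cs6 = dict(zip(report["cohort"], report["cs6_display"]))
    assert cs6["Väne 1990s"] == "0.00 (0.00-0.31)"
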