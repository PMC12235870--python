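"""Cohort genotype/allele frequency estimation with exact binomial
confidence intervals and an enumeration-based Fisher exact test.

For a codominant marker (Cs29: hom / het / non-carrier distinguishable) the
allele frequency is estimated over ``2n`` allele draws, ``p̂ = (2·hom +
het) / 2n``.  For a dominant marker (Cs6: only presence detectable) the
frequency of positive animals is reported over ``n`` animals.  95% intervals
are exact Clopper–Pearson bounds, the equal-tailed inversion of the binomial
test.  Differences in genotype frequencies between cohorts are tested with
the exact conditional Fisher test on the r×c genotype-count table, the
two-sided probability-mass convention: the p-value sums the hypergeometric
probabilities of all margin-fixed tables no more probable than the one
observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "CohortTable",
    "FreqEstimate",
    "CohortComparison",
    "allele_freq_codominant",
    "presence_freq_dominant",
    "clopper_pearson_ci",
    "fisher_exact",
    "compare_cohorts",
    "hwe_dominant_allele_freq",
    "round_half_up",
    "survey_report",
    "format_survey_report",
]


def round_half_up(x: float, digits: int = 2) -> float:
    """Round half away from zero (report display convention, not banker's)."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FreqEstimate:
    """A proportion with its exact binomial confidence interval."""

    point: float
    k: int
    n_trials: int
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.point <= self.ci_high <= 1:
            raise ValueError("require 0 <= ci_low <= point <= ci_high <= 1")
        if not 0 <= self.k <= self.n_trials:
            raise ValueError("require 0 <= k <= n_trials")

    def display(self, digits: int = 2) -> str:
        """Table-style ``0.15 (0.06-0.30)`` rendering, half-up to ``digits``."""
        fmt = f"{{:.{digits}f}}"
        return (
            f"{fmt.format(round_half_up(self.point, digits))} "
            f"({fmt.format(round_half_up(self.ci_low, digits))}-"
            f"{fmt.format(round_half_up(self.ci_high, digits))})"
        )


def clopper_pearson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) equal-tailed binomial confidence interval.

    The lower bound solves ``P(X >= k | n, p) = (1 - level)/2`` (0 when
    ``k = 0``); the upper bound solves ``P(X <= k | n, p) = (1 - level)/2``
    (1 when ``k = n``).  Computed by inverting the incomplete beta function.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = (1 - level) / 2
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.isf(alpha, k + 1, n - k))
    return low, high


def _estimate(k: int, n: int, level: float) -> FreqEstimate:
    low, high = clopper_pearson_ci(k, n, level)
    return FreqEstimate(point=k / n, k=k, n_trials=n, ci_low=low, ci_high=high, level=level)


def allele_freq_codominant(
    n_hom: int, n_het: int, n_wt: int, level: float = 0.95
) -> FreqEstimate:
    """Allele frequency of a codominant marker over ``2 × animals`` trials."""
    if min(n_hom, n_het, n_wt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n_animals = n_hom + n_het + n_wt
    if n_animals == 0:
        raise ValueError("no animals in cohort")
    return _estimate(2 * n_hom + n_het, 2 * n_animals, level)


def presence_freq_dominant(n_positive: int, n: int, level: float = 0.95) -> FreqEstimate:
    """Frequency of marker-positive animals (dominant assay, ``n`` trials)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= n_positive <= n:
        raise ValueError("require 0 <= n_positive <= n")
    return _estimate(n_positive, n, level)


def hwe_dominant_allele_freq(f_positive: float) -> float:
    """Allele frequency implied by a positive fraction under Hardy–Weinberg.

    ``q̂ = 1 - sqrt(1 - f_positive)`` from ``f_positive = 1 - (1 - q)²``.
    An extension beyond presence reporting: it assumes random mating, which
    a presence/absence table alone cannot verify.
    """
    if not 0 <= f_positive <= 1:
        raise ValueError("f_positive must be in [0, 1]")
    return 1.0 - float(np.sqrt(1.0 - f_positive))


# --- Fisher exact test by full enumeration -------------------------------

_REL_TIE_TOL = 1e-7  # probabilities within this relative slack count as ties


def _log_table_prob(table: np.ndarray, logfact_n: float) -> float:
    """Log conditional (hypergeometric) probability of an r×c table."""
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - logfact_n
        - gammaln(table + 1).sum()
    )


def _enumerate_tables(row_sums, col_sums, cap, count_only=False):
    """Yield every non-negative integer table with the given margins."""
    r, c = len(row_sums), len(col_sums)
    table = np.zeros((r, c), dtype=np.int64)
    seen = 0

    def fill(i: int, remaining_cols: np.ndarray):
        nonlocal seen
        if i == r - 1:
            if np.all(remaining_cols >= 0):
                table[i] = remaining_cols
                seen += 1
                if seen > cap:
                    raise OverflowError
                yield table
            return
        target = row_sums[i]

        def fill_row(j: int, left: int):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    table[i, j] = left
                    yield from fill(i + 1, remaining_cols - table[i])
                    table[i, j] = 0
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                table[i, j] = v
                yield from fill_row(j + 1, left - v)
            table[i, j] = 0

        yield from fill_row(0, target)

    yield from fill(0, np.array(col_sums, dtype=np.int64))


def fisher_exact(
    table, alternative: str = "two-sided", max_tables: int = 2_000_000
) -> float:
    """Two-sided exact conditional test of independence on an r×c count table.

    Enumerates every table with the observed margins and sums the
    hypergeometric probabilities of those no more probable than the observed
    table (relative tie tolerance 1e-7 absorbs floating-point ties) — the
    probability-mass two-sided convention of the conditional exact test.
    Raises if the margin-fixed table space exceeds ``max_tables`` (a
    Monte-Carlo approximation would then be the appropriate tool).
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is implemented")
    obs = np.asarray(table)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r×c table with r, c >= 2")
    if not np.issubdtype(obs.dtype, np.integer):
        if not np.allclose(obs, np.round(obs)):
            raise ValueError("table cells must be integers")
        obs = np.round(obs).astype(np.int64)
    if np.any(obs < 0):
        raise ValueError("table cells must be non-negative")
    obs = obs.astype(np.int64)
    n = int(obs.sum())
    if n < 1:
        raise ValueError("table total must be >= 1")

    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    logfact_n = float(gammaln(n + 1))
    log_p_obs = _log_table_prob(obs, logfact_n)
    threshold = log_p_obs + np.log1p(_REL_TIE_TOL)

    total = 0.0
    try:
        for t in _enumerate_tables(row_sums, col_sums, max_tables):
            lp = _log_table_prob(t, logfact_n)
            if lp <= threshold:
                total += float(np.exp(lp))
    except OverflowError:
        raise ValueError(
            f"more than {max_tables} tables share these margins; "
            "use a Monte-Carlo approximation instead"
        ) from None
    return min(total, 1.0)


# --- Cohort containers and comparison -------------------------------------


@dataclass(frozen=True)
class CohortTable:
    """Genotype-class counts for one cohort (breed and/or sampling period)."""

    label: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("genotype counts must be >= 0")
        if self.n_animals < 1:
            raise ValueError("cohort must contain at least one animal")

    @property
    def n_animals(self) -> int:
        return sum(self.counts.values())

    def count(self, cls: str) -> int:
        return self.counts.get(cls, 0)


@dataclass(frozen=True)
class CohortComparison:
    """Frequencies per cohort, the Fisher p-value, and CI overlap."""

    label_a: str
    label_b: str
    estimate_a: FreqEstimate
    estimate_b: FreqEstimate
    fisher_p: float
    cis_overlap: bool
    classes: tuple[str, ...]


def _cohort_estimate(cohort: CohortTable, marker: str, level: float) -> FreqEstimate:
    if marker == "codominant":
        return allele_freq_codominant(
            cohort.count("hom"), cohort.count("het"), cohort.count("non-carrier"),
            level=level,
        )
    if marker == "dominant":
        return presence_freq_dominant(
            cohort.count("positive"), cohort.n_animals, level=level
        )
    raise ValueError(f"unknown marker kind {marker!r}")


def compare_cohorts(
    cohort_a: CohortTable,
    cohort_b: CohortTable,
    marker: str = "codominant",
    classes: tuple[str, ...] | None = None,
    level: float = 0.95,
) -> CohortComparison:
    """Compare genotype frequencies of two cohorts of the same marker.

    ``marker`` selects the frequency estimator: ``"codominant"`` (classes
    hom / het / non-carrier, allele frequency over 2n) or ``"dominant"``
    (classes positive / negative, presence frequency over n).  The Fisher
    exact p-value is computed on the 2×c genotype-count table over
    ``classes`` (defaulting to the marker's full class set; pass e.g.
    carrier/non-carrier pools to collapse it).
    """
    if classes is None:
        classes = (
            ("hom", "het", "non-carrier")
            if marker == "codominant"
            else ("positive", "negative")
        )
    known = set(classes)
    for cohort in (cohort_a, cohort_b):
        extra = set(cohort.counts) - known
        if extra:
            raise ValueError(
                f"cohort {cohort.label!r} has classes {sorted(extra)} "
                f"not in {sorted(known)}"
            )

    est_a = _cohort_estimate(cohort_a, marker, level)
    est_b = _cohort_estimate(cohort_b, marker, level)
    contingency = np.array(
        [[cohort_a.count(c) for c in classes], [cohort_b.count(c) for c in classes]]
    )
    # drop classes absent from both cohorts so margins stay positive
    keep = contingency.sum(axis=0) > 0
    if keep.sum() < 2:
        p = 1.0
    else:
        p = fisher_exact(contingency[:, keep])
    overlap = est_a.ci_low <= est_b.ci_high and est_b.ci_low <= est_a.ci_high
    return CohortComparison(
        label_a=cohort_a.label,
        label_b=cohort_b.label,
        estimate_a=est_a,
        estimate_b=est_b,
        fisher_p=p,
        cis_overlap=overlap,
        classes=tuple(classes),
    )


def survey_report(cohorts, level: float = 0.95, digits: int = 2):
    """Frequency table across survey cohorts, one row per cohort.

    ``cohorts`` are objects with ``label``, ``n_animals``,
    ``cs29_allele_copies`` (codominant allele copies of 2n) and
    ``cs6_positive`` (dominant positives of n) — e.g.
    :class:`cside.datasets.CohortSummary`.  Returns a DataFrame with point
    estimates, exact CI bounds, and display strings rounded half-up.
    """
    import pandas as pd

    rows = []
    for c in cohorts:
        cs29 = _estimate(c.cs29_allele_copies, 2 * c.n_animals, level)
        cs6 = _estimate(c.cs6_positive, c.n_animals, level)
        rows.append(
            {
                "cohort": c.label,
                "n": c.n_animals,
                "cs29_freq": cs29.point,
                "cs29_ci_low": cs29.ci_low,
                "cs29_ci_high": cs29.ci_high,
                "cs29_display": cs29.display(digits),
                "cs6_positive_freq": cs6.point,
                "cs6_ci_low": cs6.ci_low,
                "cs6_ci_high": cs6.ci_high,
                "cs6_display": cs6.display(digits),
            }
        )
    return pd.DataFrame(rows)


def format_survey_report(report) -> str:
    """Aligned plain-text rendering of :func:`survey_report` output."""
    widths = {
        "cohort": max(6, int(report["cohort"].str.len().max())),
    }
    lines = [
        f"{'cohort':<{widths['cohort']}}  {'n':>4}  "
        f"{'Cs29 allele freq (CI)':<24}  {'Cs6 positive freq (CI)':<24}"
    ]
    for row in report.itertuples(index=False):
        lines.append(
            f"{row.cohort:<{widths['cohort']}}  {row.n:>4}  "
            f"{row.cs29_display:<24}  {row.cs6_display:<24}"
        )
    return "\n".join(lines)
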