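"""Cohort summaries and hypothesis tests for per-cell window measurements.

Per-cell window summaries are pooled per experimental condition into a
:class:`Cohort` (cells collected over several experiments, unmodeled batch).
Condition comparisons use the two-sided Wilcoxon–Mann–Whitney rank-sum
test — appropriate because response distributions are right-skewed rather
than normal — with Holm–Bonferroni step-down adjustment across the family
of pairwise comparisons reported together.  Paired designs (e.g. matched
immunoblot lanes across independent experiments) use the paired Student
t-test.  Blot densitometry is normalized per blot (dividing by the blot
mean removes exposure differences) and then per lane by a pan-antibody
loading reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cohort",
    "ComparisonResult",
    "BlotGrid",
    "CohortSummary",
    "summarize",
    "rank_sum_test",
    "holm_bonferroni",
    "paired_t_test",
    "normalize_blot",
    "compare_cohorts",
]

#: Largest per-group size at which the rank-sum test enumerates the exact
#: null distribution (tie-free data only); above it, or with ties, the
#: normal approximation with tie and continuity corrections is used.
EXACT_THRESHOLD = 12


class CohortSummary(NamedTuple):
    mean: float
    sem: float
    n: int


@dataclass
class Cohort:
    """Per-cell window summaries for one experimental condition."""

    condition: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty vector")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        self.values = values

    @property
    def n(self) -> int:
        return int(self.values.size)

    def summarize(self) -> CohortSummary:
        return summarize(self.values)


@dataclass(frozen=True)
class ComparisonResult:
    """One pairwise comparison, optionally family-adjusted."""

    pair: tuple[str, str]
    statistic: float
    p_raw: float
    p_adjusted: float | None = None


def summarize(values: Sequence[float]) -> CohortSummary:
    """Mean, SEM (sample SD with n-1 denominator over sqrt(n)), and n.

    Raises
    ------
    ValueError
        If fewer than 2 values (SEM undefined).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("SEM undefined for n < 2")
    sem = values.std(ddof=1) / np.sqrt(n)
    return CohortSummary(mean=float(values.mean()), sem=float(sem), n=int(n))


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def rank_sum_test(
    a: Sequence[float],
    b: Sequence[float],
    exact_threshold: int = EXACT_THRESHOLD,
) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Exact enumeration of the permutation null when both samples are small
    (``min(n_a, n_b) <= exact_threshold``) and the pooled data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.

    Returns
    -------
    (statistic, p)
        The Mann–Whitney U statistic of the first sample and the two-sided
        p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    use_exact = min(a.size, b.size) <= exact_threshold and not _has_ties(pooled)
    result = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if use_exact else "asymptotic",
        use_continuity=True,
    )
    return float(result.statistic), float(result.pvalue)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p-values, in input order.

    Sort ascending, multiply the k-th smallest by ``K - k + 1``, enforce
    monotone non-decreasing along the sorted order, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p_values must be a non-empty vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, p_adjusted, _, _ = multipletests(p, method="holm")
    return p_adjusted


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired Student t-test on ``x - y``.

    Identical samples are the degenerate null and return ``(0.0, 1.0)``;
    constant nonzero differences have zero variance and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired t-test requires n >= 2")
    diff = x - y
    if np.all(diff == 0):
        return 0.0, 1.0
    if diff.std(ddof=1) == 0:
        raise ValueError("zero variance of differences: t statistic undefined")
    result = sps.ttest_rel(x, y)
    return float(result.statistic), float(result.pvalue)


@dataclass
class BlotGrid:
    """Densitometry band intensities across blots sharing the same lanes.

    ``band_intensities`` is a lane x antibody table (one column per blot,
    i.e. per antibody probing of the same membrane/lysates);
    ``pan_reference`` names the pan-antibody column used as the per-lane
    loading reference.
    """

    band_intensities: pd.DataFrame
    pan_reference: str

    def __post_init__(self) -> None:
        grid = pd.DataFrame(self.band_intensities).astype(float)
        if grid.empty:
            raise ValueError("band_intensities must be non-empty")
        if (grid.to_numpy() <= 0).any():
            raise ValueError("band intensities must be strictly positive")
        if self.pan_reference not in grid.columns:
            raise ValueError(f"pan reference column {self.pan_reference!r} missing")
        self.band_intensities = grid


def normalize_blot(grid: BlotGrid) -> pd.DataFrame:
    """Blot-mean then pan-lane normalization of band intensities.

    Each band is divided by the mean of its own blot (column), removing
    per-blot exposure/gain, then by the same lane's blot-mean-normalized
    pan-reference value, removing per-lane loading differences.  The pan
    column itself becomes identically 1.
    """
    intensities = grid.band_intensities
    blot_normalized = intensities / intensities.mean(axis=0)
    pan = blot_normalized[grid.pan_reference]
    return blot_normalized.div(pan, axis=0)


def compare_cohorts(
    cohorts: Sequence[Cohort],
    family: Sequence[tuple[str, str]],
) -> tuple[pd.DataFrame, list[ComparisonResult]]:
    """Condition summary table plus family-adjusted pairwise comparisons.

    Parameters
    ----------
    cohorts
        The cohorts, with unique condition labels.
    family
        The pairwise comparisons (condition-label pairs) that share one
        Holm–Bonferroni adjustment family.  Family membership is an
        explicit input: which comparisons are reported together is a
        scientific choice that cannot be inferred from the data.

    Returns
    -------
    (summary, comparisons)
        ``summary``: DataFrame with condition, mean, sem, n.
        ``comparisons``: one :class:`ComparisonResult` per pair, with raw
        and Holm-adjusted p-values.
    """
    by_label = {c.condition: c for c in cohorts}
    if len(by_label) != len(cohorts):
        raise ValueError("cohort condition labels must be unique")
    rows = []
    for cohort in cohorts:
        mean, sem, n = cohort.summarize()
        rows.append({"condition": cohort.condition, "mean": mean, "sem": sem, "n": n})
    summary = pd.DataFrame(rows)

    raw = []
    stats_ = []
    for left, right in family:
        statistic, p = rank_sum_test(by_label[left].values, by_label[right].values)
        stats_.append(statistic)
        raw.append(p)
    adjusted = holm_bonferroni(raw) if raw else np.array([])
    comparisons = [
        ComparisonResult(
            pair=(left, right),
            statistic=stat,
            p_raw=p,
            p_adjusted=float(p_adj),
        )
        for (left, right), stat, p, p_adj in zip(family, stats_, raw, adjusted)
    ]
    return summary, comparisons
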