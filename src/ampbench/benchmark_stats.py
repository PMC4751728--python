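"""Comparative reporting: coverage cost, cluster sizes, paired tests, correlations.

Error correction trades sequencing coverage for sensitivity: the reciprocal
of the retained fraction is the fold increase in per-nucleotide sequencing
cost.  This module computes that accounting, the tag cluster-size
distribution, paired Wilcoxon signed-rank comparisons between scheme error
profiles, Shapiro-Wilk normality checks, and replicate/strand Pearson
correlations with an optional least-squares fit.

No multiple-testing correction is applied; reported p-values are raw.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .consensus_schemes import ReadGroup, SchemeResult
from .error_profiling import ErrorProfile


def coverage_report(results: dict[str, SchemeResult | tuple[int, int]]) -> pd.DataFrame:
    """Retention fraction and fold cost per stratum.

    Accepts SchemeResult objects or raw ``(raw_reads, retained_records)``
    pairs keyed by stratum label.  Zero retention reports an infinite fold
    cost; otherwise fold_cost * retention == 1 exactly.
    """
    rows = []
    for label, value in results.items():
        if isinstance(value, SchemeResult):
            raw, retained = value.raw_reads, len(value.records)
        else:
            raw, retained = value
        if retained > raw:
            raise ValueError(f"{label}: retained ({retained}) exceeds raw ({raw})")
        if raw < 0 or retained < 0:
            raise ValueError(f"{label}: counts must be non-negative")
        retention = retained / raw if raw else 0.0
        fold = 1.0 / retention if retention > 0 else np.inf
        rows.append(
            {
                "stratum": label,
                "raw_reads": raw,
                "retained": retained,
                "retention": retention,
                "fold_cost": fold,
            }
        )
    return pd.DataFrame(rows)


def fold_cost(retention: float) -> float:
    """Per-nucleotide sequencing-cost multiplier: 1/retention (inf at 0)."""
    if not 0 <= retention <= 1:
        raise ValueError("retention must lie in [0, 1]")
    return 1.0 / retention if retention > 0 else np.inf


@dataclass
class ClusterSizeDistribution:
    """Histogram of reads-per-tag with singleton accounting.

    Singleton tags largely arise from sequencing errors inside the tag
    itself, so the mean cluster size is reported excluding them.
    """

    histogram: dict[int, int]
    singleton_count: int
    mean_excluding_singletons: float
    total_reads: int

    def check_mass(self) -> bool:
        return sum(s * c for s, c in self.histogram.items()) == self.total_reads


def cluster_size_distribution(
    groups: Iterable[ReadGroup | int],
) -> ClusterSizeDistribution:
    """Summarize tag cluster sizes from ReadGroups (or plain sizes)."""
    sizes = [g.size if isinstance(g, ReadGroup) else int(g) for g in groups]
    hist = Counter(sizes)
    non_singleton = [s for s in sizes if s > 1]
    return ClusterSizeDistribution(
        histogram=dict(sorted(hist.items())),
        singleton_count=hist.get(1, 0),
        mean_excluding_singletons=float(np.mean(non_singleton)) if non_singleton else np.nan,
        total_reads=sum(sizes),
    )


@dataclass
class SchemeComparison:
    """Paired Wilcoxon signed-rank comparison of two error profiles."""

    label_a: str
    label_b: str
    types: tuple[str, ...]
    n_pairs: int  # non-zero-difference pairs actually tested
    statistic: float
    pvalue: float
    direction: str  # "A<B", "A>B", or "A=B"


def _paired_rates(
    profile_a: ErrorProfile,
    profile_b: ErrorProfile,
    types: Sequence[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Stacked per-position rate vectors over the selected types (positions aligned)."""
    if profile_a.ref_length != profile_b.ref_length:
        raise ValueError("profiles must share positions")
    xs, ys = [], []
    for etype in types:
        xs.append(profile_a.rate_vector(etype))
        ys.append(profile_b.rate_vector(etype))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ok = ~(np.isnan(x) | np.isnan(y))
    return x[ok], y[ok]


def compare_schemes(
    profile_a: ErrorProfile,
    profile_b: ErrorProfile,
    types: Sequence[str],
    label_a: str = "A",
    label_b: str = "B",
) -> SchemeComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-position rates.

    The pairing unit is position x type within the selected types (pass a
    single type for a within-type test, several for a pooled test).
    Zero-difference pairs are dropped per the standard convention; if every
    pair is zero the test is undefined and reported with p = 1.
    """
    x, y = _paired_rates(profile_a, profile_b, types)
    diff = x - y
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return SchemeComparison(label_a, label_b, tuple(types), 0, np.nan, 1.0, "A=B")
    stat, p = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    med = float(np.median(nonzero))
    direction = "A<B" if med < 0 else ("A>B" if med > 0 else "A=B")
    return SchemeComparison(
        label_a, label_b, tuple(types), int(nonzero.size), float(stat), float(p), direction
    )


def normality_check(rates: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p for a per-position rate vector.

    Requires at least 3 finite values; a constant vector is degenerate and
    reported as (nan, nan).
    """
    arr = np.asarray(rates, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise ValueError("normality check requires at least 3 values")
    if np.all(arr == arr[0]):
        return (np.nan, np.nan)
    res = stats.shapiro(arr)
    return (float(res.statistic), float(res.pvalue))


def correlation_report(
    profile_x: ErrorProfile,
    profile_y: ErrorProfile,
    types: Sequence[str] | None = None,
    fit: bool = False,
) -> pd.DataFrame:
    """Pearson r per error type across positions; optional OLS fit of y on x.

    Used for replicate-vs-replicate and forward-vs-reverse contrasts.  If
    either rate vector has zero variance, r is undefined and reported NaN.
    """
    types = tuple(types or profile_x.types)
    rows = []
    for etype in types:
        x, y = _paired_rates(profile_x, profile_y, [etype])
        row: dict = {"type": etype, "n_positions": int(x.size)}
        if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
            row.update({"pearson_r": np.nan, "pvalue": np.nan})
            if fit:
                row.update({"slope": np.nan, "intercept": np.nan})
        else:
            r, p = stats.pearsonr(x, y)
            row.update({"pearson_r": float(r), "pvalue": float(p)})
            if fit:
                reg = stats.linregress(x, y)
                row.update({"slope": float(reg.slope), "intercept": float(reg.intercept)})
        rows.append(row)
    return pd.DataFrame(rows)
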