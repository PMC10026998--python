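"""Rank-based inverse-normal normalization and descriptive statistics.

The normalization maps each value to the standard-normal quantile of
``(R - 0.5) / N`` where R is its (average, for ties) rank among the N
values of its variable.  It removes marginal skewness while preserving
rank order — the operation that turns a selection-skewed cohort into a
spuriously SLODR-like one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohorts import Cohort, DEFAULT_PAIR_MAP

__all__ = [
    "rank_inverse_normal",
    "normalize_cohort",
    "skewness_g1",
    "describe",
    "DescriptivesReport",
]


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Map values to standard-normal quantiles of (rank - 0.5) / N.

    Ties receive average ranks.  Raises for fewer than 2 values or an
    all-equal vector (ranks carry no ordering information there).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if x.size < 2:
        raise ValueError("need at least 2 values to normalize")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("all values are equal; ranks are undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / x.size)


def normalize_cohort(cohort: Cohort) -> Cohort:
    """Apply :func:`rank_inverse_normal` to every variable of a cohort."""
    new = np.column_stack([rank_inverse_normal(c) for c in cohort.scores.T])
    return cohort.with_transform(new, {"step": "rank_inverse_normal"})


def skewness_g1(values: np.ndarray) -> float:
    """Adjusted Fisher–Pearson skewness G1 = g1 * sqrt(n(n-1)) / (n-2)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("skewness needs at least 3 values")
    if np.var(x) == 0:
        raise ValueError("skewness undefined for zero-variance input")
    return float(stats.skew(x, bias=False))


@dataclass
class DescriptivesReport:
    """Per-variable moments plus the pairwise-correlation summaries."""

    variable_names: tuple
    mean: np.ndarray
    sd: np.ndarray
    skewness: np.ndarray
    correlations: np.ndarray
    within_pair: dict          # pair label -> correlation
    between_pair_mean: float
    between_pair_sd: float
    n: int

    @property
    def mean_skewness(self) -> float:
        return float(np.mean(self.skewness))

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "variables": list(self.variable_names),
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "skewness": self.skewness.tolist(),
            "mean_skewness": self.mean_skewness,
            "correlations": self.correlations.tolist(),
            "within_pair": {k: float(v) for k, v in self.within_pair.items()},
            "between_pair_mean": self.between_pair_mean,
            "between_pair_sd": self.between_pair_sd,
        }


def describe(cohort: Cohort, pair_map: tuple = DEFAULT_PAIR_MAP) -> DescriptivesReport:
    """Skewness and correlation summary in the pair grouping of the design.

    ``pair_map`` assigns each of the 4 variables to one of two pairs;
    the between-pair summary averages the 4 cross-pair correlations.
    """
    x = cohort.scores
    if x.shape[0] < 3:
        raise ValueError("descriptives need at least 3 respondents")
    corr = np.corrcoef(x, rowvar=False)
    skew = np.array([skewness_g1(c) for c in x.T])
    pairs = np.asarray(pair_map)
    within, between = {}, []
    for i in range(4):
        for j in range(i + 1, 4):
            if pairs[i] == pairs[j]:
                label = f"{cohort.variable_names[i]}-{cohort.variable_names[j]}"
                within[label] = corr[i, j]
            else:
                between.append(corr[i, j])
    between = np.asarray(between)
    return DescriptivesReport(
        variable_names=cohort.variable_names,
        mean=x.mean(axis=0),
        sd=x.std(axis=0, ddof=1),
        skewness=skew,
        correlations=corr,
        within_pair=within,
        between_pair_mean=float(between.mean()),
        between_pair_sd=float(between.std(ddof=1)),
        n=x.shape[0],
    )
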