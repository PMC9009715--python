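"""Agreement and group-comparison statistics.

Covers the validation statistics of the pipeline: root-mean-square error,
Bland–Altman bias and 95 % limits of agreement, and independent-samples
t-tests in both pooled-variance and Welch forms.  The t-test accepts
either raw observations or ``GroupSummary`` objects (n, mean, sample SD),
because published cohorts are often reported only as sex-stratified
summaries that must be pooled before comparison.  Sample SD (n−1) is used
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .types import DomainError, StructuralError

__all__ = [
    "GroupSummary",
    "AgreementReport",
    "ScreenReport",
    "rmse",
    "bland_altman",
    "independent_t",
    "group_screen",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, and sample standard deviation of one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DomainError(f"group summary needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise DomainError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def from_data(cls, x: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(x, dtype=float)
        if arr.size < 2:
            raise DomainError("need at least 2 observations")
        return cls(n=arr.size, mean=float(arr.mean()), sd=float(arr.std(ddof=1)))

    @classmethod
    def pool(cls, parts: Iterable["GroupSummary"]) -> "GroupSummary":
        """Combine stratum summaries into one group.

        Combined SS = Σ within-stratum SS + Σ n·(stratum mean − grand mean)².
        """
        parts = list(parts)
        n = sum(p.n for p in parts)
        mean = sum(p.n * p.mean for p in parts) / n
        ss = sum((p.n - 1) * p.sd**2 + p.n * (p.mean - mean) ** 2 for p in parts)
        return cls(n=n, mean=mean, sd=float(np.sqrt(ss / (n - 1))))


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman bias and 95 % limits of agreement (bias ± 1.96·SD)."""

    bias: float
    loa_low: float
    loa_high: float
    n_outside: int


@dataclass(frozen=True)
class ScreenReport:
    """Normality / variance-homogeneity screen with a variant recommendation."""

    shapiro_p: dict[str, float | None]
    levene_p: float
    recommendation: str  # "pooled" or "welch"


def rmse(predicted: Sequence[float], measured: Sequence[float]) -> float:
    """Root-mean-square error √(Σ(p−m)²/N)."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.ndim != 1 or p.size == 0:
        raise StructuralError(
            f"predicted {p.shape} and measured {m.shape} must be equal non-empty 1-D"
        )
    return float(np.sqrt(np.mean((p - m) ** 2)))


def bland_altman(
    estimated: Sequence[float], measured: Sequence[float]
) -> AgreementReport:
    """Agreement between paired estimates and measurements.

    Differences are estimated − measured; limits of agreement are
    bias ± 1.96 times their sample SD.
    """
    e = np.asarray(estimated, dtype=float)
    m = np.asarray(measured, dtype=float)
    if e.shape != m.shape or e.ndim != 1:
        raise StructuralError("paired lists of equal length required")
    if e.size < 2:
        raise DomainError("Bland-Altman needs at least 2 pairs")
    d = e - m
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(((d < lo) | (d > hi)).sum())
    return AgreementReport(bias=bias, loa_low=lo, loa_high=hi, n_outside=outside)


def _as_summary(g) -> GroupSummary:
    return g if isinstance(g, GroupSummary) else GroupSummary.from_data(g)


def independent_t(group_a, group_b, variant: str = "pooled") -> tuple[float, float]:
    """Independent-samples t statistic and degrees of freedom.

    Groups may be raw sequences or ``GroupSummary`` objects.  ``pooled``
    uses the pooled-variance t with df = n_a + n_b − 2; ``welch`` uses the
    Welch statistic with Welch–Satterthwaite df.  Zero variance in both
    groups with equal means yields t = 0 by convention.
    """
    a, b = _as_summary(group_a), _as_summary(group_b)
    if variant not in ("pooled", "welch"):
        raise DomainError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    diff = a.mean - b.mean
    if a.sd == 0.0 and b.sd == 0.0:
        if diff == 0.0:
            df = a.n + b.n - 2 if variant == "pooled" else float(a.n + b.n - 2)
            return 0.0, float(df)
        raise DomainError("zero variance in both groups with unequal means")
    if variant == "pooled":
        df = a.n + b.n - 2
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
        t = diff / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        return float(t), float(df)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = diff / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return float(t), float(df)


def group_screen(groups: Mapping[str, Sequence[float]]) -> ScreenReport:
    """Shapiro–Wilk normality per group plus Levene's homogeneity test.

    Recommends the Welch t variant when Levene rejects equal variances at
    p < 0.05, otherwise the pooled variant.  Groups with fewer than 3
    observations skip the normality test with a warning.
    """
    shapiro_p: dict[str, float | None] = {}
    arrays = []
    for name, data in groups.items():
        arr = np.asarray(data, dtype=float)
        arrays.append(arr)
        if arr.size < 3:
            warnings.warn(f"group {name!r} has n < 3; Shapiro-Wilk skipped")
            shapiro_p[name] = None
        else:
            shapiro_p[name] = float(sps.shapiro(arr).pvalue)
    levene_p = float(sps.levene(*arrays).pvalue)
    return ScreenReport(
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        recommendation="welch" if levene_p < 0.05 else "pooled",
    )
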