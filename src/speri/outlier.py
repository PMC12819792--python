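"""Tukey interquartile-range outlier fences, per analyte per stratum.

An animal is removed when any of its seven analytes lies strictly more than
``k`` interquartile ranges beyond the first or third quartile of its own
reference stratum (default k = 1.5). Removal is animal-level and single
pass: fences are not recomputed after removals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .datamodel import ANALYTES, CaptureRecord, Stratum, assign_stratum

__all__ = [
    "Fences",
    "FlaggedAnalyte",
    "quantile",
    "tukey_fences",
    "remove_outlier_animals",
    "QUANTILE_ESTIMATORS",
]

#: supported quartile rules: numpy linear interpolation of order statistics
#: (h = (n-1)p + 1), plus the two classic median-split hinge variants
QUANTILE_ESTIMATORS = ("linear", "tukey-inclusive", "tukey-exclusive")


def _hinge_quartiles(x: np.ndarray, inclusive: bool) -> tuple[float, float, float]:
    """Median-split quartiles: Q1/Q3 are medians of the lower/upper half.

    The inclusive variant keeps the middle observation in both halves when
    n is odd; the exclusive variant drops it.
    """
    n = x.size
    med = float(np.median(x))
    if n == 1:
        return med, med, med
    half = (n + 1) // 2 if (n % 2 == 1 and inclusive) else n // 2
    lower = x[:half]
    upper = x[n - half:]
    return float(np.median(lower)), med, float(np.median(upper))


def quantile(values: Sequence[float], p: float, estimator: str = "linear") -> float:
    """Empirical quantile of a sample.

    The default estimator interpolates order statistics at rank
    h = (n-1)p + 1 (1-based). The Tukey hinge estimators are defined only at
    p in {0.25, 0.5, 0.75} and fall back to linear interpolation elsewhere
    (reference-limit percentiles such as 0.025 have no hinge definition).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("quantile of an empty sample")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"quantile probability out of range: {p}")
    if estimator not in QUANTILE_ESTIMATORS:
        raise ValueError(f"unknown quantile estimator {estimator!r}")
    if estimator != "linear" and p in (0.25, 0.5, 0.75):
        q1, med, q3 = _hinge_quartiles(np.sort(x), estimator == "tukey-inclusive")
        return {0.25: q1, 0.5: med, 0.75: q3}[p]
    return float(np.quantile(x, p, method="linear"))


@dataclass(frozen=True)
class Fences:
    """Tukey fences for one analyte in one stratum (concentrations in g/dL)."""

    analyte: str
    stratum: str
    q1: float
    q3: float
    k: float = 1.5

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1

    @property
    def lower(self) -> float:
        return self.q1 - self.k * self.iqr

    @property
    def upper(self) -> float:
        return self.q3 + self.k * self.iqr

    def is_outlier(self, value: float) -> bool:
        """Strictly beyond a fence; values exactly on a fence are inside."""
        return value < self.lower or value > self.upper


def tukey_fences(
    values: Sequence[float],
    k: float = 1.5,
    *,
    analyte: str = "",
    stratum: str = "",
    estimator: str = "linear",
    min_n: int = 4,
) -> Optional[Fences]:
    """Compute Q1/Q3-based outlier fences for one analyte sample.

    Returns None (with a warning) below ``min_n`` observations — too few
    points to estimate quartiles meaningfully, so no flagging occurs for
    that analyte/stratum.
    """
    x = np.asarray(values, dtype=float)
    if x.size < min_n:
        warnings.warn(
            f"only {x.size} values for {analyte or 'analyte'} in "
            f"{stratum or 'stratum'} (min {min_n}); outlier fences skipped",
            stacklevel=2,
        )
        return None
    return Fences(
        analyte=analyte,
        stratum=stratum,
        q1=quantile(x, 0.25, estimator),
        q3=quantile(x, 0.75, estimator),
        k=k,
    )


@dataclass(frozen=True)
class FlaggedAnalyte:
    """One flagged value: which analyte of which animal broke which fence."""

    animal_id: str
    stratum: str
    analyte: str
    value: float
    lower: float
    upper: float


def remove_outlier_animals(
    cohort: Sequence[CaptureRecord],
    strata: Iterable[Stratum],
    analytes: Sequence[str] = ANALYTES,
    *,
    k: float = 1.5,
    estimator: str = "linear",
    min_n: int = 4,
    pooled: bool = False,
) -> tuple[list[CaptureRecord], list[FlaggedAnalyte]]:
    """Remove animals with any analyte outside its stratum's Tukey fences.

    Fences are computed within each reference stratum (``pooled=False``,
    the default, since intervals are stratified) or once on the pooled
    cohort. Single pass; records without an assignable stratum are left
    untouched here (the exclusion cascade routes them elsewhere).

    Returns the kept records (input order preserved) and the flag report.
    """
    strata = list(strata)
    by_stratum: dict[Optional[str], list[tuple[int, CaptureRecord]]] = {}
    labels: dict[int, Optional[str]] = {}
    for i, rec in enumerate(cohort):
        s = assign_stratum(rec, strata)
        label = s.label if s else None
        labels[i] = label
        by_stratum.setdefault(label, []).append((i, rec))

    if pooled:
        groups = {"pooled": [(i, r) for g in by_stratum.values() for i, r in g]}
    else:
        groups = {lab: members for lab, members in by_stratum.items() if lab is not None}

    flagged: list[FlaggedAnalyte] = []
    flagged_idx: set[int] = set()
    for label, members in sorted(groups.items()):
        for analyte in analytes:
            pairs = [
                (i, r.panel.value(analyte))
                for i, r in members
                if r.panel.value(analyte) is not None
            ]
            if not pairs:
                continue
            fences = tukey_fences(
                [v for _, v in pairs],
                k,
                analyte=analyte,
                stratum=label,
                estimator=estimator,
                min_n=min_n,
            )
            if fences is None:
                continue
            for i, v in pairs:
                if fences.is_outlier(v):
                    flagged.append(
                        FlaggedAnalyte(
                            animal_id=cohort[i].animal_id,
                            stratum=label,
                            analyte=analyte,
                            value=v,
                            lower=fences.lower,
                            upper=fences.upper,
                        )
                    )
                    flagged_idx.add(i)

    kept = [r for i, r in enumerate(cohort) if i not in flagged_idx]
    return kept, flagged
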