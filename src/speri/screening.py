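"""Reference-interval flagging as a screen for pathogen seropositivity.

Each analyte is treated as a crude diagnostic: an animal whose value falls
outside its own stratum's reference interval is "flagged". Against the
grouped serostatus (bacterial = Brucella + Erysipelothrix, parasitic =
Toxoplasma + Neospora) this yields a confusion matrix per analyte x group,
from which sensitivity (flagged fraction of seropositives) and specificity
(unflagged fraction of seronegatives) are computed. Animals without an RI
for their stratum (adult males) or without evaluable group serology are
not counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .datamodel import (
    ANALYTES,
    CaptureRecord,
    PATHOGEN_GROUPS,
    SeroStatus,
    Stratum,
    DEFAULT_STRATA,
    assign_stratum,
)
from .refint import AnalyteRI

__all__ = [
    "ScreeningResult",
    "flag_out_of_interval",
    "evaluate_screen",
    "screen_all",
    "screening_to_frame",
]


def flag_out_of_interval(value: Optional[float], ri: AnalyteRI) -> Optional[bool]:
    """True iff the value lies strictly outside [lri, uri].

    Boundary values are inside. A missing value is not evaluable and
    returns None (excluded from confusion counts).
    """
    if value is None:
        return None
    return value < ri.lri or value > ri.uri


@dataclass(frozen=True)
class ScreeningResult:
    """Confusion counts and operating characteristics for one analyte x group."""

    analyte: str
    pathogen_group: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> Optional[float]:
        """tp / (tp + fn); None (NA) when there are no evaluable positives."""
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> Optional[float]:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None


def _ri_lookup(ri_tables: Iterable[AnalyteRI]) -> dict[tuple[str, str], AnalyteRI]:
    return {(r.stratum, r.analyte): r for r in ri_tables}


def evaluate_screen(
    records: Sequence[CaptureRecord],
    ri_tables: Sequence[AnalyteRI],
    pathogen_group: str,
    analyte: str,
    *,
    strata: Iterable[Stratum] = DEFAULT_STRATA,
) -> ScreeningResult:
    """Confusion counts for one analyte against one pathogen group.

    Each record is matched to the RI of its own stratum. Group serostatus:
    positive if positive to any pathogen in the group, negative if negative
    to all tested pathogens in the group, otherwise not evaluable.
    """
    if pathogen_group not in PATHOGEN_GROUPS:
        raise ValueError(f"unknown pathogen group {pathogen_group!r}")
    strata = list(strata)
    lookup = _ri_lookup(ri_tables)
    tp = fp = tn = fn = 0
    for rec in records:
        stratum = assign_stratum(rec, strata)
        if stratum is None:
            continue
        ri = lookup.get((stratum.label, analyte))
        if ri is None:
            continue
        status = rec.serology.group_status(pathogen_group)
        if status is SeroStatus.UNTESTED:
            continue
        flagged = flag_out_of_interval(rec.panel.value(analyte), ri)
        if flagged is None:
            continue
        if status is SeroStatus.POSITIVE:
            tp += flagged
            fn += not flagged
        else:
            fp += flagged
            tn += not flagged
    return ScreeningResult(analyte, pathogen_group, tp=tp, fp=fp, tn=tn, fn=fn)


def screen_all(
    records: Sequence[CaptureRecord],
    ri_tables: Sequence[AnalyteRI],
    *,
    analytes: Sequence[str] = ANALYTES,
    groups: Sequence[str] = ("bacterial", "parasitic"),
    strata: Iterable[Stratum] = DEFAULT_STRATA,
) -> list[ScreeningResult]:
    """Every analyte x pathogen-group combination (7 x 2 = 14 by default)."""
    return [
        evaluate_screen(records, ri_tables, g, a, strata=strata)
        for a in analytes
        for g in groups
    ]


def screening_to_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Report table: counts plus sens/spec as percentages to 1 decimal."""
    def pct(x: Optional[float]) -> Optional[float]:
        return None if x is None else round(100.0 * x, 1)

    return pd.DataFrame(
        [
            {
                "analyte": r.analyte,
                "group": r.pathogen_group,
                "tp": r.tp,
                "fp": r.fp,
                "tn": r.tn,
                "fn": r.fn,
                "sensitivity_pct": pct(r.sensitivity),
                "specificity_pct": pct(r.specificity),
            }
            for r in results
        ]
    )
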