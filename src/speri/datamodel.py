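"""Core domain types for serum-protein-electrophoresis (SPE) cohort analysis.

The unit of observation is a *capture event*: one blood draw from one
free-ranging animal, carrying a six-analyte SPE panel (total protein,
albumin, and the four globulin fractions, all in g/dL), serostatus for four
pathogens, and the health flags used by the exclusion cascade.

Reference intervals are computed within *strata* — season x age-class x sex
subgroups — because serum protein levels shift with season and pregnancy.
"""

from __future__ import annotations

import datetime as _dt
import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "Season",
    "Sex",
    "AgeClass",
    "SeroStatus",
    "AnalytePanel",
    "SerologyPanel",
    "CaptureRecord",
    "Stratum",
    "ANALYTES",
    "MEASURED_FRACTIONS",
    "BACTERIAL_PATHOGENS",
    "PARASITIC_PATHOGENS",
    "PATHOGEN_GROUPS",
    "DEFAULT_STRATA",
    "season_of",
    "derive_panel_fields",
    "DegeneratePanelError",
]


class Season(str, enum.Enum):
    FALL = "fall"        # August-October
    SPRING = "spring"    # March-May
    SUMMER = "summer"    # June-July
    UNMAPPABLE = "unmappable"  # November-February: no defined capture season


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class AgeClass(str, enum.Enum):
    ADULT = "adult"        # >3 years
    YEARLING = "yearling"  # 10-14 months


class SeroStatus(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    UNTESTED = "untested"


#: the seven analytes every reference-interval table reports, in table order
ANALYTES = (
    "ag_ratio",
    "albumin",
    "alpha1",
    "alpha2",
    "beta",
    "gamma",
    "total_protein",
)

#: the five electrophoretic fractions actually measured by densitometry
MEASURED_FRACTIONS = ("albumin", "alpha1", "alpha2", "beta", "gamma")

BACTERIAL_PATHOGENS = ("brucella", "erysipelothrix")
PARASITIC_PATHOGENS = ("toxoplasma", "neospora")
PATHOGEN_GROUPS = {
    "bacterial": BACTERIAL_PATHOGENS,
    "parasitic": PARASITIC_PATHOGENS,
}

_SEASON_BY_MONTH = {
    8: Season.FALL, 9: Season.FALL, 10: Season.FALL,
    3: Season.SPRING, 4: Season.SPRING, 5: Season.SPRING,
    6: Season.SUMMER, 7: Season.SUMMER,
}


def season_of(capture_date: _dt.date) -> Season:
    """Map a capture date to its capture season.

    Fall is August-October, spring March-May, summer June-July. The
    remaining months (November-February) fall in no defined capture season
    and map to ``Season.UNMAPPABLE``; downstream stages exclude such
    records with an explicit "out-of-season" ledger reason.
    """
    return _SEASON_BY_MONTH.get(capture_date.month, Season.UNMAPPABLE)


class DegeneratePanelError(ValueError):
    """Raised when the globulin fractions sum to zero (A:G undefined)."""


@dataclass(frozen=True)
class AnalytePanel:
    """One SPE panel. All concentrations in g/dL; A:G is dimensionless.

    ``total_globulins`` and ``ag_ratio`` are derived fields; when an input
    file already carries an instrument-computed A:G it is validated against
    albumin / total globulins rather than overwritten.
    """

    total_protein: Optional[float] = None
    albumin: Optional[float] = None
    alpha1: Optional[float] = None
    alpha2: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    ag_ratio: Optional[float] = None
    total_globulins: Optional[float] = None

    def value(self, analyte: str) -> Optional[float]:
        return getattr(self, analyte)

    @property
    def complete(self) -> bool:
        """True when albumin and all four globulin fractions are present."""
        return all(getattr(self, a) is not None for a in MEASURED_FRACTIONS)


def derive_panel_fields(
    panel: AnalytePanel,
    *,
    ag_rel_tol: float = 0.02,
    tp_rel_tol: float = 0.05,
) -> AnalytePanel:
    """Fill ``total_globulins`` and ``ag_ratio`` from the measured fractions.

    Total globulins = alpha1 + alpha2 + beta + gamma, and A:G = albumin /
    total globulins. A supplied A:G is kept but checked against the derived
    value within ``ag_rel_tol`` relative tolerance (instrument ratios are
    rounded). Total protein comes from refractometry while the fractions come
    from densitometry, so |TP − (albumin + globulins)| beyond ``tp_rel_tol``
    relative is a warning, never an error.

    Idempotent: applying it twice yields the same panel.

    Raises
    ------
    DegeneratePanelError
        If the globulin fractions sum to zero.
    ValueError
        If a supplied A:G disagrees with albumin / total globulins beyond
        ``ag_rel_tol``, or a measured analyte is negative.
    """
    if not panel.complete:
        raise ValueError("cannot derive panel fields: incomplete fraction set")
    for a in MEASURED_FRACTIONS + ("total_protein",):
        v = getattr(panel, a)
        if v is not None and v < 0:
            raise ValueError(f"negative analyte value: {a}={v}")

    tg = panel.alpha1 + panel.alpha2 + panel.beta + panel.gamma
    if tg == 0:
        raise DegeneratePanelError("degenerate panel: total globulins are zero")
    ag = panel.albumin / tg

    if panel.ag_ratio is not None:
        if ag != 0 and abs(panel.ag_ratio - ag) > ag_rel_tol * abs(ag):
            raise ValueError(
                f"supplied A:G ratio {panel.ag_ratio:.4g} inconsistent with "
                f"albumin/globulins = {ag:.4g} (tolerance {ag_rel_tol:.0%})"
            )
        ag = panel.ag_ratio  # validated instrument value wins

    if panel.total_protein is not None:
        frac_sum = panel.albumin + tg
        if frac_sum > 0 and abs(panel.total_protein - frac_sum) > tp_rel_tol * frac_sum:
            warnings.warn(
                f"total protein {panel.total_protein:.3g} g/dL differs from "
                f"fraction sum {frac_sum:.3g} g/dL by more than {tp_rel_tol:.0%} "
                "(refractometer vs. densitometry)",
                stacklevel=2,
            )
    return replace(panel, total_globulins=tg, ag_ratio=ag)


@dataclass(frozen=True)
class SerologyPanel:
    """Serostatus for the four pathogens used as exclusion criteria."""

    brucella: SeroStatus = SeroStatus.UNTESTED
    erysipelothrix: SeroStatus = SeroStatus.UNTESTED
    toxoplasma: SeroStatus = SeroStatus.UNTESTED
    neospora: SeroStatus = SeroStatus.UNTESTED

    def status(self, pathogen: str) -> SeroStatus:
        return getattr(self, pathogen)

    def group_status(self, group: str) -> SeroStatus:
        """Serostatus for a pathogen group ("bacterial" or "parasitic").

        Positive if positive to ANY pathogen in the group; negative only if
        negative to ALL tested pathogens and at least one was tested;
        untested (not evaluable) otherwise.
        """
        statuses = [self.status(p) for p in PATHOGEN_GROUPS[group]]
        if SeroStatus.POSITIVE in statuses:
            return SeroStatus.POSITIVE
        tested = [s for s in statuses if s is not SeroStatus.UNTESTED]
        if tested and len(tested) == len(statuses):
            return SeroStatus.NEGATIVE
        return SeroStatus.UNTESTED


@dataclass(frozen=True)
class CaptureRecord:
    """One capture event: identity, demographics, SPE panel, serology, flags."""

    animal_id: str
    capture_date: _dt.date
    herd: str
    sex: Sex
    age_class: AgeClass
    panel: AnalytePanel
    serology: SerologyPanel = field(default_factory=SerologyPanel)
    clinical_illness: bool = False
    mortality_within_30d: bool = False
    hemolyzed: bool = False

    @property
    def season(self) -> Season:
        return season_of(self.capture_date)


@dataclass(frozen=True)
class Stratum:
    """A reference subgroup: age class x sex filter x season set.

    ``sex`` of ``None`` pools both sexes (the yearling stratum); ``seasons``
    is the set of admissible capture seasons.
    """

    label: str
    age_class: AgeClass
    sex: Optional[Sex]
    seasons: frozenset[Season]

    def matches(self, record: CaptureRecord) -> bool:
        if record.age_class is not self.age_class:
            return False
        if self.sex is not None and record.sex is not self.sex:
            return False
        return record.season in self.seasons


#: the published stratification: adult females per season, yearlings pooled
DEFAULT_STRATA = (
    Stratum("adult-female-fall", AgeClass.ADULT, Sex.FEMALE, frozenset({Season.FALL})),
    Stratum("adult-female-summer", AgeClass.ADULT, Sex.FEMALE, frozenset({Season.SUMMER})),
    Stratum("adult-female-spring", AgeClass.ADULT, Sex.FEMALE, frozenset({Season.SPRING})),
    Stratum(
        "yearling",
        AgeClass.YEARLING,
        None,
        frozenset({Season.SPRING, Season.SUMMER}),
    ),
)


def assign_stratum(
    record: CaptureRecord, strata: Iterable[Stratum] = DEFAULT_STRATA
) -> Optional[Stratum]:
    """Return the first stratum matching the record, or None.

    The default strata are mutually exclusive, so "first" is unambiguous;
    records with no stratum (adult males, out-of-season captures) are routed
    to the insufficient-stratum ledger reason downstream.
    """
    for s in strata:
        if s.matches(record):
            return s
    return None
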