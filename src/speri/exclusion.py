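"""Eligibility rules producing the reference cohort, with a full audit trail.

The cascade mirrors how reference-population cleaning is reported in
clinical-pathology studies: recaptures are collapsed to the first capture,
then records are tested against an ordered list of rules — out-of-season
capture, seropositivity to each of four pathogens, analyte outliers, and
the health flags (clinical illness, mortality within 30 days, hemolysis).
The first rule a record fails becomes its *attributed* reason, so the
per-reason counts are additive: kept + sum(attributed) = input. Animals
surviving every rule but belonging to no reference stratum (adult males,
for which no interval is built) are reported under "insufficient-stratum".
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .datamodel import (
    CaptureRecord,
    Season,
    SeroStatus,
    Stratum,
    DEFAULT_STRATA,
    assign_stratum,
)
from .outlier import FlaggedAnalyte, remove_outlier_animals

__all__ = [
    "ExclusionLedger",
    "dedup_recaptures",
    "apply_exclusions",
    "DEFAULT_RULE_ORDER",
    "RECORD_RULES",
    "OUTLIER_RULE",
    "INSUFFICIENT_STRATUM",
]

OUTLIER_RULE = "analyte-outlier"
INSUFFICIENT_STRATUM = "insufficient-stratum"

#: serology first (in the order the counts are reported), then outliers,
#: then the pooled health flags — the order under which the published
#: per-reason counts are additive
DEFAULT_RULE_ORDER = (
    "out-of-season",
    "seropositive-erysipelothrix",
    "seropositive-neospora",
    "seropositive-toxoplasma",
    "seropositive-brucella",
    OUTLIER_RULE,
    "illness",
    "mortality-30d",
    "hemolysis",
)


def _sero_rule(pathogen: str) -> Callable[[CaptureRecord, bool], bool]:
    def rule(rec: CaptureRecord, strict: bool) -> bool:
        status = rec.serology.status(pathogen)
        if status is SeroStatus.POSITIVE:
            return True
        return strict and status is SeroStatus.UNTESTED

    return rule


#: record-level predicates; True means "exclude". The outlier rule is not
#: record-level (it needs per-stratum fences) and is handled as a stage.
RECORD_RULES: dict[str, Callable[[CaptureRecord, bool], bool]] = {
    "out-of-season": lambda r, _s: r.season is Season.UNMAPPABLE,
    "seropositive-erysipelothrix": _sero_rule("erysipelothrix"),
    "seropositive-neospora": _sero_rule("neospora"),
    "seropositive-toxoplasma": _sero_rule("toxoplasma"),
    "seropositive-brucella": _sero_rule("brucella"),
    "illness": lambda r, _s: r.clinical_illness,
    "mortality-30d": lambda r, _s: r.mortality_within_30d,
    "hemolysis": lambda r, _s: r.hemolyzed,
}

_HEALTH_RULES = ("illness", "mortality-30d", "hemolysis")


@dataclass
class ExclusionLedger:
    """Audit trail of the cascade.

    Event-level and animal-level tallies are both kept because a dataset may
    count capture events or unique animals; `input_events` is before
    recapture deduplication, `input_animals` after.
    """

    input_events: int = 0
    duplicate_events: int = 0
    input_animals: int = 0
    kept_n: int = 0
    counts: Counter = field(default_factory=Counter)
    #: animal_id -> {"triggered": [...], "attributed": reason}
    per_record: dict[str, dict] = field(default_factory=dict)
    rule_order: tuple[str, ...] = DEFAULT_RULE_ORDER

    @property
    def excluded_n(self) -> int:
        return sum(self.counts.values())

    @property
    def health_excluded_n(self) -> int:
        """Illness + 30-day mortality + hemolysis, pooled."""
        return sum(self.counts[r] for r in _HEALTH_RULES)

    def check_conservation(self) -> None:
        if self.kept_n + self.excluded_n != self.input_animals:
            raise AssertionError(
                f"ledger not conserved: kept {self.kept_n} + excluded "
                f"{self.excluded_n} != animals {self.input_animals}"
            )

    def to_dict(self) -> dict:
        return {
            "input_events": self.input_events,
            "duplicate_events": self.duplicate_events,
            "input_animals": self.input_animals,
            "kept_n": self.kept_n,
            "excluded_n": self.excluded_n,
            "rule_order": list(self.rule_order),
            "counts": dict(self.counts),
            "per_record": self.per_record,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_dict(), **kwargs)

    def summary(self) -> str:
        lines = [
            "Exclusion ledger",
            f"  capture events in:        {self.input_events}",
            f"  recapture duplicates:     {self.duplicate_events}",
            f"  unique animals:           {self.input_animals}",
        ]
        for reason in list(self.rule_order) + [INSUFFICIENT_STRATUM]:
            if self.counts[reason]:
                lines.append(f"  excluded {reason + ':':<25}{self.counts[reason]}")
        lines += [
            f"  excluded total:           {self.excluded_n}",
            f"    (health flags pooled:   {self.health_excluded_n})",
            f"  reference cohort:         {self.kept_n}",
        ]
        return "\n".join(lines)


def dedup_recaptures(
    records: Sequence[CaptureRecord],
) -> tuple[list[CaptureRecord], list[CaptureRecord]]:
    """Keep only the first capture event per animal.

    The record with the earliest capture date wins; ties on date are broken
    by stable input order (first occurrence wins). Idempotent. Returns
    (kept, duplicates), both in input order.
    """
    best: dict[str, int] = {}
    for i, rec in enumerate(records):
        j = best.get(rec.animal_id)
        if j is None or rec.capture_date < records[j].capture_date:
            best[rec.animal_id] = i
    keep_idx = set(best.values())
    kept = [r for i, r in enumerate(records) if i in keep_idx]
    dups = [r for i, r in enumerate(records) if i not in keep_idx]
    return kept, dups


def apply_exclusions(
    records: Sequence[CaptureRecord],
    rule_order: Sequence[str] = DEFAULT_RULE_ORDER,
    *,
    strata: Iterable[Stratum] = DEFAULT_STRATA,
    strict_serology: bool = False,
    dedup: bool = True,
    tukey_k: float = 1.5,
    quantile_estimator: str = "linear",
    outlier_min_n: int = 4,
    outlier_pooled: bool = False,
) -> tuple[list[CaptureRecord], ExclusionLedger]:
    """Run the cascade and return (reference cohort, ledger).

    Rules are applied as ordered stages over the surviving records, so the
    attributed reason is the first triggered rule in ``rule_order`` and the
    per-reason counts are disjoint. The outlier stage computes Tukey fences
    within each stratum on the records surviving all prior rules. With
    ``strict_serology`` an untested pathogen also excludes (attributed to
    that pathogen's rule).

    Raises
    ------
    ValueError
        If ``rule_order`` names an unknown rule.
    """
    strata = list(strata)
    unknown = [r for r in rule_order if r != OUTLIER_RULE and r not in RECORD_RULES]
    if unknown:
        raise ValueError(f"unknown exclusion rule(s): {', '.join(unknown)}")

    ledger = ExclusionLedger(rule_order=tuple(rule_order))
    ledger.input_events = len(records)

    if dedup:
        survivors, dups = dedup_recaptures(records)
    else:
        survivors, dups = list(records), []
    ledger.duplicate_events = len(dups)
    ledger.input_animals = len(survivors)

    def note(rec: CaptureRecord, reason: str, attributed: bool) -> None:
        entry = ledger.per_record.setdefault(
            rec.animal_id, {"triggered": [], "attributed": None}
        )
        if reason not in entry["triggered"]:
            entry["triggered"].append(reason)
        if attributed and entry["attributed"] is None:
            entry["attributed"] = reason
            ledger.counts[reason] += 1

    for rule in rule_order:
        if rule == OUTLIER_RULE:
            survivors, flagged = remove_outlier_animals(
                survivors,
                strata,
                k=tukey_k,
                estimator=quantile_estimator,
                min_n=outlier_min_n,
                pooled=outlier_pooled,
            )
            by_id: dict[str, list[FlaggedAnalyte]] = {}
            for f in flagged:
                by_id.setdefault(f.animal_id, []).append(f)
            for rec_id, flags in by_id.items():
                entry = ledger.per_record.setdefault(
                    rec_id, {"triggered": [], "attributed": None}
                )
                if OUTLIER_RULE not in entry["triggered"]:
                    entry["triggered"].append(OUTLIER_RULE)
                if entry["attributed"] is None:
                    entry["attributed"] = OUTLIER_RULE
                    ledger.counts[OUTLIER_RULE] += 1
                entry["flagged_analytes"] = [
                    {"analyte": f.analyte, "value": f.value,
                     "lower": f.lower, "upper": f.upper, "stratum": f.stratum}
                    for f in flags
                ]
            continue
        pred = RECORD_RULES[rule]
        still = []
        for rec in survivors:
            if pred(rec, strict_serology):
                note(rec, rule, attributed=True)
            else:
                still.append(rec)
        survivors = still

    # record (non-attributed) triggers for the remaining record-level rules,
    # so the per-record audit shows every reason a record would have failed
    for rec in records:
        entry = ledger.per_record.get(rec.animal_id)
        if entry is None or entry["attributed"] is None:
            continue
        for rule in rule_order:
            if rule == OUTLIER_RULE:
                continue
            if RECORD_RULES[rule](rec, strict_serology) and rule not in entry["triggered"]:
                entry["triggered"].append(rule)

    # animals surviving every rule but matching no stratum (adult males,
    # typically) are reported, not silently dropped
    cohort = []
    for rec in survivors:
        if assign_stratum(rec, strata) is None:
            note(rec, INSUFFICIENT_STRATUM, attributed=True)
        else:
            cohort.append(rec)

    ledger.kept_n = len(cohort)
    ledger.check_conservation()
    return cohort, ledger
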