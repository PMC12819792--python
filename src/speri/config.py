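"""Run configuration: every analysis threshold in one place.

Defaults are the conventional choices for reference-interval work: Tukey
k = 1.5, central 95% interval, 90% bootstrap CIs from 1,000 replicates,
Shapiro-Wilk alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import yaml

from .datamodel import DEFAULT_STRATA, Stratum
from .exclusion import DEFAULT_RULE_ORDER
from .refint import DEFAULT_SEED

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Analysis settings shared by the model, CLI and acceptance runs."""

    seed: int = DEFAULT_SEED
    rule_order: tuple[str, ...] = DEFAULT_RULE_ORDER
    strict_serology: bool = False
    quantile_estimator: str = "linear"
    ri_method: str = "nonparametric"
    ri_coverage: float = 0.95
    bootstrap_reps: int = 1000
    bootstrap_conf: float = 0.90
    shapiro_alpha: float = 0.05
    tukey_k: float = 1.5
    outlier_min_n: int = 4
    outlier_pooled: bool = False
    ri_min_n: int = 20
    #: screening denominator: "post-health" excludes ill/dead/hemolyzed
    #: animals from the screen (as from the RI); "all" keeps them
    screening_cohort: str = "post-health"
    strata: tuple[Stratum, ...] = field(default_factory=lambda: DEFAULT_STRATA)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rule_order"] = list(self.rule_order)
        d["strata"] = [s.label for s in self.strata]
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "strata"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        if "rule_order" in raw:
            raw["rule_order"] = tuple(raw["rule_order"])
        return cls(**raw)
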