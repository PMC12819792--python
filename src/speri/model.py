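"""The high-level modelling interface.

:class:`ReferenceIntervalModel` wraps the full pipeline — recapture
deduplication, the exclusion cascade, per-stratum Tukey outlier removal,
stratified nonparametric reference intervals with percentile-bootstrap
confidence limits, and RI-based serostatus screening — behind a
statsmodels-style ``Model.fit() -> Results`` surface::

    model = ReferenceIntervalModel.from_csv("captures.csv")
    res = model.fit(seed=7)
    print(res.summary())
    res.ri_frame          # the published-style RI tables as a DataFrame
    res.screening_frame   # sensitivity/specificity per analyte x group
    res.ledger            # the exclusion audit trail
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from . import io as _io
from .config import RunConfig
from .datamodel import ANALYTES, CaptureRecord, Season, SeroStatus
from .exclusion import ExclusionLedger, apply_exclusions, dedup_recaptures
from .refint import AnalyteRI, build_ri_table, format_ri_table, ri_table_to_frame
from .screening import ScreeningResult, screen_all, screening_to_frame

__all__ = ["ReferenceIntervalModel", "ReferenceIntervalResults"]


class ReferenceIntervalModel:
    """Stratified serum-protein reference intervals for a capture cohort.

    Parameters
    ----------
    records
        Capture events (one per blood draw), typed as
        :class:`~speri.datamodel.CaptureRecord`.
    config
        Analysis settings; defaults are the conventional reference-interval
        choices (Tukey k = 1.5, central 95% interval, 90% bootstrap CIs from
        1,000 replicates, Shapiro-Wilk alpha = 0.05).
    """

    def __init__(
        self,
        records: Sequence[CaptureRecord],
        config: Optional[RunConfig] = None,
    ) -> None:
        self.records = list(records)
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, config: Optional[RunConfig] = None, **kwargs
    ) -> "ReferenceIntervalModel":
        """Build from a flat capture table (see :mod:`speri.io` for the dialect)."""
        return cls(_io.frame_to_records(frame, **kwargs), config)

    @classmethod
    def from_csv(
        cls, path, config: Optional[RunConfig] = None, **kwargs
    ) -> "ReferenceIntervalModel":
        return cls(_io.read_captures(path, **kwargs), config)

    def fit(self, seed: Optional[int] = None) -> "ReferenceIntervalResults":
        """Run the full pipeline and return the results object.

        ``seed`` overrides the configured seed for the bootstrap;
        everything else in the pipeline is deterministic.
        """
        cfg = self.config
        use_seed = cfg.seed if seed is None else seed
        cohort, ledger = apply_exclusions(
            self.records,
            cfg.rule_order,
            strata=cfg.strata,
            strict_serology=cfg.strict_serology,
            tukey_k=cfg.tukey_k,
            quantile_estimator=cfg.quantile_estimator,
            outlier_min_n=cfg.outlier_min_n,
            outlier_pooled=cfg.outlier_pooled,
        )
        ri_tables = build_ri_table(
            cohort,
            cfg.strata,
            ANALYTES,
            method=cfg.ri_method,
            coverage=cfg.ri_coverage,
            b_reps=cfg.bootstrap_reps,
            conf=cfg.bootstrap_conf,
            alpha=cfg.shapiro_alpha,
            estimator=cfg.quantile_estimator,
            min_n=cfg.ri_min_n,
            seed=use_seed,
        )
        screening = screen_all(
            self._screening_cohort(), ri_tables, strata=cfg.strata
        )
        return ReferenceIntervalResults(
            model=self,
            cohort=cohort,
            ledger=ledger,
            ri_tables=ri_tables,
            screening=screening,
            seed=use_seed,
        )

    def _screening_cohort(self) -> list[CaptureRecord]:
        """Deduplicated records evaluated by the screen.

        Seropositive animals must stay in (they are the condition
        positives), so the screen runs on all first-capture records with a
        mappable season; in the default "post-health" mode the health-flag
        exclusions apply here as they do for the RI cohort.
        """
        kept, _ = dedup_recaptures(self.records)
        kept = [r for r in kept if r.season is not Season.UNMAPPABLE]
        if self.config.screening_cohort == "post-health":
            kept = [
                r for r in kept
                if not (r.clinical_illness or r.mortality_within_30d or r.hemolyzed)
            ]
        return kept


class ReferenceIntervalResults:
    """Fitted reference intervals, their uncertainties, and diagnostics."""

    def __init__(
        self,
        model: ReferenceIntervalModel,
        cohort: Sequence[CaptureRecord],
        ledger: ExclusionLedger,
        ri_tables: Sequence[AnalyteRI],
        screening: Sequence[ScreeningResult],
        seed: int,
    ) -> None:
        self.model = model
        self.cohort = list(cohort)
        self.ledger = ledger
        self.ri_tables = list(ri_tables)
        self.screening = list(screening)
        self.seed = seed

    @property
    def ri_frame(self) -> pd.DataFrame:
        return ri_table_to_frame(self.ri_tables)

    @property
    def screening_frame(self) -> pd.DataFrame:
        return screening_to_frame(self.screening)

    def stratum_n(self) -> dict[str, int]:
        """Reference-cohort size per stratum (n of each RI table)."""
        return {
            s.label: sum(1 for r in self.cohort if s.matches(r))
            for s in self.model.config.strata
        }

    def summary(self) -> str:
        """Aligned-text report: cohort accounting, RI tables, screening."""
        parts = [
            "Serum protein electrophoresis reference intervals",
            "=" * 50,
            self.ledger.summary(),
            "",
            "Cohort by stratum: "
            + ", ".join(f"{k} n={v}" for k, v in self.stratum_n().items()),
            f"Bootstrap: B={self.model.config.bootstrap_reps}, "
            f"conf={self.model.config.bootstrap_conf:.0%}, seed={self.seed}",
        ]
        for s in self.model.config.strata:
            rows = [r for r in self.ri_tables if r.stratum == s.label]
            if not rows:
                continue
            parts += ["", f"Reference intervals — {s.label} (n={rows[0].n})",
                      format_ri_table(rows, s.label)]
        spct = self.screening_frame
        if len(spct):
            parts += ["", "Screening against serostatus (RI flag as test)",
                      spct.to_string(index=False)]
        return "\n".join(parts)

    def plot_seasonal_intervals(self, ax=None):
        """Interval plot: per-season adult-female RIs with 90% CI whiskers.

        One box per analyte x season spanning the reference interval, a
        midline at the interval midpoint, whiskers for the bootstrap CIs.
        """
        import matplotlib.pyplot as plt

        rows = [r for r in self.ri_tables if r.stratum.startswith("adult-female")]
        if ax is None:
            _, ax = plt.subplots(figsize=(10, 5))
        seasons = sorted({r.stratum for r in rows})
        analytes = [a for a in ANALYTES if any(r.analyte == a for r in rows)]
        width = 0.8 / max(len(seasons), 1)
        for si, stratum in enumerate(seasons):
            for ai, analyte in enumerate(analytes):
                row = next(
                    (r for r in rows if r.stratum == stratum and r.analyte == analyte),
                    None,
                )
                if row is None:
                    continue
                x = ai + si * width - 0.4 + width / 2
                ax.bar(
                    x, row.uri - row.lri, bottom=row.lri, width=width * 0.9,
                    color=f"C{si}", alpha=0.5,
                    label=stratum if ai == 0 else None,
                )
                ax.plot(
                    [x, x], [row.lri_ci[0], row.uri_ci[1]],
                    color=f"C{si}", lw=1,
                )
                ax.plot(
                    [x - width / 3, x + width / 3],
                    [(row.lri + row.uri) / 2] * 2, color="k", lw=1,
                )
        ax.set_xticks(range(len(analytes)))
        ax.set_xticklabels(analytes, rotation=30, ha="right")
        ax.set_ylabel("g/dL (A:G dimensionless)")
        ax.legend()
        return ax
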