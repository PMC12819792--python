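"""Reading and writing the flat capture-record CSV dialect.

One row per capture event. Default headers::

    animal_id, capture_date (ISO 8601), herd, sex, age_class,
    tp_gdl, alb_gdl, a1_gdl, a2_gdl, beta_gdl, gamma_gdl, ag_ratio,
    sero_brucella, sero_erysipelothrix, sero_toxoplasma, sero_neospora,
    ill, died_30d, hemolyzed

Boolean columns accept {0, 1, true, false, yes, no}; serology accepts
{pos, neg, NA}. A ``column_map`` overrides individual header names.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .datamodel import (
    AgeClass,
    AnalytePanel,
    CaptureRecord,
    SeroStatus,
    SerologyPanel,
    Sex,
    derive_panel_fields,
)

DEFAULT_COLUMNS = {
    "animal_id": "animal_id",
    "capture_date": "capture_date",
    "herd": "herd",
    "sex": "sex",
    "age_class": "age_class",
    "total_protein": "tp_gdl",
    "albumin": "alb_gdl",
    "alpha1": "a1_gdl",
    "alpha2": "a2_gdl",
    "beta": "beta_gdl",
    "gamma": "gamma_gdl",
    "ag_ratio": "ag_ratio",
    "sero_brucella": "sero_brucella",
    "sero_erysipelothrix": "sero_erysipelothrix",
    "sero_toxoplasma": "sero_toxoplasma",
    "sero_neospora": "sero_neospora",
    "clinical_illness": "ill",
    "mortality_within_30d": "died_30d",
    "hemolyzed": "hemolyzed",
}

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}
_SERO = {
    "pos": SeroStatus.POSITIVE,
    "positive": SeroStatus.POSITIVE,
    "1": SeroStatus.POSITIVE,
    "neg": SeroStatus.NEGATIVE,
    "negative": SeroStatus.NEGATIVE,
    "0": SeroStatus.NEGATIVE,
    "na": SeroStatus.UNTESTED,
    "nan": SeroStatus.UNTESTED,
    "": SeroStatus.UNTESTED,
    "untested": SeroStatus.UNTESTED,
}


class SchemaError(ValueError):
    """The input table is missing required columns or holds bad values."""


def _parse_bool(raw, column: str) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE or s == "nan":
        return False
    raise SchemaError(f"unparseable boolean {raw!r} in column {column!r}")


def _parse_sero(raw) -> SeroStatus:
    s = str(raw).strip().lower()
    try:
        return _SERO[s]
    except KeyError:
        raise SchemaError(f"unparseable serostatus {raw!r}") from None


def _parse_float(raw) -> Optional[float]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    s = str(raw).strip()
    if s == "" or s.lower() in {"na", "nan"}:
        return None
    return float(s)


def frame_to_records(
    frame: pd.DataFrame,
    column_map: Optional[Mapping[str, str]] = None,
    *,
    derive: bool = True,
) -> list[CaptureRecord]:
    """Convert a capture table to typed records.

    With ``derive`` (default), total globulins and A:G are filled from the
    fractions for every complete panel; an A:G supplied in the file is
    validated, not overwritten.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    required = [
        cols[k]
        for k in ("animal_id", "capture_date", "sex", "age_class")
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"input is missing required column(s): {', '.join(missing)}")

    records: list[CaptureRecord] = []
    for _, row in frame.iterrows():
        def get(key: str, default=None):
            col = cols[key]
            return row[col] if col in frame.columns else default

        panel = AnalytePanel(
            total_protein=_parse_float(get("total_protein")),
            albumin=_parse_float(get("albumin")),
            alpha1=_parse_float(get("alpha1")),
            alpha2=_parse_float(get("alpha2")),
            beta=_parse_float(get("beta")),
            gamma=_parse_float(get("gamma")),
            ag_ratio=_parse_float(get("ag_ratio")),
        )
        if derive and panel.complete:
            panel = derive_panel_fields(panel)
        serology = SerologyPanel(
            brucella=_parse_sero(get("sero_brucella", "NA")),
            erysipelothrix=_parse_sero(get("sero_erysipelothrix", "NA")),
            toxoplasma=_parse_sero(get("sero_toxoplasma", "NA")),
            neospora=_parse_sero(get("sero_neospora", "NA")),
        )
        date_raw = get("capture_date")
        date = (
            date_raw.date()
            if isinstance(date_raw, pd.Timestamp)
            else _dt.date.fromisoformat(str(date_raw).strip()[:10])
        )
        records.append(
            CaptureRecord(
                animal_id=str(get("animal_id")),
                capture_date=date,
                herd=str(get("herd", "")),
                sex=Sex(str(get("sex")).strip().lower()),
                age_class=AgeClass(str(get("age_class")).strip().lower()),
                panel=panel,
                serology=serology,
                clinical_illness=_parse_bool(get("clinical_illness", 0), cols["clinical_illness"]),
                mortality_within_30d=_parse_bool(get("mortality_within_30d", 0), cols["mortality_within_30d"]),
                hemolyzed=_parse_bool(get("hemolyzed", 0), cols["hemolyzed"]),
            )
        )
    return records


def read_captures(
    path, column_map: Optional[Mapping[str, str]] = None, *, derive: bool = True
) -> list[CaptureRecord]:
    """Read a capture-event CSV into typed records."""
    return frame_to_records(pd.read_csv(path), column_map, derive=derive)


def _sero_str(s: SeroStatus) -> str:
    return {"positive": "pos", "negative": "neg", "untested": "NA"}[s.value]


def records_to_frame(records: Iterable[CaptureRecord]) -> pd.DataFrame:
    """Flatten records back into the default CSV dialect."""
    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "capture_date": r.capture_date.isoformat(),
                "herd": r.herd,
                "sex": r.sex.value,
                "age_class": r.age_class.value,
                "tp_gdl": r.panel.total_protein,
                "alb_gdl": r.panel.albumin,
                "a1_gdl": r.panel.alpha1,
                "a2_gdl": r.panel.alpha2,
                "beta_gdl": r.panel.beta,
                "gamma_gdl": r.panel.gamma,
                "ag_ratio": r.panel.ag_ratio,
                "sero_brucella": _sero_str(r.serology.brucella),
                "sero_erysipelothrix": _sero_str(r.serology.erysipelothrix),
                "sero_toxoplasma": _sero_str(r.serology.toxoplasma),
                "sero_neospora": _sero_str(r.serology.neospora),
                "ill": int(r.clinical_illness),
                "died_30d": int(r.mortality_within_30d),
                "hemolyzed": int(r.hemolyzed),
            }
        )
    return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS.values()))


def write_captures(records: Sequence[CaptureRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
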