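import datetime as dt

import numpy as np
import pytest

from speri.datamodel import (
    AgeClass,
    AnalytePanel,
    CaptureRecord,
    SeroStatus,
    SerologyPanel,
    Sex,
    derive_panel_fields,
)


def quantile_oracle(values, p):
    """Independent quantile: explicit sort and 1-based linear interpolation
    at rank h = (n-1)p + 1. Deliberately avoids numpy.quantile."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * p + 1
    lo = int(h)  # floor for h >= 1
    if lo >= n:
        return xs[-1]
    frac = h - lo
    return xs[lo - 1] + frac * (xs[lo] - xs[lo - 1])


def make_record(
    animal_id="A1",
    date=dt.date(2010, 9, 15),
    sex=Sex.FEMALE,
    age_class=AgeClass.ADULT,
    albumin=4.6,
    alpha1=0.36,
    alpha2=0.40,
    beta=0.74,
    gamma=1.58,
    herd="Fortymile",
    serology=None,
    ill=False,
    died=False,
    hemolyzed=False,
):
    panel = derive_panel_fields(
        AnalytePanel(
            total_protein=albumin + alpha1 + alpha2 + beta + gamma,
            albumin=albumin,
            alpha1=alpha1,
            alpha2=alpha2,
            beta=beta,
            gamma=gamma,
        )
    )
    return CaptureRecord(
        animal_id=animal_id,
        capture_date=date,
        herd=herd,
        sex=sex,
        age_class=age_class,
        panel=panel,
        serology=serology or SerologyPanel(
            brucella=SeroStatus.NEGATIVE,
            erysipelothrix=SeroStatus.NEGATIVE,
            toxoplasma=SeroStatus.NEGATIVE,
            neospora=SeroStatus.NEGATIVE,
        ),
        clinical_illness=ill,
        mortality_within_30d=died,
        hemolyzed=hemolyzed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def small_herd():
    """A deterministic 300-event synthetic herd used across modules."""
    from speri.simulate import SimConfig, generate_herd

    return generate_herd(SimConfig(seed=42, n_events=300))
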