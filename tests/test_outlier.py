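"""Quantile estimators and Tukey fences against a brute-force oracle."""

import numpy as np
import pytest

from speri.datamodel import DEFAULT_STRATA
from speri.outlier import Fences, quantile, remove_outlier_animals, tukey_fences
from conftest import make_record, quantile_oracle


class TestQuantile:
    def test_single_observation(self):
        assert quantile([5.0], 0.1) == 5.0
        assert quantile([5.0], 0.9) == 5.0

    @pytest.mark.parametrize(
        "p,expected",
        [(0.25, 3.5), (0.975, 10.75), (0.5, 6.0), (0.0, 1.0), (1.0, 11.0)],
    )
    def test_interpolated_order_statistics_on_1_to_11(self, p, expected):
        # hand evaluation: h = (n-1)p + 1 on sorted 1..11
        assert quantile(range(1, 12), p) == pytest.approx(expected)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            quantile([], 0.5)

    def test_matches_brute_force_oracle_on_random_samples(self, rng):
        for _ in range(1000):
            n = int(rng.integers(4, 201))
            x = rng.normal(size=n) * rng.uniform(0.1, 10)
            p = float(rng.uniform())
            assert quantile(x, p) == pytest.approx(quantile_oracle(x, p), rel=1e-12, abs=1e-12)

    def test_hinge_variants_on_odd_sample(self):
        x = [1, 2, 3, 4, 5, 6, 7]  # median 4
        # inclusive hinges keep the median in both halves: lower {1,2,3,4}
        assert quantile(x, 0.25, "tukey-inclusive") == 2.5
        assert quantile(x, 0.75, "tukey-inclusive") == 5.5
        # exclusive hinges drop it: lower {1,2,3}
        assert quantile(x, 0.25, "tukey-exclusive") == 2.0
        assert quantile(x, 0.75, "tukey-exclusive") == 6.0
        x9 = list(range(1, 10))  # n=9: halves differ between variants
        assert quantile(x9, 0.25, "tukey-inclusive") == 3.0
        assert quantile(x9, 0.25, "tukey-exclusive") == 2.5


class TestTukeyFences:
    def test_constant_sample_collapses(self):
        f = tukey_fences([3.0, 3.0, 3.0, 3.0])
        assert f.iqr == 0
        assert f.lower == f.upper == 3.0
        assert not f.is_outlier(3.0)  # "more than" is strict

    def test_hand_computed_example(self):
        f = tukey_fences([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 100], k=1.5)
        assert f.q1 == pytest.approx(3.5)
        assert f.q3 == pytest.approx(8.5)
        assert f.lower == pytest.approx(-4.0)
        assert f.upper == pytest.approx(16.0)
        assert f.is_outlier(100)
        assert not f.is_outlier(10)

    def test_k_zero_collapses_to_quartiles(self):
        f = tukey_fences([1, 2, 3, 4, 5], k=0.0)
        assert f.lower == f.q1
        assert f.upper == f.q3

    def test_boundary_values_are_inside(self):
        f = Fences("x", "s", q1=2.0, q3=4.0, k=1.5)
        assert not f.is_outlier(f.lower)
        assert not f.is_outlier(f.upper)
        assert f.is_outlier(f.upper + 1e-9)

    def test_below_minimum_n_yields_no_fences(self):
        with pytest.warns(UserWarning, match="fences skipped"):
            assert tukey_fences([1.0, 2.0, 3.0], min_n=4) is None

    def test_monotone_in_k(self, rng):
        x = rng.normal(size=200)
        flagged = []
        for k in (0.5, 1.0, 1.5, 2.0, 3.0):
            f = tukey_fences(x, k)
            flagged.append(int(np.sum([f.is_outlier(v) for v in x])))
        assert flagged == sorted(flagged, reverse=True)


class TestRemoveOutlierAnimals:
    def _stratum_cohort(self, rng, n=50):
        return [
            make_record(
                animal_id=f"A{i}",
                albumin=float(rng.normal(4.6, 0.5)),
                alpha1=float(rng.normal(0.36, 0.05)),
                alpha2=float(rng.normal(0.40, 0.05)),
                beta=float(rng.normal(0.74, 0.1)),
                gamma=float(rng.normal(1.58, 0.2)),
            )
            for i in range(n)
        ]

    def test_identical_panels_remove_nothing(self):
        cohort = [make_record(animal_id=f"A{i}") for i in range(20)]
        kept, flagged = remove_outlier_animals(cohort, DEFAULT_STRATA)
        assert len(kept) == 20
        assert flagged == []

    def test_single_gross_outlier_is_the_only_removal(self, rng):
        cohort = self._stratum_cohort(rng)
        q3 = np.quantile([r.panel.gamma for r in cohort], 0.75)
        iqr = q3 - np.quantile([r.panel.gamma for r in cohort], 0.25)
        spike = make_record(animal_id="SPIKE", gamma=float(q3 + 10 * iqr))
        kept, flagged = remove_outlier_animals(cohort + [spike], DEFAULT_STRATA)
        assert "SPIKE" in {f.animal_id for f in flagged}
        assert all(r.animal_id != "SPIKE" for r in kept)

    def test_matches_brute_force_fence_check(self, rng):
        cohort = self._stratum_cohort(rng, n=80)
        kept, flagged = remove_outlier_animals(cohort, DEFAULT_STRATA)
        # oracle: per-analyte fences from the oracle quantile, animal removed
        # iff any analyte strictly outside
        from speri.datamodel import ANALYTES
        removed = set()
        for a in ANALYTES:
            vals = [r.panel.value(a) for r in cohort]
            q1, q3 = quantile_oracle(vals, 0.25), quantile_oracle(vals, 0.75)
            lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
            for r in cohort:
                v = r.panel.value(a)
                if v < lo or v > hi:
                    removed.add(r.animal_id)
        assert {f.animal_id for f in flagged} == removed
        assert {r.animal_id for r in kept} == {r.animal_id for r in cohort} - removed

    def test_order_invariance_within_stratum(self, rng):
        cohort = self._stratum_cohort(rng, n=60)
        kept1, _ = remove_outlier_animals(cohort, DEFAULT_STRATA)
        kept2, _ = remove_outlier_animals(cohort[::-1], DEFAULT_STRATA)
        assert {r.animal_id for r in kept1} == {r.animal_id for r in kept2}

    def test_unassignable_records_pass_through(self):
        import datetime as dt
        from speri.datamodel import Sex
        male = make_record(animal_id="M1", sex=Sex.MALE)
        winter = make_record(animal_id="W1", date=dt.date(2010, 12, 5))
        kept, flagged = remove_outlier_animals([male, winter], DEFAULT_STRATA)
        assert len(kept) == 2 and flagged == []
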