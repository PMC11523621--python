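"""Chilling accumulation, FR prediction, budburst dates and validation metrics."""

import numpy as np
import pandas as pd
import pytest

from chillcurve.chilling_function import (
    ReferenceChillingFunction,
    TriangularChillingFunction,
)
from chillcurve.pheno_model import PhenoModel, accumulate_ca, validate
from chillcurve.weather import ChamberRegime, chamber_series, hourly_from_daily
from tests.conftest import make_daily


@pytest.fixture
def triangle():
    return TriangularChillingFunction(
        m1=0.05, n1=1.0, m2=-0.04, n2=1.0, t_op=0.0, k=1200.0
    )


@pytest.fixture
def reference():
    return ReferenceChillingFunction(k=1500.0)


class TestAccumulateCa:
    def test_reference_constant_cold(self, reference):
        hourly = chamber_series(ChamberRegime(5.0, 24, 0.0, 0), 5)
        assert accumulate_ca(reference, hourly.iloc[:100]) == pytest.approx(100.0)

    def test_warm_hours_accumulate_nothing(self, triangle, reference):
        hourly = chamber_series(ChamberRegime(15.0, 14, 12.0, 10), 3)
        for fn in (triangle, reference):
            assert accumulate_ca(fn, hourly) == 0.0

    def test_equals_brute_force_loop(self, triangle):
        rng = np.random.default_rng(3)
        idx = pd.date_range("2021-11-01", periods=48, freq="h")
        hourly = pd.Series(rng.uniform(-15, 15, size=48), index=idx)
        brute = 0.0
        for temp in hourly.to_numpy():
            if temp > triangle.t_upper:
                continue
            limb = triangle.m1 * temp + triangle.n1 if temp <= triangle.t_op else triangle.m2 * temp + triangle.n2
            brute += min(max(limb, 0.0), 1.0)
        got = accumulate_ca(triangle, hourly, "2021-11-01", "2021-11-02")
        assert got == pytest.approx(brute, abs=1e-9)

    def test_constant_temperature_reduces_to_rate_times_hours(self, triangle):
        hourly = chamber_series(ChamberRegime(-5.0, 24, 0.0, 0), 4)
        got = accumulate_ca(triangle, hourly)
        assert got == pytest.approx(float(triangle(-5.0)) * 96.0)


class TestPredictedFr:
    @pytest.fixture
    def model(self, reference):
        return PhenoModel(a=1900.0, b=1900.0, chilling_fn=reference)

    def test_no_chilling_gives_full_requirement(self, model):
        assert float(model.predicted_fr(0.0)) == pytest.approx(3800.0)

    def test_asymptote_at_saturating_chilling(self, model):
        assert float(model.predicted_fr(1e9)) == pytest.approx(1900.0)

    def test_one_e_folding_at_ca_equal_k(self, model):
        assert float(model.predicted_fr(model.k)) == pytest.approx(1900.0 + 1900.0 / np.e)

    def test_strictly_decreasing_in_ca(self, model):
        ca = np.linspace(0, 10000, 500)
        assert np.all(np.diff(model.predicted_fr(ca)) < 0)


class TestPredictDaysToBudburst:
    def test_no_chilling_full_span(self, reference):
        model = PhenoModel(a=1900.0, b=1900.0, chilling_fn=reference)
        assert model.predict_days_to_budburst() == pytest.approx(10.0)

    def test_saturating_chilling_hits_asymptote(self, reference):
        model = PhenoModel(a=1900.0, b=1900.0, chilling_fn=reference)
        assert model.predict_days_to_budburst(ca_outside=1e9) == pytest.approx(5.0)

    def test_outside_forcing_floors_at_zero(self, reference):
        model = PhenoModel(a=1900.0, b=1900.0, chilling_fn=reference)
        assert model.predict_days_to_budburst(ca_outside=1e9, delta_fr=5000.0) == 0.0

    def test_fridge_chilling_uses_constant_rate(self, triangle):
        model = PhenoModel(a=2000.0, b=8000.0, chilling_fn=triangle)
        days = model.predict_days_to_budburst(chill_temp_c=0.0, fridge_hours=1200.0)
        fr = 2000.0 + 8000.0 * np.exp(-1200.0 / 1200.0)  # c(0) = 1, k = 1200
        assert days == pytest.approx(fr / 380.0)


def piecewise_season(spring_offset=0.0):
    """150-day dormant season with piecewise-constant daily means."""
    tmeans = np.concatenate(
        [
            np.full(10, 12.0),  # warm early November
            np.full(60, 4.0),  # chilling
            np.full(30, 0.0),  # deep winter
            np.full(20, 6.0),  # late winter
            np.full(30, 14.0 + spring_offset),  # spring forcing
        ]
    )
    return make_daily(tmeans, start="2021-11-01", half_range=4.0)


class TestPredictBudburstDate:
    @pytest.fixture
    def model(self, reference):
        return PhenoModel(a=2000.0, b=8000.0, chilling_fn=reference)

    def test_matches_day_by_day_oracle(self, model):
        daily = piecewise_season()
        hourly = hourly_from_daily(daily)
        # independent walk: daily CA from onset, daily GDH from 1 January
        onset = None
        tm = daily["tmean"].to_numpy()
        for i in range(len(tm) - 2):
            if tm[i] < 10 and tm[i + 1] < 10 and tm[i + 2] < 10:
                onset = daily["date"].iloc[i]
                break
        assert onset == pd.Timestamp("2021-11-11")
        expected = None
        ca = 0.0
        gdh = 0.0
        jan1 = pd.Timestamp("2022-01-01")
        for day, group in hourly.groupby(hourly.index.normalize()):
            if day >= onset:
                ca += sum(1.0 for t in group.to_numpy() if t <= 10.0)
            if day >= jan1:
                gdh += sum(max(t - 5.0, 0.0) for t in group.to_numpy())
                fr = 2000.0 + 8000.0 * np.exp(-ca / 1500.0)
                if gdh >= fr and expected is None:
                    expected = day.dayofyear
        assert expected is not None
        assert model.predict_budburst_date(daily) == expected

    def test_warm_spring_is_earlier(self, model):
        warm = model.predict_budburst_date(piecewise_season(spring_offset=0.0))
        cool = model.predict_budburst_date(piecewise_season(spring_offset=-2.0))
        assert warm < cool

    def test_zero_chill_winter_is_later_or_censored(self, reference):
        model = PhenoModel(a=2000.0, b=12000.0, chilling_fn=reference)
        normal = model.predict_budburst_date(piecewise_season())
        # winter held just above the chilling threshold (10.5 +/- 0.25 deg C),
        # after three onset-qualifying cold days, so almost no CA accrues
        tm = np.concatenate(
            [np.full(10, 12.0), np.full(3, 4.0), np.full(107, 10.5), np.full(30, 14.0)]
        )
        half = np.concatenate(
            [np.full(10, 4.0), np.full(3, 4.0), np.full(107, 0.25), np.full(30, 4.0)]
        )
        no_chill = pd.DataFrame(
            {
                "date": pd.date_range("2021-11-01", periods=150, freq="D"),
                "tmean": tm,
                "tmax": tm + half,
                "tmin": tm - half,
            }
        )
        late = model.predict_budburst_date(no_chill)
        assert late is None or late > normal

    def test_censored_when_forcing_never_reaches_fr(self, reference):
        model = PhenoModel(a=50000.0, b=80000.0, chilling_fn=reference)
        assert model.predict_budburst_date(piecewise_season()) is None


class TestFlatFunctionEquivalence:
    def test_triangular_and_reference_predictions_coincide(self):
        # equal decay rates: flat-top triangle and reference share k and c == 1
        import warnings

        from chillcurve.chilling_function import (
            reference_function,
            triangular_from_rates,
        )

        rates = {-10.0: 6e-4, -5.0: 6e-4, 0.0: 6e-4, 5.0: 6e-4, 10.0: 6e-4}
        ref = reference_function(rates)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tri = triangular_from_rates(rates)
        daily = piecewise_season()
        m_ref = PhenoModel(a=2000.0, b=8000.0, chilling_fn=ref)
        m_tri = PhenoModel(a=2000.0, b=8000.0, chilling_fn=tri)
        assert m_ref.k == m_tri.k
        assert m_ref.predict_budburst_date(daily) == m_tri.predict_budburst_date(daily)
        hourly = hourly_from_daily(daily)
        assert accumulate_ca(ref, hourly) == accumulate_ca(tri, hourly)


class TestValidate:
    def test_perfect_predictions(self):
        m = validate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_params=3)
        assert m.r2 == 1.0
        assert m.rmse == 0.0

    def test_hand_arithmetic(self):
        m = validate([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], n_params=1)
        assert m.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert m.r2 == pytest.approx(0.0)

    def test_aicc_penalty_monotone_in_params(self):
        obs = np.arange(12.0)
        pred = obs + 0.5
        a3 = validate(obs, pred, n_params=3).aicc
        a6 = validate(obs, pred, n_params=6).aicc
        assert a6 > a3

    def test_aicc_undefined_for_tiny_samples(self):
        m = validate([1.0, 2.0, 3.0], [1.1, 2.2, 2.9], n_params=3)
        assert np.isnan(m.aicc)
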