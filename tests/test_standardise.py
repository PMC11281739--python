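"""Direct standardisation, confidence intervals and year pooling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from backvalue import (
    DataIntegrityError,
    ESP_2013,
    InputError,
    StandardPopulation,
    crude_rate,
    direct_standardised_rate,
    pool_years,
    rate_ci,
)

BANDS = ["40-44", "45-49", "50-54"]


class TestCrudeRate:
    @pytest.mark.parametrize("events,denom,expected", [
        (0, 5000, 0.0),
        (50, 10_000, 50.0),
        (7, 3_500, 20.0),   # 10000 * 7 / 3500, by hand
    ])
    def test_examples(self, events, denom, expected):
        assert crude_rate(events, denom) == pytest.approx(expected)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(InputError):
            crude_rate(1, 0)


class TestDirectStandardisation:
    def test_hand_arithmetic_oracle(self):
        """Three strata, ESP weights 5500/6000/6500, rates 10/20/40 per
        10,000 -> (5500*10 + 6000*20 + 6500*40) / 18000 = 24.1667."""
        std = StandardPopulation("toy", dict(zip(BANDS, [5500, 6000, 6500])))
        denoms = {b: 10_000.0 for b in BANDS}
        events = dict(zip(BANDS, [10, 20, 40]))
        r = direct_standardised_rate(events, denoms, std)
        assert r.rate == pytest.approx(435_000 / 18_000, abs=1e-9)

    def test_equal_weights_average(self):
        std = StandardPopulation("toy", {"40-44": 7000, "45-49": 7000})
        r = direct_standardised_rate(
            {"40-44": 10, "45-49": 30}, {"40-44": 1e4, "45-49": 1e4}, std
        )
        assert r.rate == pytest.approx(20.0)

    @given(
        rate=st.floats(1.0, 500.0),
        denoms=st.lists(st.floats(1e3, 1e5), min_size=1, max_size=6),
    )
    def test_uniform_rates_identity(self, rate, denoms):
        """Standardisation returns uniform stratum rates unchanged."""
        bands = [f"{40 + 5 * i}-{44 + 5 * i}" for i in range(len(denoms))]
        std = StandardPopulation("toy", {b: 1000.0 * (i + 1)
                                         for i, b in enumerate(bands)})
        events = {b: rate * d / 1e4 for b, d in zip(bands, denoms)}
        r = direct_standardised_rate(events, dict(zip(bands, denoms)), std)
        assert r.rate == pytest.approx(rate, rel=1e-9)

    @given(scale=st.floats(0.01, 100.0))
    def test_weight_scale_invariance(self, scale):
        """Multiplying every standard weight by a constant changes nothing."""
        events = dict(zip(BANDS, [5, 9, 2]))
        denoms = {b: 2e4 for b in BANDS}
        w = dict(zip(BANDS, [5500.0, 6000.0, 6500.0]))
        r1 = direct_standardised_rate(events, denoms,
                                      StandardPopulation("a", w))
        r2 = direct_standardised_rate(
            events, denoms,
            StandardPopulation("b", {k: v * scale for k, v in w.items()}),
        )
        assert r1.rate == pytest.approx(r2.rate, rel=1e-9)

    @given(extra=st.integers(1, 50), idx=st.integers(0, 2))
    def test_adding_events_never_decreases_rate(self, extra, idx):
        events = dict(zip(BANDS, [5, 9, 2]))
        denoms = {b: 2e4 for b in BANDS}
        std = StandardPopulation("toy", dict(zip(BANDS, [5500, 6000, 6500])))
        before = direct_standardised_rate(events, denoms, std).rate
        events[BANDS[idx]] += extra
        after = direct_standardised_rate(events, denoms, std).rate
        assert after >= before

    def test_same_weight_applied_to_both_sexes(self):
        std = StandardPopulation("toy", {"40-44": 7000})
        r = direct_standardised_rate(
            {("40-44", "F"): 30, ("40-44", "M"): 10},
            {("40-44", "F"): 1e4, ("40-44", "M"): 1e4}, std,
        )
        assert r.rate == pytest.approx(20.0)

    def test_events_without_denominator_is_integrity_error(self):
        std = StandardPopulation("toy", {"40-44": 7000, "45-49": 7000})
        with pytest.raises(DataIntegrityError, match="45-49"):
            direct_standardised_rate(
                {"40-44": 3, "45-49": 2}, {"40-44": 1e4, "45-49": 0.0}, std
            )

    def test_empty_stratum_skipped_with_warning(self, caplog):
        std = StandardPopulation("toy", {"40-44": 7000, "45-49": 7000})
        with caplog.at_level("WARNING"):
            r = direct_standardised_rate(
                {"40-44": 3}, {"40-44": 1e4, "45-49": 0.0}, std
            )
        assert "45-49" in caplog.text
        assert r.rate == pytest.approx(3.0)

    def test_uncovered_band_rejected(self):
        std = StandardPopulation("toy", {"40-44": 7000})
        with pytest.raises(InputError, match="45-49"):
            direct_standardised_rate({"45-49": 1}, {"45-49": 1e4}, std)


class TestRateCI:
    def test_zero_events_lower_bound_zero(self):
        lo, hi = rate_ci(0, 1000)
        assert lo == 0.0 and hi > 0.0

    def test_interval_width_scales_inverse_sqrt_n(self):
        lo1, hi1 = rate_ci(50, 10_000)
        lo4, hi4 = rate_ci(200, 40_000)
        assert (hi1 - lo1) / (hi4 - lo4) == pytest.approx(2.0, rel=0.10)

    def test_dobson_brackets_rate_and_tightens(self):
        std = StandardPopulation("toy", dict(zip(BANDS, [5500, 6000, 6500])))
        denoms = {b: 2e4 for b in BANDS}
        ev_small = dict(zip(BANDS, [5, 9, 2]))
        ev_big = {b: 4 * e for b, e in ev_small.items()}
        r_small = direct_standardised_rate(ev_small, denoms, std)
        big_denoms = {b: 4 * d for b, d in denoms.items()}
        r_big = direct_standardised_rate(ev_big, big_denoms, std)
        assert r_small.ci_low <= r_small.rate <= r_small.ci_high
        assert (r_big.ci_high - r_big.ci_low) < (
            r_small.ci_high - r_small.ci_low
        )

    def test_wilson_coverage_near_nominal(self):
        """95% Wilson interval covers the true proportion in 93-97% of
        2,000 binomial draws at p=0.01, n=5,000."""
        rng = np.random.default_rng(1234)
        p, n = 0.01, 5_000
        draws = rng.binomial(n, p, 2_000)
        covered = 0
        for k in draws:
            lo, hi = rate_ci(int(k), n)
            covered += lo <= p * 1e4 <= hi
        assert 0.93 <= covered / 2_000 <= 0.97


class TestPoolYears:
    def _one_year_block(self, year):
        return pd.DataFrame({
            "patient_id": [f"p{year}{i}" for i in range(6)],
            "age": [42, 47, 52, 42, 47, 52],
            "sex": ["F", "M"] * 3,
            "practice_id": "pA",
            "imd_decile": 5,
            "fiscal_year": year,
            "event_class": "procedure",
            "intervention_id": "",
        })

    def _registers(self):
        return pd.DataFrame({
            "practice_id": "pA",
            "age_band": ["40-44", "45-49", "50-54"] * 2,
            "sex": ["F"] * 3 + ["M"] * 3,
            "imd_decile": 5,
            "count": 1000,
            "deprivation_score": 5.0,
        })

    def test_single_year_is_identity(self):
        eps = self._one_year_block("2019/20")
        ev, py = pool_years(eps, self._registers(), ["2019/20"])
        assert ev.sum() == 6
        assert py.sum() == 6000

    def test_four_equal_years_scale_counts_not_rate(self):
        years = ["2016/17", "2017/18", "2018/19", "2019/20"]
        eps = pd.concat([self._one_year_block(y) for y in years],
                        ignore_index=True)
        reg = self._registers()
        ev1, py1 = pool_years(eps, reg, years[:1])
        ev4, py4 = pool_years(eps, reg, years)
        assert ev4.sum() == 4 * ev1.sum()
        assert py4.sum() == 4 * py1.sum()
        assert crude_rate(ev4.sum(), py4.sum()) == pytest.approx(
            crude_rate(ev1.sum(), py1.sum())
        )

    def test_pooling_four_years_halves_ci_width(self):
        years = ["2016/17", "2017/18", "2018/19", "2019/20"]
        eps = pd.concat([self._one_year_block(y) for y in years],
                        ignore_index=True)
        reg = self._registers()
        ev1, py1 = pool_years(eps, reg, years[:1])
        ev4, py4 = pool_years(eps, reg, years)
        lo1, hi1 = rate_ci(int(ev1.sum()), float(py1.sum()))
        lo4, hi4 = rate_ci(int(ev4.sum()), float(py4.sum()))
        assert (hi1 - lo1) / (hi4 - lo4) == pytest.approx(2.0, rel=0.10)

    def test_unknown_year_rejected(self):
        eps = self._one_year_block("2019/20")
        with pytest.raises(InputError, match="1999/00"):
            pool_years(eps, self._registers(), ["1999/00"])
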