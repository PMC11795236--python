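"""Weekly climatology construction and warm-day classification."""

import numpy as np
import pandas as pd
import pytest

from coclimate import climatology
from conftest import percentile_oracle


def _series(county, dates, temps):
    return pd.DataFrame({"county": county, "date": pd.to_datetime(dates), "tmean_c": temps})


def _full_year_baseline(county="A", value=20.0, years=(2000, 2001)):
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    if np.isscalar(value):
        temps = np.full(len(dates), float(value))
    else:
        temps = value
    return _series(county, dates, temps)


class TestWeekBinning:
    def test_seven_day_blocks_capped_at_52(self):
        dates = pd.to_datetime(["2018-01-01", "2018-01-07", "2018-01-08", "2018-12-30", "2018-12-31"])
        assert list(climatology.week_of_year(dates)) == [1, 1, 2, 52, 52]

    def test_leap_day_uses_natural_day_of_year(self):
        # Feb 29 2000 is day 60 -> week 9, same bin as Mar 1 in leap years
        assert climatology.week_of_year(pd.to_datetime(["2000-02-29"]))[0] == 9


class TestBuildWeeklyClimatology:
    def test_constant_baseline_gives_constant_threshold(self):
        clim = climatology.build_weekly_climatology(_full_year_baseline(value=20.0))
        assert len(clim) == 52
        assert (clim["p85_c"] == 20.0).all()
        assert (clim["n_obs"] > 0).all()

    def test_matches_sort_and_interpolate_oracle(self):
        # one county-week bin holding the integers 1..210: 7 days of each
        # of 30 baseline years, all falling in week 1
        frames = []
        vals = iter(range(1, 211))
        for year in range(1981, 2011):
            dates = pd.date_range(f"{year}-01-01", periods=7, freq="D")
            frames.append(_series("A", dates, [float(next(vals)) for _ in range(7)]))
        baseline = pd.concat(frames, ignore_index=True)
        clim = climatology.build_weekly_climatology(baseline, tmean_range=(0, 300))
        got = clim.loc[clim["week"] == 1, "p85_c"].item()
        assert got == pytest.approx(percentile_oracle(range(1, 211), 85), abs=1e-12)
        assert got == pytest.approx(178.65, abs=1e-12)

    def test_percentile_100_is_bin_maximum(self):
        rng = np.random.default_rng(3)
        base = _full_year_baseline(value=rng.normal(10, 5, 731))
        clim = climatology.build_weekly_climatology(base, percentile=100)
        base = base.assign(week=climatology.week_of_year(base["date"]))
        maxima = base.groupby("week")["tmean_c"].max()
        assert np.allclose(clim.set_index("week")["p85_c"], maxima)

    def test_random_bins_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 60))
            vals = rng.normal(15, 10, n)
            q = float(rng.uniform(1, 100))
            dates = pd.date_range("2001-01-01", periods=min(n, 7), freq="D")
            frames = []
            i = 0
            year = 1981
            while i < n:
                take = min(7, n - i)
                frames.append(
                    _series("A", pd.date_range(f"{year}-01-01", periods=take), vals[i : i + take])
                )
                i += take
                year += 1
            clim = climatology.build_weekly_climatology(pd.concat(frames), percentile=q)
            got = clim.loc[clim["week"] == 1, "p85_c"].item()
            assert got == pytest.approx(percentile_oracle(vals, q), abs=1e-12)

    @pytest.mark.parametrize("bad", [0, -5, 101])
    def test_rejects_percentile_out_of_domain(self, bad):
        with pytest.raises(ValueError):
            climatology.build_weekly_climatology(_full_year_baseline(), percentile=bad)

    def test_rejects_duplicate_county_days(self):
        df = _series("A", ["2000-01-01", "2000-01-01"], [1.0, 2.0])
        with pytest.raises(ValueError, match="duplicate"):
            climatology.build_weekly_climatology(df)


class TestClassifyAnomalouslyWarm:
    @pytest.fixture()
    def flat_clim(self):
        return climatology.build_weekly_climatology(_full_year_baseline(value=20.0))

    @pytest.mark.parametrize(
        "tmean, p85_value, expect",
        [
            (25.0, 20.0, True),   # both conditions hold
            (30.0, 31.0, False),  # percentile condition fails
            (23.9, 10.0, False),  # absolute cutoff is strict: 23.9 not > 24
            (24.0, 10.0, False),  # exactly 24 is not anomalously warm
            (24.01, 24.01, True),  # percentile condition is inclusive
        ],
    )
    def test_dual_condition(self, tmean, p85_value, expect):
        clim = climatology.build_weekly_climatology(
            _full_year_baseline(value=p85_value)
        )
        study = _series("A", ["2018-06-15"], [tmean])
        flags = climatology.classify_anomalously_warm(study, clim)
        assert (len(flags) == 1) is expect

    def test_unknown_county_raises(self, flat_clim):
        study = _series("B", ["2018-06-15"], [30.0])
        with pytest.raises(ValueError, match="B"):
            climatology.classify_anomalously_warm(study, flat_clim)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(5)
        frames = []
        for county in ("A", "B"):
            dates = pd.date_range("1981-01-01", "1984-12-31", freq="D")
            frames.append(_series(county, dates, rng.normal(18, 8, len(dates))))
        baseline = pd.concat(frames, ignore_index=True)
        study_dates = pd.date_range("2018-01-01", "2018-12-31", freq="D")
        study = pd.concat(
            [
                _series(c, study_dates, rng.normal(20, 8, len(study_dates)))
                for c in ("A", "B")
            ],
            ignore_index=True,
        )
        clim = climatology.build_weekly_climatology(baseline)
        flags = climatology.classify_anomalously_warm(study, clim)
        got = {(c, d) for c, d in flags.itertuples(index=False)}

        expected = set()
        base = baseline.assign(week=climatology.week_of_year(baseline["date"]))
        for _, row in study.iterrows():
            week = climatology.week_of_year(pd.DatetimeIndex([row["date"]]))[0]
            pool = base[(base["county"] == row["county"]) & (base["week"] == week)]
            thr = percentile_oracle(pool["tmean_c"], 85)
            if row["tmean_c"] >= thr and row["tmean_c"] > 24.0:
                expected.add((row["county"], row["date"]))
        assert got == expected

    def test_monotone_shrinkage_in_cutoff_and_percentile(self):
        rng = np.random.default_rng(19)
        dates = pd.date_range("1981-01-01", "1983-12-31", freq="D")
        baseline = _series("A", dates, rng.normal(20, 6, len(dates)))
        study_dates = pd.date_range("2018-01-01", "2018-12-31", freq="D")
        study = _series("A", study_dates, rng.normal(22, 6, len(study_dates)))
        prev = None
        for cutoff in (20.0, 24.0, 28.0):
            clim = climatology.build_weekly_climatology(baseline)
            n = len(climatology.classify_anomalously_warm(study, clim, absolute_cutoff=cutoff))
            if prev is not None:
                assert n <= prev
            prev = n
        prev = None
        for q in (50, 85, 99):
            clim = climatology.build_weekly_climatology(baseline, percentile=q)
            n = len(climatology.classify_anomalously_warm(study, clim))
            if prev is not None:
                assert n <= prev
            prev = n


class TestSummarizeExceedanceDays:
    def test_three_value_quartiles(self):
        clim = climatology.build_weekly_climatology(_full_year_baseline(value=5.0))
        study = _series("A", ["2018-01-01", "2018-06-01", "2018-09-01"], [10.0, 20.0, 30.0])
        s = climatology.summarize_exceedance_days(study, clim)
        assert (s.n_days, s.median_c, s.q1_c, s.q3_c) == (3, 20.0, 15.0, 25.0)

    def test_single_day(self):
        clim = climatology.build_weekly_climatology(_full_year_baseline(value=5.0))
        study = _series("A", ["2018-06-01"], [19.0])
        s = climatology.summarize_exceedance_days(study, clim)
        assert (s.median_c, s.q1_c, s.q3_c) == (19.0, 19.0, 19.0)

    def test_no_exceedance_days_is_empty_not_error(self):
        clim = climatology.build_weekly_climatology(_full_year_baseline(value=50.0))
        study = _series("A", ["2018-06-01"], [10.0])
        s = climatology.summarize_exceedance_days(study, clim)
        assert s.empty and s.n_days == 0
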