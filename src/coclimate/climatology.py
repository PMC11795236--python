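"""Weekly county climatology and anomalously-warm-day classification.

An *anomalously warm* (AW) county-day is one whose daily mean
temperature both (a) reaches the county's week-of-year 85th-percentile
climatology built from a 30-year baseline (relative condition, >= at the
threshold) and (b) strictly exceeds an absolute cutoff of 24 degC
(physiological condition, >). The dual condition keeps mild winter days
that are merely unusual *for the season* out of the warm-day set.

Week-of-year bins are fixed 7-day blocks of the day-of-year:
``week = floor((doy - 1) / 7) + 1`` capped at 52, so days 365/366 join
week 52 and leap days keep their natural day-of-year. The percentile is
taken over all baseline daily values that fall in the bin across years
(about 210 values for a 30-year baseline); an alternative using the
distribution of the 30 per-year weekly means is available via
``use_weekly_means=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "week_of_year",
    "validate_temperature_series",
    "build_weekly_climatology",
    "classify_anomalously_warm",
    "summarize_exceedance_days",
    "ExceedanceSummary",
]

#: plausible daily-mean range (degC) used by input validation
DEFAULT_TMEAN_RANGE = (-60.0, 60.0)

REQUIRED_COLUMNS = ("county", "date", "tmean_c")


def week_of_year(dates: pd.Series | pd.DatetimeIndex) -> np.ndarray:
    """Map calendar dates to 7-day day-of-year bins 1..52.

    Days 365 and 366 are merged into week 52 so every year yields the
    same 52 bins regardless of leap status.
    """
    doy = pd.DatetimeIndex(dates).dayofyear.to_numpy()
    return np.minimum((doy - 1) // 7 + 1, 52)


def validate_temperature_series(
    df: pd.DataFrame,
    tmean_range: tuple[float, float] = DEFAULT_TMEAN_RANGE,
) -> pd.DataFrame:
    """Check a county/date/tmean_c frame and return it with parsed dates.

    Raises ``ValueError`` on missing columns, duplicate (county, date)
    rows, non-finite temperatures, or values outside ``tmean_range``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"temperature series missing columns: {missing}")
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"])
    dups = out.duplicated(["county", "date"])
    if dups.any():
        bad = out.loc[dups, ["county", "date"]].head(5).to_dict("records")
        raise ValueError(f"duplicate (county, date) records, e.g. {bad}")
    t = out["tmean_c"].to_numpy(dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("non-finite tmean_c values present")
    lo, hi = tmean_range
    if (t < lo).any() or (t > hi).any():
        raise ValueError(f"tmean_c outside plausible range [{lo}, {hi}] degC")
    return out


def build_weekly_climatology(
    baseline: pd.DataFrame,
    percentile: float = 85.0,
    method: str = "linear",
    use_weekly_means: bool = False,
    tmean_range: tuple[float, float] = DEFAULT_TMEAN_RANGE,
) -> pd.DataFrame:
    """Build the per-county week-of-year percentile climatology.

    Parameters
    ----------
    baseline
        Baseline-period daily series with columns ``county, date, tmean_c``
        (e.g. 1981-2010 for the California analysis).
    percentile
        Percentile level in (0, 100]; 85 gives the standard threshold.
    method
        Quantile interpolation method passed to :func:`numpy.percentile`
        (default linear interpolation between order statistics).
    use_weekly_means
        If True, take the percentile over the per-year weekly means
        instead of over all daily values in the bin.

    Returns
    -------
    DataFrame with columns ``county, week, p85_c, n_obs``, one row per
    non-empty (county, week) bin.
    """
    if not 0.0 < percentile <= 100.0:
        raise ValueError(f"percentile must be in (0, 100], got {percentile}")
    baseline = validate_temperature_series(baseline, tmean_range=tmean_range)
    df = baseline.copy()
    df["week"] = week_of_year(df["date"])
    if use_weekly_means:
        df["year"] = df["date"].dt.year
        df = (
            df.groupby(["county", "week", "year"], sort=True)["tmean_c"]
            .mean()
            .reset_index()
        )
    grouped = df.groupby(["county", "week"], sort=True)["tmean_c"]
    clim = grouped.agg(
        p85_c=lambda v: float(np.percentile(v, percentile, method=method)),
        n_obs="size",
    ).reset_index()
    return clim


def _lookup_thresholds(study: pd.DataFrame, clim: pd.DataFrame) -> pd.DataFrame:
    """Attach the (county, week) threshold to each study row, or raise."""
    study = study.copy()
    study["week"] = week_of_year(study["date"])
    missing_counties = sorted(
        set(study["county"]) - set(clim["county"]), key=str
    )
    if missing_counties:
        raise ValueError(
            f"study counties absent from climatology: {missing_counties}"
        )
    merged = study.merge(clim[["county", "week", "p85_c"]], on=["county", "week"], how="left")
    if merged["p85_c"].isna().any():
        bad = (
            merged.loc[merged["p85_c"].isna(), ["county", "week"]]
            .drop_duplicates()
            .to_dict("records")
        )
        raise ValueError(f"empty climatology bin for (county, week): {bad}")
    return merged


def classify_anomalously_warm(
    study: pd.DataFrame,
    clim: pd.DataFrame,
    absolute_cutoff: float = 24.0,
) -> pd.DataFrame:
    """Flag anomalously warm county-days in the study-period series.

    A day is flagged iff ``tmean_c >= p85(county, week)`` (boundary
    inclusive) AND ``tmean_c > absolute_cutoff`` (strict). Returns a
    ``county, date`` frame sorted by county then date; per-county day
    counts are ``flags.groupby("county").size()``.
    """
    study = validate_temperature_series(study)
    merged = _lookup_thresholds(study, clim)
    mask = (merged["tmean_c"] >= merged["p85_c"]) & (
        merged["tmean_c"] > absolute_cutoff
    )
    flags = (
        merged.loc[mask, ["county", "date"]]
        .sort_values(["county", "date"])
        .reset_index(drop=True)
    )
    return flags


@dataclass(frozen=True)
class ExceedanceSummary:
    """Median/IQR of daily means on percentile-exceedance days."""

    n_days: int
    median_c: float
    q1_c: float
    q3_c: float

    @property
    def empty(self) -> bool:
        return self.n_days == 0


def summarize_exceedance_days(
    study: pd.DataFrame, clim: pd.DataFrame
) -> ExceedanceSummary:
    """Summarize temperatures on days meeting only the percentile condition.

    Restricts to study days with ``tmean_c >= p85`` — the absolute
    cutoff is deliberately NOT applied — and reports median and
    linear-interpolation quartiles. Because the percentile is seasonal,
    many exceedance days are cool in absolute terms; this summary shows
    why the 24 degC cutoff is needed on top of the relative condition.
    """
    study = validate_temperature_series(study)
    merged = _lookup_thresholds(study, clim)
    vals = merged.loc[merged["tmean_c"] >= merged["p85_c"], "tmean_c"].to_numpy()
    if vals.size == 0:
        return ExceedanceSummary(0, float("nan"), float("nan"), float("nan"))
    q1, med, q3 = np.percentile(vals, [25, 50, 75], method="linear")
    return ExceedanceSummary(int(vals.size), float(med), float(q1), float(q3))
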