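"""Social Vulnerability Index correlation and quartile summaries.

The SVI is a county-level composite score in [0, 1] (0 least, 1 most
vulnerable), consumed as input. For each single and co-occurring event
category we correlate per-county event-day counts with SVI using
Spearman's rank correlation (average ranks for ties), restricted to the
*affected* counties — those with at least one day of that category —
matching the per-panel sample sizes of the published scatter plots. No
p-values are attached: with a handful of affected counties the
coefficient is descriptive only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from coclimate.cooccurrence import CO_CATEGORIES

__all__ = [
    "spearman_rho",
    "correlate_events_svi",
    "quartile_summary",
    "QuartileSummary",
    "validate_svi_table",
]


def validate_svi_table(svi: pd.DataFrame) -> pd.Series:
    """Return a county -> score Series, checking range and uniqueness."""
    if not {"county", "svi"}.issubset(svi.columns):
        raise ValueError("SVI table needs columns county, svi")
    if svi["county"].duplicated().any():
        dups = sorted(svi.loc[svi["county"].duplicated(), "county"].unique())
        raise ValueError(f"duplicate SVI rows for counties: {dups}")
    vals = svi["svi"].to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any() or (vals > 1).any():
        raise ValueError("SVI scores must be finite and in [0, 1]")
    return pd.Series(vals, index=svi["county"].to_numpy())


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks. Inputs must be equal-length (>= 2)
    sequences of finite numbers; degenerate inputs (zero rank variance)
    yield ``nan``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx, sy = rx.std(), ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass(frozen=True)
class CorrelationResult:
    category: str
    n: int
    rho: float
    estimable: bool
    subset: str


def correlate_events_svi(
    summary,
    svi: pd.DataFrame,
    categories: tuple[str, ...] | None = None,
    subset_affected: bool = True,
) -> pd.DataFrame:
    """Correlate per-county event-day counts with SVI per category.

    Parameters
    ----------
    summary
        A :class:`~coclimate.cooccurrence.CooccurrenceSummary`; its
        ``per_county`` table supplies day counts per category.
    svi
        ``county, svi`` table covering every affected county.
    categories
        Categories to correlate; defaults to all single-event marginals
        plus the exclusive co-occurring categories.
    subset_affected
        Restrict each correlation to counties with >= 1 day of that
        category (the published convention). ``False`` uses all
        counties in the summary.

    Returns a frame ``category, n, rho, estimable, subset``; categories
    with fewer than 2 usable counties (or zero rank variance) are
    flagged not estimable with ``rho = nan``.
    """
    scores = validate_svi_table(svi)
    per_county = summary.per_county
    if categories is None:
        categories = ("AW_marginal", "WBZD_marginal", "PO_marginal") + CO_CATEGORIES
    rows = []
    for cat in categories:
        if cat not in per_county.columns:
            raise KeyError(f"unknown category {cat!r}")
        counts = per_county[cat]
        if subset_affected:
            counts = counts[counts >= 1]
        missing = sorted(set(counts.index) - set(scores.index))
        if missing:
            raise ValueError(f"SVI missing for affected counties: {missing}")
        n = int(len(counts))
        subset = "affected" if subset_affected else "all"
        if n < 2:
            rows.append((cat, n, float("nan"), False, subset))
            continue
        rho = spearman_rho(counts.to_numpy(), scores.loc[counts.index].to_numpy())
        rows.append((cat, n, rho, bool(np.isfinite(rho)), subset))
    return pd.DataFrame(rows, columns=["category", "n", "rho", "estimable", "subset"])


@dataclass
class QuartileSummary:
    """Co-occurring county-day counts in the SVI extremes.

    ``top`` counts days in counties with svi > hi (most vulnerable
    quarter), ``bottom`` in counties with svi < lo; boundary values fall
    in neither stratum. ``mean_svi_unassessed`` is the mean score of
    counties lacking reliable outage data.
    """

    hi: float
    lo: float
    top: dict[str, int]
    bottom: dict[str, int]
    n_top_counties: int
    n_bottom_counties: int
    mean_svi_unassessed: float

    def to_dict(self) -> dict:
        return {
            "hi": self.hi,
            "lo": self.lo,
            "top": dict(self.top),
            "bottom": dict(self.bottom),
            "n_top_counties": self.n_top_counties,
            "n_bottom_counties": self.n_bottom_counties,
            "mean_svi_unassessed": self.mean_svi_unassessed,
        }


def quartile_summary(
    calendar: pd.DataFrame,
    svi: pd.DataFrame,
    hi: float = 0.75,
    lo: float = 0.25,
) -> QuartileSummary:
    """Stratify co-occurring county-days by SVI extremes.

    Counts each exclusive co-occurring category's county-days within the
    ``svi > hi`` and ``svi < lo`` county strata, and reports the mean
    SVI of counties whose PO flag is entirely missing (no reliable
    outage data).
    """
    scores = validate_svi_table(svi)
    missing = sorted(set(calendar["county"].unique()) - set(scores.index))
    if missing:
        raise ValueError(f"SVI missing for calendar counties: {missing}")

    top_counties = set(scores.index[scores > hi])
    bot_counties = set(scores.index[scores < lo])

    def stratum_counts(counties: set[str]) -> dict[str, int]:
        sub = calendar[calendar["county"].isin(counties)]
        vc = sub["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CO_CATEGORIES}

    unassessed = calendar.groupby("county")["po"].apply(lambda s: s.isna().all())
    unassessed_counties = list(unassessed.index[unassessed])
    mean_unassessed = (
        float(scores.loc[unassessed_counties].mean())
        if unassessed_counties
        else float("nan")
    )
    return QuartileSummary(
        hi=hi,
        lo=lo,
        top=stratum_counts(top_counties),
        bottom=stratum_counts(bot_counties),
        n_top_counties=len(top_counties),
        n_bottom_counties=len(bot_counties),
        mean_svi_unassessed=mean_unassessed,
    )
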