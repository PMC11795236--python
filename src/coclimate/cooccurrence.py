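"""Event calendar assembly and co-occurrence tabulation.

The calendar is the central product: one row per county-day over the
full study grid (e.g. 58 California counties x 730 days of 2018-2019 =
42,340 rows) with boolean AW / WBZD / PO flags and a mutually exclusive
category. PO is *not assessable* in counties without reliable outage
data: the po flag is missing there and such county-days can never enter
a PO-involving category or denominator.

Categories partition every county-day into one of eight classes:
none, AW, WBZD, PO, AW+WBZD, AW+PO, WBZD+PO, AW+WBZD+PO. Pair
categories exclude the triple, so the exclusive multi-event counts sum
to the total number of co-occurring county-days.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "CO_CATEGORIES",
    "build_event_calendar",
    "tabulate",
    "CooccurrenceSummary",
    "round_half_up",
]

CATEGORIES = (
    "none",
    "AW",
    "WBZD",
    "PO",
    "AW+WBZD",
    "AW+PO",
    "WBZD+PO",
    "AW+WBZD+PO",
)
#: exclusive multi-event (co-occurring) categories
CO_CATEGORIES = ("AW+WBZD", "AW+PO", "WBZD+PO", "AW+WBZD+PO")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (half-up), as printed percentages are."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _category(aw: bool, wbzd: bool, po: bool) -> str:
    parts = [name for name, flag in (("AW", aw), ("WBZD", wbzd), ("PO", po)) if flag]
    return "+".join(parts) if parts else "none"


def _flag_set(flags: pd.DataFrame | None) -> set[tuple]:
    if flags is None or len(flags) == 0:
        return set()
    df = flags[["county", "date"]].copy()
    df["date"] = pd.to_datetime(df["date"])
    return set(map(tuple, df.itertuples(index=False)))


def build_event_calendar(
    aw_flags: pd.DataFrame,
    wbzd_flags: pd.DataFrame,
    po_flags: pd.DataFrame,
    counties: Sequence[str],
    study_start: str | pd.Timestamp,
    study_end: str | pd.Timestamp,
    reliable_counties: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble the dense county-day event calendar.

    Parameters
    ----------
    aw_flags, wbzd_flags, po_flags
        ``county, date`` frames from the three detectors (wbzd may carry
        a fire_id column; duplicates are collapsed).
    counties
        Full county roster (the calendar covers every roster county).
    study_start, study_end
        Inclusive date bounds of the study period.
    reliable_counties
        Counties with reliable outage data; elsewhere po is set to
        missing (not assessable). ``None`` means all counties reliable.

    Returns the calendar frame ``county, date, aw, wbzd, po, category``
    with ``po`` a nullable boolean. Raises ``ValueError`` when a flag
    falls outside the roster or period, or a PO flag occurs in a
    non-assessable county.
    """
    counties = list(counties)
    roster = set(counties)
    dates = pd.date_range(study_start, study_end, freq="D")
    period = set(dates)
    reliable = roster if reliable_counties is None else set(reliable_counties)

    sets = {
        "aw": _flag_set(aw_flags),
        "wbzd": _flag_set(wbzd_flags),
        "po": _flag_set(po_flags),
    }
    for name, fs in sets.items():
        offenders = [
            (c, d.date().isoformat())
            for c, d in fs
            if c not in roster or d not in period
        ]
        if offenders:
            raise ValueError(
                f"{name} flags outside roster/study period: {sorted(offenders)[:10]}"
            )
    bad_po = sorted({c for c, _ in sets["po"] if c not in reliable})
    if bad_po:
        raise ValueError(
            f"PO flags in counties without reliable outage data: {bad_po}"
        )

    idx = pd.MultiIndex.from_product([counties, dates], names=["county", "date"])
    cal = pd.DataFrame(index=idx).reset_index()
    keys = list(zip(cal["county"], cal["date"]))
    cal["aw"] = [k in sets["aw"] for k in keys]
    cal["wbzd"] = [k in sets["wbzd"] for k in keys]
    assessable = cal["county"].isin(reliable)
    po_vals = pd.array([k in sets["po"] for k in keys], dtype="boolean")
    po_vals[~assessable.to_numpy()] = pd.NA
    cal["po"] = po_vals
    cal["category"] = [
        _category(a, w, bool(p) if p is not pd.NA else False)
        for a, w, p in zip(cal["aw"], cal["wbzd"], cal["po"])
    ]
    return cal


@dataclass
class CooccurrenceSummary:
    """Exclusive and marginal co-occurrence accounting for a calendar.

    Day-count percentages are shares of the full county-day grid (the
    printed convention); county percentages use the 58-county roster for
    AW/WBZD figures and the reliable-county count for any PO-involving
    figure.
    """

    n_counties: int
    n_reliable_counties: int
    n_county_days: int
    exclusive_day_counts: dict[str, int]
    marginal_day_counts: dict[str, int]
    marginal_county_counts: dict[str, int]
    category_county_counts: dict[str, int]
    inclusive_pair_day_counts: dict[str, int]
    per_county: pd.DataFrame = field(repr=False)

    @property
    def total_cooccurring_days(self) -> int:
        """Sum of the four exclusive multi-event categories."""
        return sum(self.exclusive_day_counts[c] for c in CO_CATEGORIES)

    def county_denominator(self, category: str) -> int:
        return self.n_reliable_counties if "PO" in category else self.n_counties

    def percent_counties(self, category: str, ndigits: int = 0) -> float:
        """Affected-county share of the category's denominator, in %."""
        n = self.category_county_counts.get(
            category, self.marginal_county_counts.get(category, 0)
        )
        return round_half_up(100.0 * n / self.county_denominator(category), ndigits)

    def percent_marginal_counties(self, event: str, ndigits: int = 0) -> float:
        n = self.marginal_county_counts[event]
        return round_half_up(100.0 * n / self.county_denominator(event), ndigits)

    def percent_days(self, event: str, ndigits: int = 2) -> float:
        """Marginal county-day share of the full grid, in %."""
        return round_half_up(
            100.0 * self.marginal_day_counts[event] / self.n_county_days, ndigits
        )

    def to_dict(self) -> dict:
        return {
            "n_counties": self.n_counties,
            "n_reliable_counties": self.n_reliable_counties,
            "n_county_days": self.n_county_days,
            "exclusive_day_counts": dict(self.exclusive_day_counts),
            "marginal_day_counts": dict(self.marginal_day_counts),
            "marginal_county_counts": dict(self.marginal_county_counts),
            "category_county_counts": dict(self.category_county_counts),
            "inclusive_pair_day_counts": dict(self.inclusive_pair_day_counts),
            "total_cooccurring_days": self.total_cooccurring_days,
        }


def tabulate(
    calendar: pd.DataFrame,
    reliable_counties: Iterable[str] | None = None,
) -> CooccurrenceSummary:
    """Tabulate exclusive-category and marginal counts from a calendar.

    Exclusive categories partition the calendar (their day counts sum to
    its size). Marginal per-event totals treat events non-exclusively:
    the AW marginal is the sum of the four exclusive categories
    containing AW, and likewise for WBZD and PO. Inclusive pair counts
    (pair + triple) are also reported since published pair figures may
    follow either convention.
    """
    counties = calendar["county"].unique()
    if reliable_counties is None:
        # a county is assessable iff its po column is ever non-missing
        assessable = calendar.groupby("county")["po"].apply(
            lambda s: s.notna().any()
        )
        reliable = set(assessable.index[assessable])
    else:
        reliable = set(reliable_counties)

    exclusive = {c: 0 for c in CATEGORIES}
    exclusive.update(calendar["category"].value_counts().to_dict())

    marg_days, marg_counties = {}, {}
    for event, col in (("AW", "aw"), ("WBZD", "wbzd"), ("PO", "po")):
        mask = calendar[col].fillna(False).astype(bool)
        marg_days[event] = int(mask.sum())
        marg_counties[event] = int(calendar.loc[mask, "county"].nunique())

    cat_counties = {
        c: int(calendar.loc[calendar["category"] == c, "county"].nunique())
        for c in CATEGORIES
    }

    inclusive_pairs = {
        "AW+WBZD": exclusive["AW+WBZD"] + exclusive["AW+WBZD+PO"],
        "AW+PO": exclusive["AW+PO"] + exclusive["AW+WBZD+PO"],
        "WBZD+PO": exclusive["WBZD+PO"] + exclusive["AW+WBZD+PO"],
    }

    per_county = (
        calendar.pivot_table(
            index="county", columns="category", aggfunc="size", fill_value=0
        )
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .reindex(counties, fill_value=0)
    )
    per_county.columns.name = None
    for event, col in (("AW", "aw"), ("WBZD", "wbzd"), ("PO", "po")):
        per_county[f"{event}_marginal"] = (
            calendar.assign(flag=calendar[col].fillna(False).astype(bool))
            .groupby("county")["flag"]
            .sum()
            .reindex(counties, fill_value=0)
            .astype(int)
        )
    per_county["cooccurring"] = per_county[list(CO_CATEGORIES)].sum(axis=1)

    return CooccurrenceSummary(
        n_counties=int(len(counties)),
        n_reliable_counties=int(len(reliable)),
        n_county_days=int(len(calendar)),
        exclusive_day_counts={c: int(exclusive[c]) for c in CATEGORIES},
        marginal_day_counts=marg_days,
        marginal_county_counts=marg_counties,
        category_county_counts=cat_counties,
        inclusive_pair_day_counts=inclusive_pairs,
        per_county=per_county,
    )
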