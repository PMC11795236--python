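"""Synthetic inputs with a planted-event truth ledger.

Generates internally consistent temperature, wildfire, outage and SVI
inputs for the full pipeline, together with a :class:`TruthLedger`
recording exactly which county-days were planted as detectable events.
The ledger is the oracle for parameter-recovery tests: running the
detectors on generated data must recover the planted warm days, burn
zone disaster days, outage days and reliable-county set exactly.

The temperature model is a per-county seasonal sinusoid plus Gaussian
noise. Planted warm days are forced strictly above both detection
thresholds (the week-of-year 85th percentile of the generated baseline,
and 24 degC) with a safety margin; all non-planted study days are, by
default, clamped strictly below at least one threshold so the planted
set is exactly the detectable set (a generator guarantee, toggleable
for stress tests). Outage traces are hourly by default with sub-0.4%
background jitter, planted episodes at stated fractions/durations, and
sub-threshold decoys. Counties are laid out as unit squares on a line
so polygon footprints and county geometries stay trivial.

Limitations by design: no raster temperature grids, no realistic fire
spread geometry, no utility-feed quirks beyond reporting gaps.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass, field, fields as _dataclass_fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from coclimate import climatology
from coclimate.outage import OutageSeries
from coclimate.wildfire import WildfireRecord

__all__ = [
    "SimConfig",
    "CountyClimate",
    "FireBlueprint",
    "OutagePlant",
    "ReportingMeta",
    "TruthLedger",
    "SimulationError",
    "SimResult",
    "generate_temperatures",
    "generate_fires",
    "generate_outages",
    "generate_svi",
    "build_truth_ledger",
    "county_geometries",
    "simulate",
    "california_county_day_config",
]

SVI_MODES = ("independent", "increasing-with-events", "decreasing-with-events")

#: detection thresholds the truth ledger encodes (the standard analysis values)
LEDGER_PCT_THRESHOLD = 0.005
LEDGER_MIN_HOURS = 8.0
LEDGER_MIN_REPORTING = 0.5
LEDGER_MIN_COVERAGE = 0.5


class SimulationError(ValueError):
    """Raised when a configuration cannot be realized as specified."""


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


@dataclass(frozen=True)
class CountyClimate:
    """Seasonal temperature parameters for one county (degC)."""

    mean_c: float = 15.0
    amplitude_c: float = 8.0
    noise_c: float = 2.0


@dataclass(frozen=True)
class FireBlueprint:
    """Planted fire: dates, severity fields, footprint counties.

    ``community_overlap`` must be decided in the blueprint (True/False)
    so disaster status is known without a density grid. When
    ``as_polygon`` is set the emitted record carries a polygon footprint
    (small boxes inside each listed county's unit square) instead of the
    explicit county list, exercising the spatial-overlap path.
    """

    fire_id: str
    ignition: dt.date
    containment: dt.date
    counties: tuple[str, ...]
    structures_destroyed: int = 0
    civilian_deaths: int = 0
    fema_fmd: bool = False
    community_overlap: bool = True
    as_polygon: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "ignition", _as_date(self.ignition))
        object.__setattr__(self, "containment", _as_date(self.containment))
        if self.containment < self.ignition:
            raise SimulationError(
                f"blueprint {self.fire_id}: containment before ignition"
            )

    @property
    def is_disaster(self) -> bool:
        severity = (
            self.structures_destroyed >= 1
            or self.civilian_deaths >= 1
            or self.fema_fmd
        )
        return severity and self.community_overlap


@dataclass(frozen=True)
class OutagePlant:
    """Planted outage episode: county, start, duration, customer fraction."""

    county: str
    start: pd.Timestamp
    duration_h: float
    fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        if self.fraction <= 0:
            raise SimulationError(
                f"outage plant in {self.county}: fraction must be > 0"
            )
        if self.duration_h <= 0:
            raise SimulationError(
                f"outage plant in {self.county}: duration must be > 0"
            )

    @property
    def end(self) -> pd.Timestamp:
        return self.start + pd.Timedelta(hours=self.duration_h)

    @property
    def qualifies(self) -> bool:
        return self.fraction > LEDGER_PCT_THRESHOLD and (
            self.duration_h >= LEDGER_MIN_HOURS
        )


@dataclass(frozen=True)
class ReportingMeta:
    """Per-county outage-feed quality used by the reliability filter."""

    reporting_fraction: float = 1.0
    coverage_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("reporting_fraction", "coverage_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name}={v} outside [0, 1]")

    @property
    def reliable(self) -> bool:
        return (
            self.reporting_fraction >= LEDGER_MIN_REPORTING
            and self.coverage_fraction >= LEDGER_MIN_COVERAGE
        )


@dataclass
class SimConfig:
    """Full simulation configuration; the study conditions in one object.

    Defaults mirror the California analysis design: a 1981-2010
    climatology baseline, a 2018-2019 study period, hourly outage
    reporting, and 10,000 customers per county. Counties are named
    ``C01..Cnn``.
    """

    n_counties: int
    baseline_years: tuple[int, int] = (1981, 2010)
    study_years: tuple[int, int] = (2018, 2019)
    seed: int = 0
    default_climate: CountyClimate = field(default_factory=CountyClimate)
    county_climate: dict[str, CountyClimate] = field(default_factory=dict)
    planted_warm_days: list[tuple[str, dt.date]] = field(default_factory=list)
    planted_fires: list[FireBlueprint] = field(default_factory=list)
    planted_outages: list[OutagePlant] = field(default_factory=list)
    outage_reporting: dict[str, ReportingMeta] = field(default_factory=dict)
    customers_total: int = 10_000
    outage_resolution_h: float = 1.0
    svi_mode: str = "independent"
    svi_jitter: float = 0.0
    svi_event_source: str = "AW"
    svi_values: dict[str, float] | None = None
    include_decoys: bool = True
    warm_margin_c: float = 1.5
    clamp_nonplanted: bool = True
    tmean_max_c: float = 60.0

    def __post_init__(self) -> None:
        self.planted_warm_days = [
            (c, _as_date(d)) for c, d in self.planted_warm_days
        ]
        self.validate()

    @property
    def counties(self) -> list[str]:
        return [f"C{i:02d}" for i in range(1, self.n_counties + 1)]

    @property
    def study_start(self) -> dt.date:
        return dt.date(self.study_years[0], 1, 1)

    @property
    def study_end(self) -> dt.date:
        return dt.date(self.study_years[1], 12, 31)

    def climate_for(self, county: str) -> CountyClimate:
        return self.county_climate.get(county, self.default_climate)

    def reporting_for(self, county: str) -> ReportingMeta:
        return self.outage_reporting.get(county, ReportingMeta())

    def validate(self) -> None:
        if self.n_counties < 1:
            raise SimulationError("n_counties must be >= 1")
        b0, b1 = self.baseline_years
        s0, s1 = self.study_years
        if b0 > b1 or s0 > s1:
            raise SimulationError("year ranges must be (first, last) inclusive")
        if not (b1 < s0 or s1 < b0):
            raise SimulationError("baseline and study year ranges overlap")
        if self.svi_mode not in SVI_MODES:
            raise SimulationError(f"unknown svi_mode {self.svi_mode!r}")
        if self.customers_total <= 0:
            raise SimulationError("customers_total must be > 0")
        roster = set(self.counties)
        lo, hi = self.study_start, self.study_end
        for county, d in self.planted_warm_days:
            if county not in roster:
                raise SimulationError(f"planted warm day in unknown county {county}")
            if not lo <= d <= hi:
                raise SimulationError(f"planted warm day {county} {d} outside study")
            if d.month == 2 and d.day == 29:
                raise SimulationError("study-period leap-day planting is forbidden")
        for bp in self.planted_fires:
            if not (lo <= bp.ignition and bp.containment <= hi):
                raise SimulationError(
                    f"fire {bp.fire_id} outside study period"
                )
            unknown = set(bp.counties) - roster
            if unknown:
                raise SimulationError(
                    f"fire {bp.fire_id} in unknown counties {sorted(unknown)}"
                )
        self._validate_outage_plants(lo, hi, roster)

    def to_dict(self) -> dict:
        """Plain-data form suitable for YAML/JSON serialization."""

        def clim(c: CountyClimate) -> dict:
            return {
                "mean_c": c.mean_c,
                "amplitude_c": c.amplitude_c,
                "noise_c": c.noise_c,
            }

        return {
            "n_counties": self.n_counties,
            "baseline_years": list(self.baseline_years),
            "study_years": list(self.study_years),
            "seed": self.seed,
            "default_climate": clim(self.default_climate),
            "county_climate": {c: clim(v) for c, v in self.county_climate.items()},
            "planted_warm_days": [
                [c, d.isoformat()] for c, d in self.planted_warm_days
            ],
            "planted_fires": [
                {
                    "fire_id": bp.fire_id,
                    "ignition": bp.ignition.isoformat(),
                    "containment": bp.containment.isoformat(),
                    "counties": list(bp.counties),
                    "structures_destroyed": bp.structures_destroyed,
                    "civilian_deaths": bp.civilian_deaths,
                    "fema_fmd": bp.fema_fmd,
                    "community_overlap": bp.community_overlap,
                    "as_polygon": bp.as_polygon,
                }
                for bp in self.planted_fires
            ],
            "planted_outages": [
                {
                    "county": p.county,
                    "start": p.start.isoformat(),
                    "duration_h": p.duration_h,
                    "fraction": p.fraction,
                }
                for p in self.planted_outages
            ],
            "outage_reporting": {
                c: {
                    "reporting_fraction": m.reporting_fraction,
                    "coverage_fraction": m.coverage_fraction,
                }
                for c, m in self.outage_reporting.items()
            },
            "customers_total": self.customers_total,
            "outage_resolution_h": self.outage_resolution_h,
            "svi_mode": self.svi_mode,
            "svi_jitter": self.svi_jitter,
            "svi_event_source": self.svi_event_source,
            "svi_values": self.svi_values,
            "include_decoys": self.include_decoys,
            "warm_margin_c": self.warm_margin_c,
            "clamp_nonplanted": self.clamp_nonplanted,
            "tmean_max_c": self.tmean_max_c,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        known = {f.name for f in _dataclass_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimulationError(f"unknown SimConfig keys: {sorted(unknown)}")
        kw = dict(raw)
        for key in ("baseline_years", "study_years"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if "default_climate" in kw and isinstance(kw["default_climate"], dict):
            kw["default_climate"] = CountyClimate(**kw["default_climate"])
        if "county_climate" in kw:
            kw["county_climate"] = {
                c: CountyClimate(**v) if isinstance(v, dict) else v
                for c, v in kw["county_climate"].items()
            }
        if "planted_warm_days" in kw:
            kw["planted_warm_days"] = [
                (c, _as_date(d)) for c, d in kw["planted_warm_days"]
            ]
        if "planted_fires" in kw:
            kw["planted_fires"] = [
                FireBlueprint(
                    **{**bp, "counties": tuple(bp["counties"])}
                )
                if isinstance(bp, dict)
                else bp
                for bp in kw["planted_fires"]
            ]
        if "planted_outages" in kw:
            kw["planted_outages"] = [
                OutagePlant(**p) if isinstance(p, dict) else p
                for p in kw["planted_outages"]
            ]
        if "outage_reporting" in kw:
            kw["outage_reporting"] = {
                c: ReportingMeta(**m) if isinstance(m, dict) else m
                for c, m in kw["outage_reporting"].items()
            }
        return cls(**kw)

    def _validate_outage_plants(self, lo, hi, roster) -> None:
        margin = pd.Timedelta(hours=self.outage_resolution_h)
        by_county: dict[str, list[OutagePlant]] = {}
        for p in self.planted_outages:
            if p.county not in roster:
                raise SimulationError(f"outage plant in unknown county {p.county}")
            if not (
                pd.Timestamp(lo) <= p.start
                and p.end <= pd.Timestamp(hi) + pd.Timedelta(days=1)
            ):
                raise SimulationError(
                    f"outage plant {p.county} {p.start} outside study period"
                )
            by_county.setdefault(p.county, []).append(p)
        # planted windows expanded by one reporting interval must be
        # pairwise disjoint, otherwise adjacent plants would merge into a
        # single run and the ledger would no longer be exact
        for county, plants in by_county.items():
            plants = sorted(plants, key=lambda p: p.start)
            for a, b in zip(plants, plants[1:]):
                if b.start < a.end + margin:
                    raise SimulationError(
                        f"outage plants in {county} abut or overlap "
                        f"({a.start} .. {a.end} vs {b.start}); separate them by "
                        "at least one reporting interval"
                    )


@dataclass
class TruthLedger:
    """Ground truth of planted, detectable events.

    Every entry corresponds to a planted item in the configuration,
    filtered by the standard detection rules (e.g. outage plants under
    0.5% of customers or shorter than 8 h never enter ``po_days``;
    plants in unreliable counties are excluded).
    """

    warm_days: set[tuple[str, dt.date]] = field(default_factory=set)
    disaster_fires: set[str] = field(default_factory=set)
    wbzd_days: set[tuple[str, dt.date]] = field(default_factory=set)
    po_days: set[tuple[str, dt.date]] = field(default_factory=set)
    reliable_counties: set[str] = field(default_factory=set)

    def to_json(self) -> str:
        def days(s):
            return sorted([c, d.isoformat()] for c, d in s)

        return json.dumps(
            {
                "warm_days": days(self.warm_days),
                "disaster_fires": sorted(self.disaster_fires),
                "wbzd_days": days(self.wbzd_days),
                "po_days": days(self.po_days),
                "reliable_counties": sorted(self.reliable_counties),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        raw = json.loads(text)

        def days(key):
            return {(c, dt.date.fromisoformat(d)) for c, d in raw[key]}

        return cls(
            warm_days=days("warm_days"),
            disaster_fires=set(raw["disaster_fires"]),
            wbzd_days=days("wbzd_days"),
            po_days=days("po_days"),
            reliable_counties=set(raw["reliable_counties"]),
        )


def flags_to_day_set(flags: pd.DataFrame) -> set[tuple[str, dt.date]]:
    """Normalize a detector's county/date frame for ledger comparison."""
    return {
        (c, pd.Timestamp(d).date())
        for c, d in flags[["county", "date"]].itertuples(index=False)
    }


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, stream])


def _seasonal_frame(
    config: SimConfig, years: tuple[int, int], rng: np.random.Generator
) -> pd.DataFrame:
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    # phase puts the seasonal peak around mid-July (day ~196)
    seasonal_unit = np.sin(2 * np.pi * (doy - 105.25) / 365.25)
    frames = []
    for county in config.counties:
        clim = config.climate_for(county)
        temps = (
            clim.mean_c
            + clim.amplitude_c * seasonal_unit
            + rng.normal(0.0, clim.noise_c, len(dates))
        )
        frames.append(
            pd.DataFrame({"county": county, "date": dates, "tmean_c": temps})
        )
    return pd.concat(frames, ignore_index=True)


def generate_temperatures(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (baseline, study) daily mean temperature frames.

    Planted warm days sit strictly above both the generated baseline's
    week-of-year percentile and 24 degC by ``warm_margin_c``; with
    ``clamp_nonplanted`` (default) every other study day is strictly
    below at least one of the two thresholds, so the detectable set
    equals the planted set exactly.
    """
    baseline = _seasonal_frame(config, config.baseline_years, _rng(config, 1))
    study = _seasonal_frame(config, config.study_years, _rng(config, 2))

    clim = climatology.build_weekly_climatology(baseline)
    p85 = {(c, w): v for c, w, v in clim[["county", "week", "p85_c"]].itertuples(index=False)}

    weeks = climatology.week_of_year(study["date"])
    thresholds = np.array(
        [p85[(c, w)] for c, w in zip(study["county"], weeks)]
    )
    planted = set(
        (c, pd.Timestamp(d)) for c, d in config.planted_warm_days
    )
    is_planted = np.array(
        [(c, d) in planted for c, d in zip(study["county"], study["date"])]
    )

    vals = study["tmean_c"].to_numpy().copy()
    forced = np.maximum(thresholds, 24.0) + config.warm_margin_c
    too_hot = forced > config.tmean_max_c
    if (is_planted & too_hot).any():
        bad = study.loc[is_planted & too_hot, ["county", "date"]].head(5)
        raise SimulationError(
            "planted warm day margin exceeds the configured temperature bound "
            f"for: {bad.to_dict('records')}"
        )
    vals[is_planted] = forced[is_planted]
    if config.clamp_nonplanted:
        # push accidental exceedances strictly below the *larger*
        # threshold: below p85 when p85 > 24 (fails the percentile
        # condition), below 24 otherwise (fails the absolute condition)
        violate = (~is_planted) & (vals > 24.0) & (vals >= thresholds)
        vals[violate] = np.maximum(thresholds[violate], 24.0) - 0.1
    study = study.assign(tmean_c=vals)
    return baseline, study


def county_geometries(config: SimConfig) -> dict[str, "box"]:
    """Unit-square planar geometry for each county, laid out on a line."""
    return {
        county: box(i, 0.0, i + 1.0, 1.0)
        for i, county in enumerate(config.counties)
    }


def _blueprint_polygon(bp: FireBlueprint, config: SimConfig) -> "box":
    from shapely.ops import unary_union

    order = {c: i for i, c in enumerate(config.counties)}
    boxes = [
        box(order[c] + 0.2, 0.2, order[c] + 0.8, 0.8) for c in bp.counties
    ]
    return unary_union(boxes)


def generate_fires(config: SimConfig) -> list[WildfireRecord]:
    """Emit wildfire records from blueprints (plus default decoys).

    Decoys exercise classifier branches without entering the ledger: one
    fire failing the severity disjunction and one with severity but no
    community overlap.
    """
    records = []
    for bp in config.planted_fires:
        if bp.as_polygon:
            footprint, counties = _blueprint_polygon(bp, config), None
        else:
            footprint, counties = None, tuple(bp.counties)
        records.append(
            WildfireRecord(
                fire_id=bp.fire_id,
                ignition_date=bp.ignition,
                containment_date=bp.containment,
                structures_destroyed=bp.structures_destroyed,
                civilian_deaths=bp.civilian_deaths,
                fema_fmd=bp.fema_fmd,
                counties=counties,
                footprint=footprint,
                community_overlap=bp.community_overlap,
            )
        )
    if config.include_decoys:
        c0 = config.counties[0]
        start = config.study_start
        records.append(
            WildfireRecord(
                fire_id="decoy-no-severity",
                ignition_date=start,
                containment_date=start + dt.timedelta(days=2),
                counties=(c0,),
                community_overlap=True,
            )
        )
        records.append(
            WildfireRecord(
                fire_id="decoy-no-community",
                ignition_date=start,
                containment_date=start + dt.timedelta(days=4),
                structures_destroyed=2,
                counties=(c0,),
                community_overlap=False,
            )
        )
    return records


def _decoy_windows(
    config: SimConfig, county: str, needs: list[float]
) -> list[pd.Timestamp]:
    """Find day-starts for decoy episodes that stay clear of plants."""
    margin = pd.Timedelta(hours=2 * config.outage_resolution_h)
    busy = [
        (p.start - margin, p.end + margin)
        for p in config.planted_outages
        if p.county == county
    ]
    starts = []
    day = pd.Timestamp(config.study_start)
    end_limit = pd.Timestamp(config.study_end) - pd.Timedelta(days=2)
    for hours in needs:
        while day <= end_limit:
            s = day + pd.Timedelta(hours=1)
            e = s + pd.Timedelta(hours=hours)
            clear = all(e + margin <= b0 or s - margin >= b1 for b0, b1 in busy)
            prior = all(
                e + margin <= t or s - margin >= t + pd.Timedelta(hours=h)
                for t, h in zip(starts, needs)
            )
            if clear and prior:
                starts.append(s)
                day += pd.Timedelta(days=2)
                break
            day += pd.Timedelta(days=1)
        else:
            return starts  # no room left; emit what fits
    return starts


def generate_outages(config: SimConfig) -> list[OutageSeries]:
    """Generate per-county customers-out series at the configured cadence.

    Background jitter stays strictly below 0.5% of customers; planted
    episodes raise customers-out to their stated fraction for their
    stated duration. Two default decoys exercise the detector's
    rejection branches: a 0.4% outage for 24 h (never crosses the
    customer threshold) and a 2% outage for 7 h (too short). Counties with ``reporting_fraction < 1`` have that
    share of their non-planted readings dropped at random.
    """
    rng = _rng(config, 3)
    step = pd.Timedelta(hours=config.outage_resolution_h)
    stamps = pd.date_range(
        config.study_start,
        pd.Timestamp(config.study_end) + pd.Timedelta(days=1) - step,
        freq=step,
    )
    total = config.customers_total
    jitter_cap = max(1, math.floor(0.004 * total))
    decoy_county = config.counties[0] if config.include_decoys else None

    series = []
    for county in config.counties:
        out = rng.integers(0, jitter_cap + 1, len(stamps)).astype(np.int64)
        protected = np.zeros(len(stamps), dtype=bool)
        plants = [p for p in config.planted_outages if p.county == county]
        if county == decoy_county:
            windows = _decoy_windows(config, county, [24.0, 7.0])
            for (hours, frac), s in zip([(24.0, 0.004), (7.0, 0.02)], windows):
                plants.append(OutagePlant(county, s, hours, frac))
        for p in plants:
            mask = np.asarray((stamps >= p.start) & (stamps < p.end))
            level = math.ceil(p.fraction * total)
            out[mask] = np.maximum(out[mask], level)
            protected |= mask
        out = np.minimum(out, total)

        meta = config.reporting_for(county)
        keep = np.ones(len(stamps), dtype=bool)
        if meta.reporting_fraction < 1.0:
            droppable = np.flatnonzero(~protected)
            n_drop = int(round((1.0 - meta.reporting_fraction) * len(stamps)))
            n_drop = min(n_drop, len(droppable))
            keep[rng.choice(droppable, size=n_drop, replace=False)] = False
        rec = pd.DataFrame(
            {"timestamp": stamps[keep], "customers_out": out[keep]}
        )
        series.append(
            OutageSeries(
                county=county,
                records=rec,
                customers_total=total,
                reporting_fraction=meta.reporting_fraction,
                coverage_fraction=meta.coverage_fraction,
            )
        )
    return series


def _plant_po_days(plant: OutagePlant) -> set[tuple[str, dt.date]]:
    last = (plant.end - pd.Timedelta(nanoseconds=1)).normalize()
    return {
        (plant.county, d.date())
        for d in pd.date_range(plant.start.normalize(), last, freq="D")
    }


def build_truth_ledger(config: SimConfig) -> TruthLedger:
    """Derive the ground-truth event sets implied by the configuration."""
    reliable = {
        c for c in config.counties if config.reporting_for(c).reliable
    }
    warm = set(config.planted_warm_days)
    disasters = {bp.fire_id for bp in config.planted_fires if bp.is_disaster}
    wbzd: set[tuple[str, dt.date]] = set()
    for bp in config.planted_fires:
        if not bp.is_disaster:
            continue
        for county in bp.counties:
            d = bp.ignition
            while d <= bp.containment:
                wbzd.add((county, d))
                d += dt.timedelta(days=1)
    po: set[tuple[str, dt.date]] = set()
    for plant in config.planted_outages:
        if plant.county in reliable and plant.qualifies:
            po |= _plant_po_days(plant)
    return TruthLedger(
        warm_days=warm,
        disaster_fires=disasters,
        wbzd_days=wbzd,
        po_days=po,
        reliable_counties=reliable,
    )


def _event_counts(config: SimConfig, ledger: TruthLedger) -> np.ndarray:
    """Per-county event-day counts for the configured SVI source."""
    aw, wb, po = ledger.warm_days, ledger.wbzd_days, ledger.po_days
    source = config.svi_event_source
    combos = {
        "AW": aw,
        "WBZD": wb,
        "PO": po,
        "AW+WBZD": aw & wb,
        "AW+PO": aw & po,
        "WBZD+PO": wb & po,
        "AW+WBZD+PO": aw & wb & po,
        "all": aw | wb | po,
    }
    if source not in combos:
        raise SimulationError(f"unknown svi_event_source {source!r}")
    days = combos[source]
    return np.array(
        [sum(1 for c, _ in days if c == county) for county in config.counties],
        dtype=float,
    )


def generate_svi(config: SimConfig, ledger: TruthLedger) -> pd.DataFrame:
    """Generate the county SVI table.

    Explicit ``svi_values`` win when provided. Otherwise mode
    ``independent`` draws uniform scores; the monotone modes apply a
    strictly increasing (or decreasing) affine transform of the chosen
    planted event-day counts into [0.05, 0.95], plus bounded jitter,
    so the downstream Spearman sign is known and, with zero jitter and
    distinct counts, the magnitude is exactly 1.
    """
    counties = config.counties
    if config.svi_values is not None:
        missing = set(counties) - set(config.svi_values)
        if missing:
            raise SimulationError(f"svi_values missing counties {sorted(missing)}")
        vals = np.array([config.svi_values[c] for c in counties], dtype=float)
    else:
        rng = _rng(config, 4)
        if config.svi_mode == "independent":
            vals = rng.uniform(0.0, 1.0, len(counties))
        else:
            counts = _event_counts(config, ledger)
            lo, hi = counts.min(), counts.max()
            base = (
                np.full(len(counties), 0.5)
                if hi == lo
                else 0.05 + 0.9 * (counts - lo) / (hi - lo)
            )
            if config.svi_mode == "decreasing-with-events":
                base = 1.0 - base
            vals = base + config.svi_jitter * rng.uniform(-1, 1, len(counties))
            vals = np.clip(vals, 0.0, 1.0)
    if (vals < 0).any() or (vals > 1).any():
        raise SimulationError("generated SVI outside [0, 1]")
    return pd.DataFrame({"county": counties, "svi": vals})


@dataclass
class SimResult:
    """Bundle of all generated inputs plus the truth ledger."""

    config: SimConfig
    baseline: pd.DataFrame
    study: pd.DataFrame
    fires: list[WildfireRecord]
    outages: list[OutageSeries]
    svi: pd.DataFrame
    ledger: TruthLedger


def simulate(config: SimConfig) -> SimResult:
    """Run every generator and assemble the truth ledger."""
    baseline, study = generate_temperatures(config)
    fires = generate_fires(config)
    outages = generate_outages(config)
    ledger = build_truth_ledger(config)
    svi = generate_svi(config, ledger)
    return SimResult(
        config=config,
        baseline=baseline,
        study=study,
        fires=fires,
        outages=outages,
        svi=svi,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# Reference scenario: the California 2018-2019 county-day accounting
# ---------------------------------------------------------------------------


def _reference_svi_values(counties: Sequence[str]) -> dict[str, float]:
    """58 scores: min 0, max 1, median 0.5; the 20 counties without
    reliable outage data (C39..C58) average 0.573."""
    reliable_vals = (
        [i / 44 for i in range(21)]           # 21 values in [0, 0.477]
        + [0.5, 0.5]
        + [0.5 + i / 30 for i in range(1, 16)]  # 15 values in (0.5, 1.0]
    )
    unreliable_vals = []
    for k in range(1, 11):
        unreliable_vals += [0.573 - 0.02 * k, 0.573 + 0.02 * k]
    vals = reliable_vals + unreliable_vals
    return dict(zip(counties, vals))


def california_county_day_config(seed: int = 0) -> SimConfig:
    """Synthetic configuration emulating the California 2018-2019 record.

    Plants events over 58 counties and 730 study days so that the
    statewide tallies match the published accounting: 2004 anomalously
    warm county-days across 56 counties, 1131 burn zone disaster days
    across 33 counties (63 of them with two simultaneous fires), 597
    long-outage days across 24 of the 38 counties with reliable outage
    feeds, and exclusive co-occurrences of 144 (AW+WBZD, 24 counties),
    29 (AW+PO, 5 counties), 10 (WBZD+PO, 7 counties) and a single
    triple-event day (2018-08-10, mirroring the Ferguson Fire day).
    The exact calendar placement of planted days within each county is
    arbitrary and chosen deterministically; the tallies are the point.
    """
    n = 58
    counties = [f"C{i:02d}" for i in range(1, n + 1)]
    study_days = pd.date_range("2018-01-01", "2019-12-31", freq="D")
    triple_county, triple_day = "C01", dt.date(2018, 8, 10)

    # per-county day counts for each exclusive category
    aw_wbzd = {c: 0 for c in counties}
    aw_wbzd["C01"] = 22
    for c in counties[1:8]:
        aw_wbzd[c] = 6
    for c in counties[8:24]:
        aw_wbzd[c] = 5

    aw_po = {c: 0 for c in counties}
    for c, k in zip(counties[7:12], (6, 6, 6, 6, 5)):
        aw_po[c] = k

    wbzd_po = {c: 0 for c in counties}
    wbzd_po["C01"] = 4
    for c in counties[1:7]:
        wbzd_po[c] = 1

    aw_only = {c: 0 for c in counties}
    for c in counties[:38]:
        aw_only[c] = 33
    for c in counties[38:56]:
        aw_only[c] = 32

    wbzd_only = {c: 0 for c in counties}
    for c in counties[:19]:
        wbzd_only[c] = 30
    for c in counties[19:33]:
        wbzd_only[c] = 29

    po_only = {c: 0 for c in counties}
    for c in counties[:5]:
        po_only[c] = 24
    for c in counties[5:24]:
        po_only[c] = 23

    warm_days: list[tuple[str, dt.date]] = [(triple_county, triple_day)]
    fires: list[FireBlueprint] = []
    outages: list[OutagePlant] = []

    # counties carrying a duplicate simultaneous fire over (part of)
    # their burn-zone block: 29 + 29 + 5 = 63 two-fire county-days
    dup_counts = {"C25": 29, "C26": 29, "C27": 5}

    def episode(county: str, day: dt.date) -> OutagePlant:
        start = pd.Timestamp(day) + pd.Timedelta(hours=8)
        return OutagePlant(county, start, 9.0, 0.015)

    outages.append(episode(triple_county, triple_day))

    for county in counties:
        free = [d.date() for d in study_days]
        if county == triple_county:
            free.remove(triple_day)
        cursor = 0

        def take(k: int) -> list[dt.date]:
            nonlocal cursor
            days = free[cursor : cursor + k]
            cursor += k
            return days

        d_aw_wbzd = take(aw_wbzd[county])
        d_wbzd_po = take(wbzd_po[county])
        d_wbzd_only = take(wbzd_only[county])
        d_aw_po = take(aw_po[county])
        d_aw_only = take(aw_only[county])
        d_po_only = take(po_only[county])

        warm_days += [(county, d) for d in d_aw_wbzd + d_aw_po + d_aw_only]
        outages += [episode(county, d) for d in d_wbzd_po + d_aw_po + d_po_only]

        wbzd_dates = sorted(d_aw_wbzd + d_wbzd_po + d_wbzd_only)
        if county == triple_county:
            wbzd_dates.append(triple_day)
        k = 0
        for run in _contiguous_runs(wbzd_dates):
            fires.append(
                FireBlueprint(
                    fire_id=f"{county}-F{k}",
                    ignition=run[0],
                    containment=run[-1],
                    counties=(county,),
                    structures_destroyed=1,
                )
            )
            k += 1
        dup = dup_counts.get(county, 0)
        if dup:
            dup_dates = sorted(d_wbzd_only)[:dup]
            for run in _contiguous_runs(dup_dates):
                fires.append(
                    FireBlueprint(
                        fire_id=f"{county}-F{k}-twin",
                        ignition=run[0],
                        containment=run[-1],
                        counties=(county,),
                        fema_fmd=True,
                    )
                )
                k += 1

    reporting = {c: ReportingMeta(1.0, 1.0) for c in counties[:38]}
    for c in counties[38:48]:
        reporting[c] = ReportingMeta(0.3, 1.0)
    for c in counties[48:]:
        reporting[c] = ReportingMeta(1.0, 0.4)

    return SimConfig(
        n_counties=n,
        seed=seed,
        planted_warm_days=warm_days,
        planted_fires=fires,
        planted_outages=outages,
        outage_reporting=reporting,
        svi_values=_reference_svi_values(counties),
    )


def _contiguous_runs(days: Iterable[dt.date]) -> list[list[dt.date]]:
    runs: list[list[dt.date]] = []
    for d in sorted(days):
        if runs and (d - runs[-1][-1]).days == 1:
            runs[-1].append(d)
        else:
            runs.append([d])
    return runs
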