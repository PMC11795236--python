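# coclimate

County-day classification and co-occurrence analysis of compound
climate-driven events, built for the California 2018–2019 setting:
**anomalously warm days (AW)**, **wildfire burn zone disaster days
(WBZD)** and **long power outage days (PO)**, their co-occurrence on
the same county-day, and the relationship between per-county event
burdens and the CDC/ATSDR Social Vulnerability Index (SVI).

It is aimed at environmental epidemiologists and climate-health
researchers who need reproducible, unit-tested exposure calendars at
the county-day level, plus a synthetic-data generator with a known
ground truth so the whole pipeline can be exercised and verified
without any external data download.

## The classification rules

The unit of analysis is the *county-day*: one county on one calendar
date (58 California counties × 730 days of 2018–2019 = 42,340
county-days).

- **Anomalously warm (AW).** A county-day with daily mean temperature
  *T* is anomalously warm iff *T* ≥ *P*₈₅(county, week) **and**
  *T* > 24 °C, where *P*₈₅ is the 85th percentile (linear
  interpolation) of all baseline daily means (1981–2010) falling in the
  county's week-of-year bin (7-day day-of-year blocks, days 365/366
  merged into week 52). The relative condition captures seasonal
  anomaly; the absolute cutoff keeps unusually-mild winter days out.
- **Wildfire burn zone disaster (WBZD).** A fire qualifies iff it
  destroyed ≥ 1 structure, killed a civilian, or received a FEMA Fire
  Management Declaration, **and** its burn zone overlapped a community
  (population density ≥ 250 people/km²). Every county overlapped by a
  qualifying fire's footprint is flagged on every date from ignition
  through containment, inclusive.
- **Long power outage (PO).** Assessable only in counties whose outage
  feed reported ≥ 50 % of the time and covered ≥ 50 % of county
  customers. A qualifying episode is a maximal run of readings with
  customers-out > 0.5 % of county customers lasting ≥ 8 h (readings
  are interval-censored; a run's duration is right-extended by one
  reporting interval). Every calendar date intersected by an episode is
  flagged.
- **Co-occurrence.** Two or more events on the same county-day. The
  eight categories (none, AW, WBZD, PO, AW+WBZD, AW+PO, WBZD+PO,
  AW+WBZD+PO) partition the calendar; pair categories exclude the
  triple day.
- **SVI correlation.** For each category, Spearman's ρ (average ranks)
  between per-county event-day counts and SVI among *affected* counties
  (≥ 1 day of that category), plus county-day counts within the
  SVI > 0.75 and SVI < 0.25 strata.

## Worked example

```python
import pandas as pd
import coclimate as cc

cfg = cc.SimConfig(
    n_counties=3,
    baseline_years=(1981, 2010),
    study_years=(2018, 2019),
    seed=42,
    planted_warm_days=[("C01", "2018-08-10"), ("C02", "2019-07-04")],
    planted_fires=[
        cc.FireBlueprint("ferguson-like", "2018-07-13", "2018-08-19",
                         ("C01",), structures_destroyed=10),
    ],
    planted_outages=[
        cc.OutagePlant("C01", pd.Timestamp("2018-08-10 06:00"), 12.0, 0.02),
    ],
)
res = cc.simulate(cfg)

clim = cc.build_weekly_climatology(res.baseline)
aw = cc.classify_anomalously_warm(res.study, clim)
wbzd = cc.fire_county_days(res.fires)
reliable, _ = cc.assess_reliability(res.outages)
episodes = pd.concat(
    [cc.detect_episodes(s, reliable_counties=reliable) for s in res.outages],
    ignore_index=True,
)
po = cc.episodes_to_county_days(episodes)

calendar = cc.build_event_calendar(
    aw, wbzd, po, cfg.counties, "2018-01-01", "2019-12-31", reliable
)
summary = cc.tabulate(calendar, reliable_counties=reliable)
print("county-days:", summary.n_county_days)
print("warm days:", summary.marginal_day_counts["AW"])
print("burn zone disaster days:", summary.marginal_day_counts["WBZD"])
print("long outage days:", summary.marginal_day_counts["PO"])
print("co-occurring county-days:", summary.total_cooccurring_days)
```

prints

```
county-days: 2190
warm days: 2
burn zone disaster days: 38
long outage days: 1
co-occurring county-days: 1
```

Three counties over two years give 2,190 county-days. The planted fire
burns 2018-07-13 → 2018-08-19 (38 inclusive days, all in county C01);
both planted warm days are recovered; the 12-hour, 2 %-of-customers
outage on 2018-08-10 yields one PO day. That day — warm, burning and
dark in C01 — is the single triple-event county-day, so there is
exactly one co-occurring county-day.

The same steps are available from the shell:

```sh
coclimate simulate --preset california --out sim/
coclimate detect-warm --baseline sim/baseline.csv --study sim/study.csv --out aw.csv
coclimate detect-fire --fires sim/fires.csv --out wbzd.csv
coclimate detect-outage --series sim/outage_series.csv --meta sim/outage_meta.csv --out po.csv
coclimate cooccur --aw aw.csv --wbzd wbzd.csv --po po.csv \
    --meta sim/outage_meta.csv --svi sim/svi.csv --out summary.json
```

or in one shot with `coclimate run --config pipeline.yaml`.

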