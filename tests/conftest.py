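"""Shared fixtures and oracle helpers."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from coclimate.synthetic import (
    FireBlueprint,
    OutagePlant,
    ReportingMeta,
    SimConfig,
)

# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def percentile_oracle(values, q: float) -> float:
    """Sorted-order-statistic percentile with linear interpolation."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def average_ranks_oracle(values) -> list[float]:
    """Average ranks computed by explicit tie grouping."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def spearman_oracle(x, y) -> float:
    return pearson_oracle(average_ranks_oracle(list(x)), average_ranks_oracle(list(y)))


def maximal_runs_oracle(timestamps, exceed, interval_h: float, min_hours: float):
    """All-subintervals search for maximal qualifying exceedance runs.

    Returns (start, end_exclusive, duration_h) triples. A subinterval
    [i, j] qualifies when every reading exceeds, it cannot be extended
    (both neighbours missing-or-not-exceeding, where a timestamp gap of
    more than one interval counts as missing), and its right-extended
    duration reaches min_hours.
    """
    n = len(timestamps)
    step = dt.timedelta(hours=interval_h)
    out = []
    for i in range(n):
        for j in range(i, n):
            if not all(exceed[i : j + 1]):
                continue
            contiguous = all(
                timestamps[k + 1] - timestamps[k] <= step for k in range(i, j)
            )
            if not contiguous:
                continue
            left_ok = i == 0 or not exceed[i - 1] or timestamps[i] - timestamps[i - 1] > step
            right_ok = (
                j == n - 1 or not exceed[j + 1] or timestamps[j + 1] - timestamps[j] > step
            )
            if not (left_ok and right_ok):
                continue
            duration = (timestamps[j] + step - timestamps[i]) / dt.timedelta(hours=1)
            if duration >= min_hours:
                out.append((timestamps[i], timestamps[j] + step, duration))
    return out


# ---------------------------------------------------------------------------
# configuration builders
# ---------------------------------------------------------------------------


def random_planted_config(n_counties: int, seed: int, n_events: int = 20) -> SimConfig:
    """A randomized SimConfig with ~n_events planted items per type.

    Plants unique warm days, a mix of disaster and non-disaster fires,
    and outage episodes both qualifying and sub-threshold; two counties
    get unreliable feeds so reliability filtering is exercised.
    """
    rng = np.random.default_rng(seed)
    counties = [f"C{i:02d}" for i in range(1, n_counties + 1)]
    study = pd.date_range("2018-01-01", "2019-12-30", freq="D")

    pairs = set()
    while len(pairs) < n_events:
        pairs.add(
            (
                counties[rng.integers(0, n_counties)],
                study[rng.integers(0, len(study))].date(),
            )
        )
    warm = sorted(pairs)

    fires = []
    for k in range(max(4, n_events // 3)):
        start = study[rng.integers(0, len(study) - 12)].date()
        span = int(rng.integers(0, 10))
        n_c = int(rng.integers(1, min(3, n_counties) + 1))
        chosen = tuple(
            counties[i] for i in rng.choice(n_counties, size=n_c, replace=False)
        )
        kind = k % 4
        fires.append(
            FireBlueprint(
                fire_id=f"fire-{k}",
                ignition=start,
                containment=start + dt.timedelta(days=span),
                counties=chosen,
                structures_destroyed=int(rng.integers(1, 5)) if kind != 1 else 0,
                civilian_deaths=1 if kind == 2 else 0,
                fema_fmd=kind == 3,
                community_overlap=kind != 0,  # kind 0: severity but no community
            )
        )

    outages = []
    used_days: dict[str, set] = {c: set() for c in counties}
    n_out = 0
    while n_out < n_events:
        county = counties[rng.integers(0, n_counties)]
        day = study[rng.integers(0, len(study))].date()
        near = {day + dt.timedelta(days=o) for o in (-1, 0, 1)}
        if near & used_days[county]:
            continue
        used_days[county].add(day)
        qualifying = rng.random() < 0.7
        duration = float(rng.integers(8, 16)) if qualifying else float(rng.integers(2, 8))
        fraction = float(rng.uniform(0.006, 0.03)) if rng.random() < 0.85 else 0.004
        start_ts = pd.Timestamp(day) + pd.Timedelta(hours=int(rng.integers(0, 8)))
        outages.append(OutagePlant(county, start_ts, duration, fraction))
        n_out += 1

    reporting = {c: ReportingMeta(1.0, 1.0) for c in counties}
    if n_counties >= 3:
        reporting[counties[-1]] = ReportingMeta(0.3, 1.0)
        reporting[counties[-2]] = ReportingMeta(0.9, 0.45)

    return SimConfig(
        n_counties=n_counties,
        baseline_years=(1981, 2010),
        study_years=(2018, 2019),
        seed=seed,
        planted_warm_days=warm,
        planted_fires=fires,
        planted_outages=outages,
        outage_reporting=reporting,
    )


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """3 counties, short baseline, a handful of planted events."""
    return SimConfig(
        n_counties=3,
        baseline_years=(1981, 1986),
        study_years=(2018, 2019),
        seed=7,
        planted_warm_days=[
            ("C01", dt.date(2018, 8, 10)),
            ("C02", dt.date(2019, 1, 5)),
            ("C02", dt.date(2019, 7, 1)),
        ],
        planted_fires=[
            FireBlueprint(
                "tiny-f0",
                dt.date(2018, 8, 9),
                dt.date(2018, 8, 12),
                ("C01",),
                structures_destroyed=2,
            ),
            FireBlueprint(
                "tiny-f1",
                dt.date(2019, 6, 1),
                dt.date(2019, 6, 3),
                ("C02", "C03"),
                fema_fmd=True,
            ),
        ],
        planted_outages=[
            OutagePlant("C03", pd.Timestamp("2019-10-09 00:00"), 10.0, 0.01),
            OutagePlant("C01", pd.Timestamp("2018-08-10 12:00"), 9.0, 0.02),
        ],
    )


@pytest.fixture(scope="session")
def tiny_result(tiny_config):
    from coclimate.synthetic import simulate

    return simulate(tiny_config)
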