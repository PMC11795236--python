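"""Synthetic-data generator: determinism, leakage, ledger recovery."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import coclimate as cc
from coclimate.outage import empty_episodes
from coclimate.synthetic import (
    FireBlueprint,
    OutagePlant,
    ReportingMeta,
    SimConfig,
    SimulationError,
    TruthLedger,
    build_truth_ledger,
    flags_to_day_set,
    generate_svi,
    generate_temperatures,
    simulate,
)
from conftest import random_planted_config


def run_detectors(result):
    """Full detector pass over a SimResult; returns the recovered sets."""
    clim = cc.build_weekly_climatology(result.baseline)
    aw = cc.classify_anomalously_warm(result.study, clim)
    wb = cc.fire_county_days(result.fires)
    reliable, _ = cc.assess_reliability(result.outages)
    frames = [
        cc.detect_episodes(s, reliable_counties=reliable)
        for s in result.outages
        if s.county in reliable
    ]
    frames = [f for f in frames if not f.empty]
    episodes = pd.concat(frames, ignore_index=True) if frames else empty_episodes()
    po = cc.episodes_to_county_days(episodes)
    return {
        "warm": flags_to_day_set(aw),
        "wbzd": flags_to_day_set(wb),
        "po": flags_to_day_set(po),
        "reliable": reliable,
    }


class TestConfigValidation:
    def test_overlapping_year_ranges_rejected(self):
        with pytest.raises(SimulationError, match="overlap"):
            SimConfig(n_counties=2, baseline_years=(1990, 2019), study_years=(2018, 2019))

    def test_planted_event_outside_study_rejected(self):
        with pytest.raises(SimulationError, match="outside study"):
            SimConfig(n_counties=2, planted_warm_days=[("C01", dt.date(2016, 7, 1))])

    def test_containment_before_ignition_rejected(self):
        with pytest.raises(SimulationError, match="containment"):
            FireBlueprint("x", dt.date(2018, 8, 10), dt.date(2018, 8, 9), ("C01",))

    def test_nonpositive_outage_fraction_rejected(self):
        with pytest.raises(SimulationError, match="fraction"):
            OutagePlant("C01", pd.Timestamp("2018-06-01"), 9.0, 0.0)

    def test_abutting_outage_plants_rejected(self):
        with pytest.raises(SimulationError, match="abut"):
            SimConfig(
                n_counties=1,
                planted_outages=[
                    OutagePlant("C01", pd.Timestamp("2018-06-01 00:00"), 9.0, 0.01),
                    OutagePlant("C01", pd.Timestamp("2018-06-01 09:00"), 9.0, 0.01),
                ],
            )

    def test_reporting_fraction_out_of_range_rejected(self):
        with pytest.raises(SimulationError):
            ReportingMeta(reporting_fraction=1.5)

    def test_unknown_svi_mode_rejected(self):
        with pytest.raises(SimulationError, match="svi_mode"):
            SimConfig(n_counties=2, svi_mode="sideways")

    def test_roundtrip_through_dict(self, tiny_config):
        clone = SimConfig.from_dict(tiny_config.to_dict())
        assert clone.to_dict() == tiny_config.to_dict()

    def test_unknown_key_rejected(self):
        with pytest.raises(SimulationError, match="unknown"):
            SimConfig.from_dict({"n_counties": 2, "n_countys": 3})


class TestDeterminism:
    def test_identical_config_identical_outputs(self, tiny_config):
        a = simulate(tiny_config)
        b = simulate(SimConfig.from_dict(tiny_config.to_dict()))
        pd.testing.assert_frame_equal(a.baseline, b.baseline)
        pd.testing.assert_frame_equal(a.study, b.study)
        pd.testing.assert_frame_equal(a.svi, b.svi)
        assert a.ledger.to_json() == b.ledger.to_json()
        for sa, sb in zip(a.outages, b.outages):
            pd.testing.assert_frame_equal(sa.records, sb.records)

    def test_different_seed_different_noise(self, tiny_config):
        other = SimConfig.from_dict({**tiny_config.to_dict(), "seed": 8})
        a, _ = generate_temperatures(tiny_config)
        b, _ = generate_temperatures(other)
        assert not np.allclose(a["tmean_c"], b["tmean_c"])


class TestNoLeakage:
    def test_zero_planted_events_all_detectors_empty(self):
        cfg = SimConfig(
            n_counties=4,
            baseline_years=(1981, 1990),
            study_years=(2018, 2019),
            seed=3,
            include_decoys=True,  # decoys must not leak either
        )
        res = simulate(cfg)
        got = run_detectors(res)
        assert got["warm"] == set()
        assert got["wbzd"] == set()
        assert got["po"] == set()
        assert res.ledger.warm_days == set()


class TestTemperatureGuarantees:
    def test_cool_config_never_crosses_cutoff(self):
        cfg = SimConfig(
            n_counties=1,
            baseline_years=(1981, 1983),
            study_years=(2018, 2019),
            default_climate=cc.synthetic.CountyClimate(10.0, 5.0, 0.0),
        )
        _, study = generate_temperatures(cfg)
        assert (study["tmean_c"] <= 15.0 + 1e-9).all()

    def test_planted_day_exceeds_both_thresholds(self, tiny_result):
        clim = cc.build_weekly_climatology(tiny_result.baseline)
        study = tiny_result.study.set_index(["county", "date"])
        v = study.loc[("C01", pd.Timestamp("2018-08-10")), "tmean_c"]
        week = cc.week_of_year(pd.DatetimeIndex([pd.Timestamp("2018-08-10")]))[0]
        p85 = clim.set_index(["county", "week"]).loc[("C01", week), "p85_c"]
        assert v > 24.0 and v > p85

    def test_impossible_margin_reports_county_day(self):
        cfg_dict = SimConfig(
            n_counties=1,
            baseline_years=(1981, 1983),
            planted_warm_days=[("C01", dt.date(2018, 7, 15))],
        ).to_dict()
        cfg_dict["tmean_max_c"] = 25.0  # margin pushes past the bound
        with pytest.raises(SimulationError, match="C01"):
            generate_temperatures(SimConfig.from_dict(cfg_dict))


class TestLedgerRecovery:
    @pytest.mark.parametrize("n_counties, seed", [(3, 7), (5, 11), (8, 13)])
    def test_detectors_recover_ledger_exactly(self, n_counties, seed):
        cfg = random_planted_config(n_counties, seed)
        res = simulate(cfg)
        got = run_detectors(res)
        assert got["warm"] == res.ledger.warm_days
        assert got["wbzd"] == res.ledger.wbzd_days
        assert got["po"] == res.ledger.po_days
        assert got["reliable"] == res.ledger.reliable_counties

    def test_ledger_roundtrip_json(self, tiny_result):
        clone = TruthLedger.from_json(tiny_result.ledger.to_json())
        assert clone == tiny_result.ledger

    def test_decoy_outages_below_threshold(self, tiny_result):
        # decoys appear in the traces but never in the ledger
        ledger = tiny_result.ledger
        assert len(ledger.po_days) == 2  # the two planted qualifying episodes
        assert ledger.disaster_fires == {"tiny-f0", "tiny-f1"}


class TestGenerateSvi:
    def _cfg(self, mode, jitter=0.0):
        # distinct per-county warm-day counts 1..5
        warm = []
        for i in range(1, 6):
            for k in range(i):
                warm.append((f"C{i:02d}", dt.date(2018, 3 + k, 1)))
        return SimConfig(
            n_counties=5,
            planted_warm_days=warm,
            svi_mode=mode,
            svi_jitter=jitter,
            svi_event_source="AW",
        )

    def test_increasing_mode_rank_matches_counts(self):
        cfg = self._cfg("increasing-with-events")
        ledger = build_truth_ledger(cfg)
        table = generate_svi(cfg, ledger)
        counts = [
            sum(1 for c, _ in ledger.warm_days if c == county)
            for county in cfg.counties
        ]
        assert cc.spearman_rho(counts, table["svi"].to_numpy()) == pytest.approx(1.0)

    def test_decreasing_mode_gives_minus_one(self):
        cfg = self._cfg("decreasing-with-events")
        ledger = build_truth_ledger(cfg)
        table = generate_svi(cfg, ledger)
        counts = [
            sum(1 for c, _ in ledger.warm_days if c == county)
            for county in cfg.counties
        ]
        assert cc.spearman_rho(counts, table["svi"].to_numpy()) == pytest.approx(-1.0)

    def test_independent_mode_in_range_and_seeded(self):
        cfg = self._cfg("independent")
        ledger = build_truth_ledger(cfg)
        a = generate_svi(cfg, ledger)
        b = generate_svi(cfg, ledger)
        pd.testing.assert_frame_equal(a, b)
        assert a["svi"].between(0, 1).all()

    def test_explicit_values_override(self):
        cfg = self._cfg("independent")
        cfg.svi_values = {c: 0.5 for c in cfg.counties}
        table = generate_svi(cfg, build_truth_ledger(cfg))
        assert (table["svi"] == 0.5).all()
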