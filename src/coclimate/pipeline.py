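"""End-to-end pipeline orchestration with a single configuration object.

``PipelineConfig`` houses every numeric constant of the analysis in one
place — the 85th temperature percentile and 24 degC cutoff, the 250
people/km^2 community density, the 0.5% / 8 h outage rule, the 50%/50%
reliability filters, and the 0.75/0.25 SVI quartile bounds — plus all
design-decision toggles. ``run_pipeline`` executes climatology ->
wildfire -> outage -> co-occurrence -> SVI in order, writes every
intermediate artifact, and returns a manifest with row counts and
checksums so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from coclimate import climatology, cooccurrence, io, outage, svi, wildfire

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("coclimate")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for a full pipeline run."""

    # inputs
    baseline_csv: str
    study_csv: str
    fires_csv: str
    outage_series_csv: str
    outage_meta_csv: str
    svi_csv: str
    out_dir: str
    study_start: str = "2018-01-01"
    study_end: str = "2019-12-31"
    footprints_geojson: str | None = None
    counties_geojson: str | None = None
    density_geojson: str | None = None
    # thresholds (analysis constants)
    percentile: float = 85.0
    absolute_cutoff_c: float = 24.0
    density_threshold: float = 250.0
    outage_pct_threshold: float = 0.005
    outage_min_hours: float = 8.0
    min_reporting: float = 0.5
    min_coverage: float = 0.5
    svi_hi: float = 0.75
    svi_lo: float = 0.25
    # toggles
    percentile_method: str = "linear"
    use_weekly_means: bool = False
    gap_tolerance: int = 0
    sample_resolution: int = 200
    subset_affected: bool = True

    def __post_init__(self) -> None:
        checks = [
            (0 < self.percentile <= 100, "percentile in (0, 100]"),
            (self.density_threshold >= 0, "density_threshold >= 0"),
            (0 <= self.outage_pct_threshold < 1, "outage_pct_threshold in [0, 1)"),
            (self.outage_min_hours > 0, "outage_min_hours > 0"),
            (0 <= self.min_reporting <= 1, "min_reporting in [0, 1]"),
            (0 <= self.min_coverage <= 1, "min_coverage in [0, 1]"),
            (0 <= self.svi_lo <= self.svi_hi <= 1, "svi bounds ordered in [0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid PipelineConfig: require {msg}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: pipeline config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage {name}: {e}") from e
            log.info("stage %s: done", name)
            return result

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write artifacts under ``out_dir``, return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    counts: dict[str, int] = {}

    @_stage("climatology")
    def stage_climatology():
        baseline = io.read_temperature_csv(config.baseline_csv)
        study = io.read_temperature_csv(config.study_csv)
        clim = climatology.build_weekly_climatology(
            baseline,
            percentile=config.percentile,
            method=config.percentile_method,
            use_weekly_means=config.use_weekly_means,
        )
        aw = climatology.classify_anomalously_warm(
            study, clim, absolute_cutoff=config.absolute_cutoff_c
        )
        clim.to_csv(out / "climatology.csv", index=False)
        io.write_flags_csv(aw, out / "aw_flags.csv")
        artifacts["climatology"] = out / "climatology.csv"
        artifacts["aw_flags"] = out / "aw_flags.csv"
        counts["aw_flags"] = len(aw)
        return aw

    @_stage("wildfire")
    def stage_wildfire():
        footprints = (
            io.read_geometries_geojson(config.footprints_geojson)
            if config.footprints_geojson
            else None
        )
        fires = io.read_fires_csv(config.fires_csv, footprints=footprints)
        county_geoms = (
            io.read_geometries_geojson(config.counties_geojson)
            if config.counties_geojson
            else None
        )
        grid = (
            io.read_density_grid_geojson(config.density_geojson)
            if config.density_geojson
            else None
        )
        wbzd = wildfire.fire_county_days(
            fires,
            county_geometries=county_geoms,
            grid=grid,
            density_threshold=config.density_threshold,
            sample_resolution=config.sample_resolution,
        )
        io.write_flags_csv(wbzd, out / "wbzd_flags.csv")
        artifacts["wbzd_flags"] = out / "wbzd_flags.csv"
        counts["wbzd_flags"] = len(wbzd)
        counts["multi_fire_days"] = wildfire.count_multi_fire_days(wbzd)
        return wbzd

    @_stage("outage")
    def stage_outage():
        series = io.read_outage_series_csv(
            config.outage_series_csv, config.outage_meta_csv
        )
        reliable, excluded = outage.assess_reliability(
            series,
            min_reporting=config.min_reporting,
            min_coverage=config.min_coverage,
        )
        episodes = [
            outage.detect_episodes(
                s,
                pct_threshold=config.outage_pct_threshold,
                min_hours=config.outage_min_hours,
                gap_tolerance=config.gap_tolerance,
                reliable_counties=reliable,
            )
            for s in series
            if s.county in reliable
        ]
        episodes = (
            pd.concat(episodes, ignore_index=True)
            if episodes
            else outage.empty_episodes()
        )
        po = outage.episodes_to_county_days(episodes)
        episodes.to_csv(out / "episodes.csv", index=False)
        io.write_flags_csv(po, out / "po_flags.csv")
        (out / "reliability.json").write_text(
            json.dumps(
                {"reliable": sorted(reliable), "excluded": excluded}, indent=2
            )
        )
        artifacts["episodes"] = out / "episodes.csv"
        artifacts["po_flags"] = out / "po_flags.csv"
        artifacts["reliability"] = out / "reliability.json"
        counts["episodes"] = len(episodes)
        counts["po_flags"] = len(po)
        counts["reliable_counties"] = len(reliable)
        return po, reliable

    @_stage("cooccurrence")
    def stage_cooccurrence(aw, wbzd, po, reliable, roster):
        calendar = cooccurrence.build_event_calendar(
            aw,
            wbzd,
            po,
            counties=roster,
            study_start=config.study_start,
            study_end=config.study_end,
            reliable_counties=reliable,
        )
        summary = cooccurrence.tabulate(calendar, reliable_counties=reliable)
        cal_out = calendar.copy()
        cal_out["date"] = cal_out["date"].dt.strftime("%Y-%m-%d")
        cal_out.to_csv(out / "calendar.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
        artifacts["calendar"] = out / "calendar.csv"
        artifacts["summary"] = out / "summary.json"
        counts["calendar"] = len(calendar)
        counts["total_cooccurring_days"] = summary.total_cooccurring_days
        return calendar, summary

    @_stage("svi")
    def stage_svi(calendar, summary, svi_table):
        corr = svi.correlate_events_svi(
            summary, svi_table, subset_affected=config.subset_affected
        )
        quart = svi.quartile_summary(
            calendar, svi_table, hi=config.svi_hi, lo=config.svi_lo
        )
        corr.to_csv(out / "correlations.csv", index=False)
        (out / "quartiles.json").write_text(json.dumps(quart.to_dict(), indent=2))
        artifacts["correlations"] = out / "correlations.csv"
        artifacts["quartiles"] = out / "quartiles.json"
        counts["correlations"] = len(corr)

    aw = stage_climatology()
    wbzd = stage_wildfire()
    po, reliable = stage_outage()
    svi_table = io.read_svi_csv(config.svi_csv)
    roster = list(svi_table["county"])
    calendar, summary = stage_cooccurrence(aw, wbzd, po, reliable, roster)
    stage_svi(calendar, summary, svi_table)

    manifest = {
        "row_counts": counts,
        "artifacts": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
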