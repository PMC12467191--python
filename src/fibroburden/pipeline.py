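"""End-to-end pipeline: simulate/load -> validate -> trends -> inequality -> frontier.

A single :class:`RunConfig` (YAML or JSON file, or built in code) drives the
whole analysis. Every run writes its outputs plus a ``manifest.json``
recording the config hash, seed, per-stage status and SHA-256 checksums of
every output file — identical config + seed therefore yields identical
checksums, which is the pipeline's determinism contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import frontier as frontier_mod
from . import gbd_io, inequality, synthetic, trends

__all__ = [
    "PipelineError",
    "ConfigError",
    "RunConfig",
    "validate_config",
    "load_panel_dir",
    "run_pipeline",
]

log = logging.getLogger("fibroburden")

STAGES = ("simulate", "validate", "trends", "inequality", "frontier")


class PipelineError(RuntimeError):
    """A pipeline stage failed; see the manifest for which."""


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Parameterization of a full pipeline run.

    Exactly one input mode is active: ``synthetic`` (a
    :class:`~fibroburden.synthetic.PanelSpec`) or ``csv`` (paths to burden,
    SDI and population tables, optionally a pre-aggregated group-rate table).
    """

    mode: str = "synthetic"
    panel_spec: synthetic.PanelSpec | None = None
    input_files: dict[str, str] | None = None
    causes: list[str] | None = None
    years: tuple[int, int] | None = None
    measure: str = "dalys"
    stages: dict[str, bool] = field(default_factory=lambda: {
        "trends": True, "inequality": True, "frontier": True})
    inequality_method: str = "wls"
    n_bootstrap: int = 200
    frontier_bins: int = 100
    frontier_bandwidth: float = 0.3
    frontier_year: int | None = None
    top_k: int = 15
    out_dir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "csv"):
            raise ConfigError(f"unknown input mode {self.mode!r}")
        if self.mode == "csv":
            if self.panel_spec is not None:
                raise ConfigError("panel_spec given but mode is 'csv': exactly one input mode")
            if not self.input_files:
                raise ConfigError("csv mode requires input_files")
            full = all(k in self.input_files for k in ("burden", "sdi", "population"))
            if not full and "group_rates" not in self.input_files:
                raise ConfigError(
                    "csv mode needs burden+sdi+population files, or at least a "
                    "group_rates table for a trends-only run")
            out = Path(self.out_dir).resolve()
            for p in self.input_files.values():
                if Path(p).resolve().parent == out:
                    raise ConfigError("output directory must differ from the input directory")
        else:
            if self.input_files is not None:
                raise ConfigError("input_files given but mode is 'synthetic': exactly one input mode")
        if not self.out_dir:
            raise ConfigError("out_dir is required")
        if self.n_bootstrap < 0:
            raise ConfigError("n_bootstrap must be >= 0")


_KNOWN_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(path: str | Path) -> RunConfig:
    """Parse and invariant-check a YAML/JSON config file; fill defaults."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "panel_spec" in raw and raw["panel_spec"] is not None:
        spec_raw = dict(raw["panel_spec"])
        known_spec = {f.name for f in dataclasses.fields(synthetic.PanelSpec)}
        bad = set(spec_raw) - known_spec
        if bad:
            raise ConfigError(f"unknown panel_spec key(s): {sorted(bad)}")
        for key in ("years", "sdi_start_range", "sdi_growth_range",
                    "population_lognormal"):
            if key in spec_raw and spec_raw[key] is not None:
                spec_raw[key] = tuple(spec_raw[key])
        raw["panel_spec"] = synthetic.PanelSpec(**spec_raw)
    if "years" in raw and raw["years"] is not None:
        raw["years"] = tuple(raw["years"])
    if "stages" in raw and raw["stages"] is not None:
        bad = set(raw["stages"]) - {"trends", "inequality", "frontier"}
        if bad:
            raise ConfigError(f"unknown stage toggle(s): {sorted(bad)}")
        stages = {"trends": True, "inequality": True, "frontier": True}
        stages.update(raw["stages"])
        raw["stages"] = stages
    config = RunConfig(**raw)
    config.validate()
    for f in dataclasses.fields(RunConfig):
        log.debug("config %s = %r", f.name, getattr(config, f.name))
    return config


def load_panel_dir(directory: str | Path) -> gbd_io.Panel:
    """Load a panel from a directory of burden/sdi/population CSVs.

    Picks up an optional ``group_rates.csv`` of pre-aggregated SDI-group rows.
    """
    directory = Path(directory)
    panel = gbd_io.assemble_panel(
        gbd_io.read_burden_csv(directory / "burden.csv"),
        gbd_io.read_sdi_csv(directory / "sdi.csv"),
        gbd_io.read_population_csv(directory / "population.csv"),
    )
    groups = directory / "group_rates.csv"
    if groups.exists():
        panel.group_rates = gbd_io.read_burden_csv(groups)
    return panel


def _config_hash(config: RunConfig) -> str:
    def _default(obj: Any):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, tuple):
            return list(obj)
        return str(obj)
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=_default)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all requested stages; return (and write) the run manifest.

    Any stage error marks that stage failed in the manifest (still written)
    and raises :class:`PipelineError`.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "checksums": {},
    }
    outputs: list[Path] = []
    panel: gbd_io.Panel | None = None
    truth: synthetic.PanelTruth | None = None
    group_rates: pd.DataFrame | None = None

    def _stage(name: str, enabled: bool, fn) -> None:
        if not enabled:
            manifest["stages"][name] = {"status": "skipped"}
            return
        t0 = time.perf_counter()
        try:
            produced = fn() or []
            manifest["stages"][name] = {
                "status": "ok",
                "outputs": [str(p.relative_to(out_dir)) for p in produced],
                "seconds": round(time.perf_counter() - t0, 3),
            }
            outputs.extend(produced)
            log.info("stage %-10s ok (%.2fs)", name, time.perf_counter() - t0)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out_dir, outputs)
            log.error("stage %s failed: %s", name, exc)
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    def do_simulate() -> list[Path]:
        nonlocal panel, truth
        if config.mode == "synthetic":
            spec = config.panel_spec or synthetic.PanelSpec(seed=config.seed)
            if config.panel_spec is None:
                spec = dataclasses.replace(spec, seed=config.seed)
            panel, truth = synthetic.generate_panel(spec)
            paths = list(synthetic.write_panel_csvs(panel, out_dir / "panel").values())
            gpath = synthetic.write_group_rates_csv(panel, out_dir / "panel")
            if gpath is not None:
                paths.append(gpath)
            paths.append(synthetic.write_truth_json(truth, out_dir / "panel" / "truth.json"))
            return paths
        files = config.input_files
        if all(k in files for k in ("burden", "sdi", "population")):
            panel = gbd_io.assemble_panel(
                gbd_io.read_burden_csv(files["burden"]),
                gbd_io.read_sdi_csv(files["sdi"]),
                gbd_io.read_population_csv(files["population"]),
            )
        else:  # group-rate table alone: trends-only run
            panel = None
        if "group_rates" in files:
            nonlocal group_rates
            group_rates = gbd_io.read_burden_csv(files["group_rates"])
            if panel is not None:
                panel.group_rates = group_rates
        return []

    def do_validate() -> list[Path]:
        if panel is None:
            log.info("trends-only run: %d group-rate rows, no country panel",
                     0 if group_rates is None else len(group_rates))
            return []
        report = pd.DataFrame(panel.missing, columns=["location", "year"])
        path = out_dir / "completeness.csv"
        report.to_csv(path, index=False)
        log.info("panel: %d locations, %d years, %d causes, %d incomplete pairs",
                 len(panel.locations), len(panel.years), len(panel.causes),
                 len(panel.missing))
        return [path]

    def do_trends() -> list[Path]:
        produced = []
        if panel is not None:
            causes = config.causes or panel.causes
            has_numbers = not panel.burden[panel.burden["metric"] == "number"].empty
            if has_numbers:
                props = trends.proportion_timeseries(panel, causes, config.measure)
                p = out_dir / "proportions.csv"
                props.to_csv(p, index=False)
                produced.append(p)
        rates = group_rates if panel is None else panel.group_rates
        if rates is not None and not rates.empty:
            causes = config.causes or sorted(set(rates["cause"]))
            if config.years is not None:
                years = config.years
            else:
                yrs = sorted(rates["year"].unique())
                years = (int(yrs[0]), int(yrs[-1]))
            groups = [g for g in synthetic.SDI_GROUPS if g in set(rates["location"])]
            table = trends.summary_table(rates, causes, groups, years=years)
            p = out_dir / "summary_table.csv"
            table.to_csv(p, index=False)
            produced.append(p)
        if not produced:
            raise trends.TrendsError(
                "trends stage needs number records or a group-rate table")
        return produced

    def do_inequality() -> list[Path]:
        if panel is None:
            raise PipelineError("inequality stage needs a country panel")
        causes = config.causes or panel.causes
        frames = []
        years = list(range(config.years[0], config.years[1] + 1)) if config.years else None
        for cause in causes:
            ts = inequality.inequality_timeseries(
                panel, cause, config.measure, years=years,
                method=config.inequality_method,
                n_bootstrap=config.n_bootstrap, seed=config.seed)
            ts.insert(0, "cause", cause)
            frames.append(ts)
        path = out_dir / "inequality.csv"
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)
        return [path]

    def do_frontier() -> list[Path]:
        if panel is None:
            raise PipelineError("frontier stage needs a country panel")
        causes = config.causes or panel.causes
        year = config.frontier_year or panel.years[-1]
        curve_rows, gap_frames, top_frames = [], [], []
        for cause in causes:
            pieces = []
            for yr in panel.years:
                s = gbd_io.slice_panel(panel, yr, cause, config.measure,
                                       "rate", "age_standardized")
                s = s.rename(columns={"value": "asr"})
                s.insert(1, "year", yr)
                pieces.append(s)
            cloud = pd.concat(pieces, ignore_index=True)
            curve = frontier_mod.fit_frontier(
                cloud["sdi"].to_numpy(), cloud["asr"].to_numpy(),
                n_bins=config.frontier_bins, bandwidth=config.frontier_bandwidth)
            gaps = frontier_mod.effective_differences(curve, cloud)
            gaps.insert(0, "cause", cause)
            direction = frontier_mod.trend_directions(
                cloud, panel.years[0], panel.years[-1])
            gaps["trend_direction"] = gaps["location"].map(direction)
            gap_frames.append(gaps[gaps["year"] == year])
            top = frontier_mod.rank_deviators(gaps, year, k=config.top_k)["top"]
            top_frames.append(top)
            curve_rows.append(pd.DataFrame({
                "cause": cause, "sdi": curve.grid, "frontier_asr": curve.values}))
        paths = []
        for name, frames in (("frontier.csv", curve_rows), ("gaps.csv", gap_frames),
                             ("top_deviators.csv", top_frames)):
            p = out_dir / name
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            paths.append(p)
        return paths

    _stage("simulate", True, do_simulate)
    _stage("validate", True, do_validate)
    _stage("trends", config.stages.get("trends", True), do_trends)
    _stage("inequality", config.stages.get("inequality", True), do_inequality)
    _stage("frontier", config.stages.get("frontier", True), do_frontier)

    _write_manifest(manifest, out_dir, outputs)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path, outputs: list[Path]) -> None:
    manifest["checksums"] = {
        str(p.relative_to(out_dir)): _sha256(p) for p in outputs if p.exists()
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
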