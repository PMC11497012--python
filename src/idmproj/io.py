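"""Readers, writers and pipeline orchestration.

The input dialect is the GHDx results CSV as exported by the GBD query
tool: columns ``measure, location, sex, age, cause, metric, year, val,
upper, lower`` (header case-insensitive), one row per cell. Only
``metric == "Rate"`` rows in the age-standardized stratum are ingested;
deaths are split into cause-specific and all-cause by the ``cause``
column. Synthetic panels are written in the same dialect so they are
drop-in replacements for real extracts.

``run_pipeline`` drives the whole analysis from one YAML/dict config:
load or generate a panel, calibrate, project with intervals, derive the
trend analytics, and write every result table plus a run manifest. All
randomness descends from the single ``seed`` config field, so rerunning
a config yields byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytics import lollipop_long, region_panel
from .calibration import EpiSeries
from .errors import ConfigurationError, CoverageError, SchemaError
from .estimator import IllnessDeathForecaster
from .idm import TransitionSchedule
from .projection import ProjectionTable
from .synthetic import GeneratorConfig, SyntheticTruth, make_truth, observe

logger = logging.getLogger(__name__)

__all__ = [
    "read_ghdx_csv",
    "write_ghdx_csv",
    "write_projection_table",
    "read_projection_long",
    "write_schedule_csv",
    "read_schedule_csv",
    "run_pipeline",
    "RunResult",
]

_GHDX_COLUMNS = ["measure", "location", "sex", "age", "cause", "metric", "year", "val", "upper", "lower"]

_DEFAULT_MEASURE_MAP = {"prevalence": "prevalence", "incidence": "incidence", "deaths": "deaths"}

_SEX_ALIASES = {"male": "male", "female": "female", "both": "both", "both sexes": "both"}


def read_ghdx_csv(
    path: str | Path,
    measure_map: Mapping[str, str] | None = None,
    age_group: str = "Age-standardized",
    all_causes_label: str = "All causes",
) -> EpiSeries:
    """Read a GHDx-dialect CSV extract into a validated panel.

    Rows failing the metric/age filters are dropped (counts logged);
    ``Deaths`` rows are assigned to ``deaths_all`` when ``cause`` equals
    ``all_causes_label`` and to ``deaths_cause`` otherwise. Completeness
    per (location, sex) key is enforced by :class:`EpiSeries`.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _GHDX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing GHDx columns {missing}")
    n_total = len(df)
    df = df[df["metric"].str.strip().str.lower() == "rate"]
    df = df[df["age"].str.strip().str.lower() == age_group.strip().lower()]
    logger.info("%s: kept %d of %d rows after metric/age filters", path.name, len(df), n_total)
    if df.empty:
        raise CoverageError(f"{path}: no '{age_group}' Rate rows to ingest")

    mmap = {k.lower(): v for k, v in (measure_map or _DEFAULT_MEASURE_MAP).items()}
    ghdx_measure = df["measure"].str.strip().str.lower().map(mmap)
    unknown = df.loc[ghdx_measure.isna(), "measure"].unique()
    if unknown.size:
        logger.info("%s: dropping unmapped measures %s", path.name, sorted(unknown))
    df = df[ghdx_measure.notna()].copy()
    mapped = ghdx_measure.dropna()
    is_all_cause = df["cause"].str.strip().str.lower() == all_causes_label.strip().lower()
    df["measure"] = np.where(
        mapped == "deaths", np.where(is_all_cause, "deaths_all", "deaths_cause"), mapped
    )
    sex = df["sex"].str.strip().str.lower().map(_SEX_ALIASES)
    if sex.isna().any():
        raise SchemaError(f"{path}: unknown sex labels {sorted(df.loc[sex.isna(), 'sex'].unique())}")
    df["sex"] = sex
    out = df.rename(columns={"val": "value"})[
        ["location", "sex", "measure", "year", "value", "lower", "upper"]
    ]
    return EpiSeries(out)


_GHDX_MEASURE_NAMES = {
    "prevalence": "Prevalence",
    "incidence": "Incidence",
    "deaths_cause": "Deaths",
    "deaths_all": "Deaths",
}


def write_ghdx_csv(
    series: EpiSeries,
    path: str | Path,
    cause: str = "Pancreatic cancer",
    age_group: str = "Age-standardized",
) -> Path:
    """Write a panel in the GHDx results dialect (inverse of the reader)."""
    path = Path(path)
    df = series.frame
    out = pd.DataFrame(
        {
            "measure": df["measure"].map(_GHDX_MEASURE_NAMES),
            "location": df["location"],
            "sex": df["sex"].str.capitalize().replace({"Both": "Both sexes"}),
            "age": age_group,
            "cause": np.where(df["measure"] == "deaths_all", "All causes", cause),
            "metric": "Rate",
            "year": df["year"],
            "val": df["value"],
            "upper": df["upper"],
            "lower": df["lower"],
        }
    )
    out.to_csv(path, index=False)
    return path


def write_projection_table(
    tables: ProjectionTable | list[ProjectionTable],
    path: str | Path,
    layout: str = "long",
) -> Path:
    """Write projection tables as CSV in ``long`` or ``table1`` layout.

    Long: tidy rows (location, sex, year-or-period, estimate, lower,
    upper). table1: one row per (location, sex) with 5-year snapshot
    columns and the two period-change columns.
    """
    if isinstance(tables, ProjectionTable):
        tables = [tables]
    path = Path(path)
    if layout == "long":
        frame = (
            pd.concat([t.to_frame() for t in tables], ignore_index=True)
            if tables
            else pd.DataFrame(columns=["location", "sex", "year", "estimate", "lower", "upper"])
        )
    elif layout == "table1":
        frame = (
            pd.concat([t.snapshot_frame() for t in tables], ignore_index=True)
            if tables
            else pd.DataFrame(columns=["location", "sex"])
        )
    else:
        raise ValueError("layout must be 'long' or 'table1'")
    frame.to_csv(path, index=False)
    return path


def read_projection_long(path: str | Path) -> pd.DataFrame:
    """Read back a long-layout projection CSV (inverse of the writer).

    Year rows keep integer years; period rows keep their ``YYYY-YYYY``
    labels, matching the frame the writer was given.
    """
    df = pd.read_csv(path, dtype={"year": str}, float_precision="round_trip")
    df["year"] = [int(y) if y.isdigit() else y for y in df["year"]]
    df["year"] = df["year"].astype(object)
    return df


def write_schedule_csv(
    schedules: Mapping[tuple[str, str], TransitionSchedule], path: str | Path
) -> Path:
    """Write calibrated schedules: columns location, sex, year, i, m_S, m_I."""
    frames = []
    for (loc, sex), sched in schedules.items():
        f = sched.to_frame()
        f.insert(0, "location", loc)
        f.insert(1, "sex", sex)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return Path(path)


def read_schedule_csv(path: str | Path) -> dict[tuple[str, str], TransitionSchedule]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for (loc, sex), sub in df.groupby(["location", "sex"]):
        sub = sub.sort_values("year")
        out[(loc, sex)] = TransitionSchedule(
            sub["year"].to_numpy(), sub["i"].to_numpy(), sub["m_S"].to_numpy(), sub["m_I"].to_numpy()
        )
    return out


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("seed", "output_dir", "horizon_year", "input")


@dataclass
class RunResult:
    """Everything one pipeline run produced, with output file paths."""

    series: EpiSeries
    truth: SyntheticTruth | None
    forecaster: IllnessDeathForecaster
    tables: dict[tuple[str, str], ProjectionTable]
    panel: pd.DataFrame
    outputs: dict[str, Path]


def _validate_config(config: Mapping) -> dict:
    cfg = dict(config)
    for key in _REQUIRED_KEYS:
        if key not in cfg:
            raise ConfigurationError(f"config is missing required key {key!r}")
    if not isinstance(cfg["seed"], int):
        raise ConfigurationError("seed must be an integer")
    if not isinstance(cfg["horizon_year"], int):
        raise ConfigurationError("horizon_year must be an integer")
    inp = cfg["input"]
    if not isinstance(inp, Mapping) or inp.get("kind") not in ("synthetic", "ghdx"):
        raise ConfigurationError("input.kind must be 'synthetic' or 'ghdx'")
    if inp["kind"] == "ghdx" and "path" not in inp:
        raise ConfigurationError("input.kind = ghdx requires input.path")
    cfg.setdefault("method", "loglinear")
    cfg.setdefault("window", 10)
    cfg.setdefault("n_draws", 200)
    if cfg["method"] not in ("loglinear", "hold_last"):
        raise ConfigurationError("method must be 'loglinear' or 'hold_last'")
    if cfg["n_draws"] < 1:
        raise ConfigurationError("n_draws must be >= 1")
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return _validate_config(cfg)


def run_pipeline(config: Mapping | str | Path) -> RunResult:
    """Run load/synth -> calibrate -> project -> analytics -> write.

    ``config`` is a mapping or a path to a YAML file; see the package
    README for the schema. Every stage logs row counts; any stage error
    aborts with that stage's exception.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else _validate_config(config)
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    outputs: dict[str, Path] = {}

    # stage 1: input panel
    truth = None
    if cfg["input"]["kind"] == "synthetic":
        synth_cfg = dict(cfg["input"].get("synthetic", {}))
        noise_cv = float(synth_cfg.pop("noise_cv", 0.05))
        gen = GeneratorConfig(seed=seed, **synth_cfg)
        truth = make_truth(gen)
        series = observe(truth, noise_cv=noise_cv, seed=seed + 1)
        outputs["panel"] = write_ghdx_csv(series, outdir / "panel.csv")
        outputs["truth_schedules"] = write_schedule_csv(
            truth.schedules, outdir / "truth_schedules.csv"
        )
        logger.info("generated synthetic panel: %d keys, %d rows", len(series.keys()), len(series))
    else:
        series = read_ghdx_csv(cfg["input"]["path"], measure_map=cfg["input"].get("measure_map"))
        logger.info("read panel %s: %d keys, %d rows", cfg["input"]["path"], len(series.keys()), len(series))

    # stage 2: calibrate
    forecaster = IllnessDeathForecaster(
        method=cfg["method"],
        window=cfg["window"],
        n_draws=cfg["n_draws"],
        random_state=seed + 2,
    ).fit(series)
    outputs["schedules"] = write_schedule_csv(forecaster.schedules_, outdir / "schedules.csv")
    logger.info("calibrated %d schedules", len(forecaster.schedules_))

    # stage 3: project with intervals
    tables = {
        key: forecaster.predict_table(cfg["horizon_year"], key, with_intervals=True)
        for key in forecaster.keys_
    }
    table_list = list(tables.values())
    outputs["projection_long"] = write_projection_table(
        table_list, outdir / "projection_long.csv", layout="long"
    )
    outputs["projection_table1"] = write_projection_table(
        table_list, outdir / "projection_table1.csv", layout="table1"
    )
    logger.info("projected %d keys to %d", len(tables), cfg["horizon_year"])

    # stage 4: analytics
    panel = region_panel(table_list)
    panel.reset_index().to_csv(outdir / "region_summary.csv", index=False)
    outputs["region_summary"] = outdir / "region_summary.csv"
    lollipop_long(panel).to_csv(outdir / "lollipop.csv", index=False)
    outputs["lollipop"] = outdir / "lollipop.csv"

    # stage 5: manifest (config + seed + version; deliberately no timestamp,
    # so identical configs give byte-identical bundles)
    manifest = {"config": _plain(cfg), "package_version": __version__}
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    outputs["manifest"] = outdir / "manifest.yaml"
    return RunResult(
        series=series, truth=truth, forecaster=forecaster,
        tables=tables, panel=panel, outputs=outputs,
    )


def _plain(obj):
    """Recursively coerce config values to YAML-safe builtins."""
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
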