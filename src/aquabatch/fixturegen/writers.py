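"""Writers emitting simulated seasons as dialect-conformant file sets.

Two layouts are produced, mirroring the two ways the simulation engine
is run: GUI mode saves 10 files per run (a project file, 8 daily files
split by variable category and one seasonal summary), plug-in (batch)
mode saves 3 (project, ``day.OUT`` with the union of daily variables,
``season.OUT``). Values are printed to 2 decimals; cells with no
defined value (here: the salinity columns, since the toy model carries
no salt) hold the -9.00 sentinel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .. import dialect
from .._calendar import doy_to_month_day
from ..errors import ValidationError
from ..readers import RunFileSet
from .crop import CO2_REFERENCE, SimulatedSeason

#: Mapping from dialect daily column name -> column of the season's
#: daily trace, or None for sentinel columns.
_DAILY_SOURCES = {
    "Tmin": "tmin", "Tmax": "tmax", "Tavg": "tavg", "ETo": "eto", "Rain": "rain",
    "GDD": "gdd", "GDDcum": "gdd_cum", "CC": "cc", "Ks": "ks", "Tr": "tr",
    "StressDay": "stress_day",
    "E": "evap", "ET": "et", "Runoff": "runoff", "Drain": "drainage",
    "Infilt": "infilt",
    "Inet": "inet",
    "SaltProf": None, "ECe": None,
    "EC1": None, "EC2": None, "EC3": None, "EC4": None,
}


def _daily_matrix(season: SimulatedSeason, schema) -> np.ndarray:
    d = season.daily
    cols = [d["day"], d["month"], d["year"], d["dap"], d["stage"]]
    for name, _unit in schema:
        if name == "Wr":
            cols.append(d["storage"])
        elif name == "WrTop":
            cols.append(0.4 * d["storage"])
        elif name.startswith("WC"):
            cols.append(0.25 * d["storage"])
        elif _DAILY_SOURCES.get(name) is None:
            cols.append(np.full(len(d), np.nan))
        else:
            cols.append(d[_DAILY_SOURCES[name]])
    return np.column_stack([np.asarray(c, dtype=float) for c in cols])


def seasonal_row(season: SimulatedSeason, run_no: int) -> list[float]:
    """One seasonal-summary row in SEASONAL_SCHEMA order (with keys)."""
    d = season.daily
    sow_month, sow_day = doy_to_month_day([season.sowing_doy])
    harv_month, harv_day = doy_to_month_day([season.harvest_doy])
    nan = float("nan")
    values = {
        "Cycle": season.cycle_length,
        "SowDay": float(sow_day[0]), "SowMonth": float(sow_month[0]),
        "HarvDay": float(harv_day[0]), "HarvMonth": float(harv_month[0]),
        "GDD": season.gdd_total,
        "TminAvg": float(d["tmin"].mean()), "TmaxAvg": float(d["tmax"].mean()),
        "TAvg": float(d["tavg"].mean()),
        "Rain": float(d["rain"].sum()), "ETo": float(d["eto"].sum()),
        "CO2": CO2_REFERENCE,
        "Irri": 0.0, "Infilt": float(d["infilt"].sum()),
        "Runoff": float(d["runoff"].sum()), "Drain": float(d["drainage"].sum()),
        "Upflow": 0.0,
        "E": season.sum_evap, "Ex": season.sum_ex,
        "E/Ex": 100.0 * season.sum_evap / season.sum_ex if season.sum_ex > 0 else nan,
        "Tr": season.sum_tr, "Trx": season.sum_trx,
        "Tr/Trx": 100.0 * season.sum_tr / season.sum_trx if season.sum_trx > 0 else nan,
        "ET": season.sum_et, "ETx": season.sum_ex + season.sum_trx,
        "WrEnd": float(d["storage"].iloc[-1]),
        "SaltIn": nan, "SaltOut": nan, "SaltUp": nan, "SaltProf": nan,
        "ECeAvg": nan,
        "ExpStress": 0.0, "StoStress": season.stress_pct,
        "FertStress": 0.0, "WeedStress": 0.0, "TempStress": season.stress_pct,
        "Biomass": season.biomass, "Brel": 100.0,
        "HI": 100.0 * season.crop.hi, "Yield": season.yield_,
        "WPet": season.wp_et,
    }
    return [float(run_no), float(season.season_year)] + [
        values[name] for name, _ in dialect.SEASONAL_SCHEMA]


def _seasonal_table(seasons) -> np.ndarray:
    return np.array([seasonal_row(s, i + 1) for i, s in enumerate(seasons)])


def _check_preconditions(seasons, prefix: str):
    if not seasons:
        raise ValidationError("at least one simulated season is required")
    if not prefix:
        raise ValidationError("prefix must be nonempty")
    if prefix != prefix.strip() or any(ch.isspace() for ch in prefix):
        raise ValidationError(f"prefix must not contain whitespace: {prefix!r}")


def _write_project(path: Path, seasons, prefix: str, soil_horizons: int,
                   input_files: dict[str, str] | None, params: dict[str, str] | None):
    if not 1 <= soil_horizons <= 5:
        raise ValidationError(f"soil_horizons must be in 1..5, got {soil_horizons}")
    first, last = seasons[0], seasons[-1]
    sow_m, sow_d = doy_to_month_day([first.sowing_doy])
    harv_m, harv_d = doy_to_month_day([last.harvest_doy])
    crop_name = first.crop.name
    files = {
        "ClimateFile": f"{prefix}.CLI",
        "CropFile": f"{crop_name}.CRO",
        "SoilFile": "Loam.SOL",
        "ManagementFile": "Default.MAN",
    }
    if input_files:
        files.update(input_files)
    lines = [
        f"{prefix} - synthetic project file",
        "",
        f"NumberOfRuns = {len(seasons)}",
        f"FirstDaySim = {int(sow_d[0]):02d} {int(sow_m[0]):02d} {first.season_year}",
        f"LastDaySim = {int(harv_d[0]):02d} {int(harv_m[0]):02d} {last.season_year}",
        f"FirstDayCrop = {int(sow_d[0]):02d} {int(sow_m[0]):02d} {first.season_year}",
        f"LastDayCrop = {int(harv_d[0]):02d} {int(harv_m[0]):02d} {last.season_year}",
    ]
    lines += [f"{k} = {v}" for k, v in files.items()]
    lines.append(f"SoilHorizons = {soil_horizons}")
    for k, v in (params or {}).items():
        lines.append(f"{k} = {v}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_gui_fileset(season_runs, out_dir, prefix: str, *, soil_horizons: int = 3,
                      input_files: dict[str, str] | None = None,
                      params: dict[str, str] | None = None) -> RunFileSet:
    """Write one run's seasons as the 10-file GUI-mode file set.

    Daily variables are partitioned by category across the 8 daily
    files; ``Run.OUT`` holds one seasonal-summary row per season.
    """
    _check_preconditions(season_runs, prefix)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    prm = out_dir / f"{prefix}{dialect.GUI_SUFFIXES['project']}"
    _write_project(prm, season_runs, prefix, soil_horizons, input_files, params)
    files["project"] = prm

    for kind in dialect.DAILY_KINDS_GUI:
        schema = dialect.DAILY_SCHEMAS[kind]
        names = dialect.DAILY_KEYS + [n for n, _ in schema]
        units = dialect.DAILY_KEY_UNITS + [u for _, u in schema]
        matrix = np.vstack([_daily_matrix(s, schema) for s in season_runs])
        path = out_dir / f"{prefix}{dialect.GUI_SUFFIXES[kind]}"
        dialect.write_table(path, f"{prefix} - daily {kind} output",
                            names, units, [(None, matrix)])
        files[kind] = path

    run_path = out_dir / f"{prefix}{dialect.GUI_SUFFIXES['run']}"
    names = dialect.SEASONAL_KEYS + [n for n, _ in dialect.SEASONAL_SCHEMA]
    units = dialect.SEASONAL_KEY_UNITS + [u for _, u in dialect.SEASONAL_SCHEMA]
    dialect.write_table(run_path, f"{prefix} - seasonal output",
                        names, units, [(None, _seasonal_table(season_runs))])
    files["run"] = run_path
    return RunFileSet(prefix=prefix, mode="gui", files=files)


def write_plugin_fileset(season_runs, out_dir, prefix: str, *, soil_horizons: int = 3,
                         input_files: dict[str, str] | None = None,
                         params: dict[str, str] | None = None) -> RunFileSet:
    """Write one run's seasons as the 3-file plug-in (batch) file set.

    ``day.OUT`` holds one ``Run: N`` block per season (no block header
    when there is a single season) with the union of daily variables;
    ``season.OUT`` holds one row per season; the project file uses the
    ``.PRO`` extension for a single-season project, ``.PRM`` otherwise.
    """
    _check_preconditions(season_runs, prefix)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    single = len(season_runs) == 1

    kind = "project_single" if single else "project"
    prm = out_dir / f"{prefix}{dialect.PLUGIN_SUFFIXES[kind]}"
    _write_project(prm, season_runs, prefix, soil_horizons, input_files, params)
    files[kind] = prm

    names = dialect.DAILY_KEYS + [n for n, _ in dialect.DAY_UNION_SCHEMA]
    units = dialect.DAILY_KEY_UNITS + [u for _, u in dialect.DAY_UNION_SCHEMA]
    blocks = [(None if single else i + 1, _daily_matrix(s, dialect.DAY_UNION_SCHEMA))
              for i, s in enumerate(season_runs)]
    day_path = out_dir / f"{prefix}{dialect.PLUGIN_SUFFIXES['day']}"
    dialect.write_table(day_path, f"{prefix} - daily output", names, units, blocks)
    files["day"] = day_path

    names = dialect.SEASONAL_KEYS + [n for n, _ in dialect.SEASONAL_SCHEMA]
    units = dialect.SEASONAL_KEY_UNITS + [u for _, u in dialect.SEASONAL_SCHEMA]
    season_path = out_dir / f"{prefix}{dialect.PLUGIN_SUFFIXES['season']}"
    dialect.write_table(season_path, f"{prefix} - seasonal output",
                        names, units, [(None, _seasonal_table(season_runs))])
    files["season"] = season_path
    return RunFileSet(prefix=prefix, mode="plugin", files=files)
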