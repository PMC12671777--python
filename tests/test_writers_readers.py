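import random
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from aquabatch import dialect, readers
from aquabatch.errors import AmbiguityError, ParseError, ValidationError
from aquabatch.fixturegen import (
    ToyCropParams, WeatherParams, generate_weather, seasonal_row, simulate_run,
    write_gui_fileset, write_plugin_fileset,
)
from conftest import assert_tables_equal_at_precision


# ---------------------------------------------------------------- writers

def test_gui_fileset_has_ten_nonempty_files(three_year_seasons, tmp_path):
    fs = write_gui_fileset(three_year_seasons, tmp_path, "A")
    assert len(fs.files) == 10
    assert set(fs.files) == set(dialect.GUI_SUFFIXES)
    for path in fs.files.values():
        assert path.exists() and path.stat().st_size > 0


def test_plugin_fileset_has_three_files_and_blocks(three_year_seasons, tmp_path):
    fs = write_plugin_fileset(three_year_seasons[:2], tmp_path, "M")
    assert set(fs.files) == {"project", "day", "season"}
    assert fs.files["project"].name == "M.PRM"
    day = readers.read_daily(fs.files["day"], "day")
    assert sorted(day.frame["season_index"].unique()) == [1, 2]
    season = readers.read_seasonal(fs.files["season"])
    assert len(season.frame) == 2


def test_single_season_project_uses_pro_extension(three_year_seasons, tmp_path):
    fs = write_plugin_fileset(three_year_seasons[:1], tmp_path, "Solo")
    assert fs.files["project_single"].name == "Solo.PRO"


def test_empty_prefix_rejected(three_year_seasons, tmp_path):
    with pytest.raises(ValidationError, match="prefix"):
        write_gui_fileset(three_year_seasons, tmp_path, "")
    with pytest.raises(ValidationError, match="season"):
        write_plugin_fileset([], tmp_path, "X")


def test_writers_are_deterministic(three_year_seasons, tmp_path):
    a = write_plugin_fileset(three_year_seasons, tmp_path / "a", "D")
    b = write_plugin_fileset(three_year_seasons, tmp_path / "b", "D")
    for kind in a.files:
        assert a.files[kind].read_bytes() == b.files[kind].read_bytes()


def test_seasonal_schema_is_41_variables(three_year_seasons, tmp_path):
    fs = write_plugin_fileset(three_year_seasons, tmp_path, "W")
    frag = readers.read_seasonal(fs.files["season"])
    non_key = [c for c in frag.columns if c not in dialect.SEASONAL_KEYS]
    assert len(non_key) == 41


# ------------------------------------------------------------ round trips

def expected_seasonal_frame(seasons) -> pd.DataFrame:
    names = dialect.SEASONAL_KEYS + [n for n, _ in dialect.SEASONAL_SCHEMA]
    return pd.DataFrame([seasonal_row(s, i + 1) for i, s in enumerate(seasons)],
                        columns=names)


def test_seasonal_round_trip_at_printed_precision(three_year_seasons, tmp_path):
    fs = write_plugin_fileset(three_year_seasons, tmp_path, "RT")
    parsed = readers.read_seasonal(fs.files["season"]).frame
    expected = expected_seasonal_frame(three_year_seasons)
    assert_tables_equal_at_precision(expected, parsed, list(expected.columns))


def test_gui_and_plugin_seasonal_files_agree(three_year_seasons, tmp_path):
    gui = write_gui_fileset(three_year_seasons, tmp_path / "g", "X")
    plg = write_plugin_fileset(three_year_seasons, tmp_path / "p", "X")
    a = readers.read_seasonal(gui.files["run"], "run").frame
    b = readers.read_seasonal(plg.files["season"]).frame
    cols = [c for c in a.columns if c != "season_index"]
    pd.testing.assert_frame_equal(a[cols], b[cols])


def test_daily_round_trip_at_printed_precision(three_year_seasons, tmp_path):
    fs = write_gui_fileset(three_year_seasons, tmp_path, "RT")
    clim = readers.read_daily(fs.files["clim"], "clim").frame
    src = pd.concat([s.daily for s in three_year_seasons], ignore_index=True)
    expected = pd.DataFrame({
        "Tmin": src["tmin"], "Tmax": src["tmax"], "Tavg": src["tavg"],
        "ETo": src["eto"], "Rain": src["rain"],
    })
    assert_tables_equal_at_precision(expected, clim, list(expected.columns))
    assert len(clim) == sum(s.cycle_length for s in three_year_seasons)


@pytest.mark.parametrize("seed", range(6))
def test_round_trip_property_across_seeds(seed, tmp_path):
    weather = generate_weather(WeatherParams(n_years=2, seed=seed))
    seasons = simulate_run(weather, ToyCropParams())
    fs = write_plugin_fileset(seasons, tmp_path, f"S{seed}")
    parsed = readers.read_seasonal(fs.files["season"]).frame
    expected = expected_seasonal_frame(seasons)
    assert_tables_equal_at_precision(expected, parsed, list(expected.columns))


def test_sentinel_reads_back_as_missing(three_year_seasons, tmp_path):
    fs = write_gui_fileset(three_year_seasons, tmp_path, "S")
    salt = readers.read_daily(fs.files["salt"], "salt").frame
    assert salt["SaltProf"].isna().all()
    assert np.isnan(salt["SaltProf"].mean())  # absent from any mean


# --------------------------------------------------------------- projects

def test_project_round_trip(three_year_seasons, tmp_path):
    fs = write_plugin_fileset(
        three_year_seasons, tmp_path, "P_Run", soil_horizons=4,
        input_files={"SoilFile": "Chernozem.SOL"}, params={"CO2File": "default"})
    rec = readers.read_project(fs.files["project"])
    assert rec.run_id == "P_Run"
    assert rec.n_runs == len(three_year_seasons)
    assert rec.soil_horizons == 4
    assert rec.input_files["SoilFile"] == "Chernozem.SOL"
    assert rec.input_files["CropFile"] == "Maize.CRO"
    assert rec.params["CO2File"] == "default"
    assert rec.sim_start.year == three_year_seasons[0].season_year
    assert rec.sim_end >= rec.sim_start


def test_six_soil_horizons_rejected(three_year_seasons, tmp_path):
    with pytest.raises(ValidationError, match="soil_horizons"):
        write_plugin_fileset(three_year_seasons, tmp_path, "H", soil_horizons=6)
    # and a file carrying 6 horizons is rejected on read
    fs = write_plugin_fileset(three_year_seasons, tmp_path, "H", soil_horizons=5)
    text = fs.files["project"].read_text().replace("SoilHorizons = 5",
                                                   "SoilHorizons = 6")
    fs.files["project"].write_text(text)
    with pytest.raises(ValidationError, match="soil_horizons"):
        readers.read_project(fs.files["project"])


def test_missing_period_dates_is_parse_error(tmp_path):
    bad = tmp_path / "bad.PRM"
    bad.write_text("title\n\nCropFile = Maize.CRO\n")
    with pytest.raises(ParseError, match="FirstDaySim"):
        readers.read_project(bad)


def test_pro_single_season_project(three_year_seasons, tmp_path):
    fs = write_plugin_fileset(three_year_seasons[:1], tmp_path, "One")
    rec = readers.read_project(fs.files["project_single"])
    assert rec.n_runs == 1


# -------------------------------------------------------------- discovery

def touch(directory: Path, *names: str) -> list[Path]:
    out = []
    for name in names:
        p = directory / name
        p.write_text("x\n")
        out.append(p)
    return out


def test_partial_gui_set_discovered_with_warning(tmp_path, caplog):
    paths = touch(tmp_path, "A_Clim.OUT", "A_Crop.OUT", "A.PRM")
    with caplog.at_level("WARNING"):
        runs = readers.discover_runs(paths)
    assert len(runs) == 1
    run = runs[0]
    assert run.prefix == "A" and run.mode == "gui"
    assert set(run.files) == {"clim", "crop", "project"}
    assert any("absent" in r.message for r in caplog.records)


def test_plugin_set_discovered(tmp_path):
    paths = touch(tmp_path, "Mday.OUT", "Mseason.OUT", "M.PRM")
    runs = readers.discover_runs(paths)
    assert len(runs) == 1
    assert runs[0].mode == "plugin"
    assert set(runs[0].files) == {"day", "season", "project"}


def test_unregistered_suffix_goes_to_unmatched(tmp_path):
    paths = touch(tmp_path, "notes.txt")
    runs = readers.discover_runs(paths)
    assert len(runs) == 0
    assert [p.name for p in runs.unmatched] == ["notes.txt"]


def test_discovery_is_order_independent(tmp_path):
    names = ["B_Clim.OUT", "B.PRM", "Cday.OUT", "Cseason.OUT", "C.PRM", "junk.bin"]
    paths = touch(tmp_path, *names)
    base = readers.discover_runs(paths)
    for _ in range(3):
        random.shuffle(paths)
        again = readers.discover_runs(paths)
        assert [(r.prefix, r.mode, sorted(r.files)) for r in again] == \
               [(r.prefix, r.mode, sorted(r.files)) for r in base]


def test_mixed_families_same_prefix_is_ambiguous(tmp_path):
    paths = touch(tmp_path, "Z_Clim.OUT", "Zday.OUT")
    with pytest.raises(AmbiguityError, match="Z"):
        readers.discover_runs(paths)


def test_every_path_lands_in_exactly_one_bucket(tmp_path):
    names = ["A_Clim.OUT", "A.PRM", "A_Run.OUT", "Bday.OUT", "B.PRM",
             "Bseason.OUT", "stray.log", "README"]
    paths = touch(tmp_path, *names)
    runs = readers.discover_runs(paths)
    assigned = [p for r in runs for p in r.files.values()]
    assert len(assigned) == len(set(assigned))
    assert len(assigned) + len(runs.unmatched) == len(paths)


def test_longest_suffix_wins(tmp_path):
    # a prefix ending in "day" must not be split at the shorter match
    (tmp_path / "Xmonday.OUT").write_text("x\n")
    prefix, kind, _ = dialect.match_suffix("Xmonday.OUT")
    assert kind == "day" and prefix == "Xmon"
    prefix, kind, _ = dialect.match_suffix("YCrop.OUT")
    assert kind == "crop" and prefix == "Y"


# --------------------------------------------------------------- metadata

def test_extract_metadata_with_names():
    meta = readers.extract_metadata("Maize_Soroca_RCP26",
                                    ["crop", "location", "scenario"])
    assert meta.fields == {"crop": "Maize", "location": "Soroca",
                           "scenario": "RCP26"}


def test_extract_metadata_autonames_single_token():
    meta = readers.extract_metadata("Run1")
    assert meta.fields == {"token1": "Run1"}


def test_extract_metadata_count_mismatch():
    with pytest.raises(ValidationError, match="3.*2|2.*3"):
        readers.extract_metadata("A_B", ["x", "y", "z"])


# ------------------------------------------------------- dialect parsing

def test_header_units_mismatch_is_parse_error(tmp_path):
    p = tmp_path / "bad.OUT"
    p.write_text("t\n\nDay Month Year DAP Stage V\n- - -\n")
    with pytest.raises(ParseError, match="columns"):
        dialect.read_table(p)


def test_non_numeric_cell_reports_row_and_column(tmp_path):
    p = tmp_path / "bad2.OUT"
    p.write_text("t\n\nA B\n- -\n1.00 oops\n")
    with pytest.raises(ParseError, match="oops.*B|B.*oops"):
        dialect.read_table(p)


def test_empty_data_section_gives_zero_row_fragment(tmp_path):
    p = tmp_path / "empty_season.OUT"
    names = dialect.SEASONAL_KEYS + [n for n, _ in dialect.SEASONAL_SCHEMA]
    units = dialect.SEASONAL_KEY_UNITS + [u for _, u in dialect.SEASONAL_SCHEMA]
    dialect.write_table(p, "t", names, units, [(None, np.empty((0, len(names))))])
    frag = readers.read_seasonal(p)
    assert len(frag.frame) == 0
    assert frag.columns == names


def test_crlf_tolerated(three_year_seasons, tmp_path):
    fs = write_plugin_fileset(three_year_seasons, tmp_path, "CRLF")
    path = fs.files["season"]
    path.write_bytes(path.read_bytes().replace(b"\n", b"\r\n"))
    frag = readers.read_seasonal(path)
    assert len(frag.frame) == len(three_year_seasons)
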