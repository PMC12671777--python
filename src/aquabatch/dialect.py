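"""The output-file dialect shared by writers and readers.

AquaCrop stores simulation results in whitespace-aligned text files. The
exact byte layout of the real program's files is version-dependent; this
package defines a single normative dialect with the same shape, which its
writers emit and its readers accept:

* line 1: free-text title/comment,
* line 2: blank,
* per data block: an optional ``Run: N`` header (plug-in multi-season
  daily files only), one line of variable names, one line of units, then
  numeric rows printed to 2 decimals,
* undefined cells carry the sentinel ``-9.00`` and are surfaced as
  missing values by the readers, never as numbers.

Daily files lead with ``Day Month Year DAP Stage`` key columns; seasonal
files lead with ``Run Year``.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError

SENTINEL = -9.0
SENTINEL_TEXT = "-9.00"

#: File kinds per mode, keyed by kind name -> filename suffix.
GUI_SUFFIXES = {
    "project": ".PRM",
    "clim": "Clim.OUT",
    "compec": "CompEC.OUT",
    "compwc": "CompWC.OUT",
    "crop": "Crop.OUT",
    "inet": "Inet.OUT",
    "prof": "Prof.OUT",
    "salt": "Salt.OUT",
    "wabal": "Wabal.OUT",
    "run": "Run.OUT",
}
PLUGIN_SUFFIXES = {
    "project": ".PRM",
    "project_single": ".PRO",
    "day": "day.OUT",
    "season": "season.OUT",
}

DAILY_KINDS_GUI = ("clim", "compec", "compwc", "crop", "inet", "prof", "salt", "wabal")
SEASONAL_KINDS = ("run", "season")

DAILY_KEYS = ["Day", "Month", "Year", "DAP", "Stage"]
DAILY_KEY_UNITS = ["-", "-", "-", "days", "-"]
SEASONAL_KEYS = ["Run", "Year"]
SEASONAL_KEY_UNITS = ["-", "-"]

#: Daily variable schema per GUI file kind: (name, unit) pairs. Variable
#: names are disjoint across kinds so the wide daily union is well defined.
DAILY_SCHEMAS = {
    "clim": [("Tmin", "degC"), ("Tmax", "degC"), ("Tavg", "degC"),
             ("ETo", "mm"), ("Rain", "mm")],
    "crop": [("GDD", "degC.day"), ("GDDcum", "degC.day"), ("CC", "-"),
             ("Ks", "-"), ("Tr", "mm"), ("StressDay", "-")],
    "wabal": [("E", "mm"), ("ET", "mm"), ("Runoff", "mm"),
              ("Drain", "mm"), ("Infilt", "mm")],
    "inet": [("Inet", "mm")],
    "prof": [("Wr", "mm"), ("WrTop", "mm")],
    "salt": [("SaltProf", "ton/ha"), ("ECe", "dS/m")],
    "compec": [("EC1", "dS/m"), ("EC2", "dS/m"), ("EC3", "dS/m"), ("EC4", "dS/m")],
    "compwc": [("WC1", "mm"), ("WC2", "mm"), ("WC3", "mm"), ("WC4", "mm")],
}

#: Union of daily variables in category order — the plug-in day.OUT schema.
DAY_UNION_SCHEMA = (DAILY_SCHEMAS["clim"] + DAILY_SCHEMAS["crop"]
                    + DAILY_SCHEMAS["wabal"] + DAILY_SCHEMAS["inet"]
                    + DAILY_SCHEMAS["prof"] + DAILY_SCHEMAS["salt"]
                    + DAILY_SCHEMAS["compec"] + DAILY_SCHEMAS["compwc"])

#: Canonical seasonal schema: exactly 41 variable columns after the
#: Run/Year keys, grouped by category (simulation period, climatic, soil
#: water, soil salinity, stresses, production).
SEASONAL_SCHEMA = [
    # simulation period
    ("Cycle", "days"), ("SowDay", "-"), ("SowMonth", "-"),
    ("HarvDay", "-"), ("HarvMonth", "-"), ("GDD", "degC.day"),
    # climatic totals / means
    ("TminAvg", "degC"), ("TmaxAvg", "degC"), ("TAvg", "degC"),
    ("Rain", "mm"), ("ETo", "mm"), ("CO2", "ppm"),
    # soil water
    ("Irri", "mm"), ("Infilt", "mm"), ("Runoff", "mm"), ("Drain", "mm"),
    ("Upflow", "mm"), ("E", "mm"), ("Ex", "mm"), ("E/Ex", "%"),
    ("Tr", "mm"), ("Trx", "mm"), ("Tr/Trx", "%"), ("ET", "mm"),
    ("ETx", "mm"), ("WrEnd", "mm"),
    # soil salinity
    ("SaltIn", "ton/ha"), ("SaltOut", "ton/ha"), ("SaltUp", "ton/ha"),
    ("SaltProf", "ton/ha"), ("ECeAvg", "dS/m"),
    # average stresses
    ("ExpStress", "%"), ("StoStress", "%"), ("FertStress", "%"),
    ("WeedStress", "%"), ("TempStress", "%"),
    # production
    ("Biomass", "ton/ha"), ("Brel", "%"), ("HI", "%"),
    ("Yield", "ton/ha"), ("WPet", "kg/m3"),
]
assert len(SEASONAL_SCHEMA) == 41


def match_suffix(filename: str):
    """Match ``filename`` against the registered suffixes, longest first.

    Returns ``(prefix, kind, family)`` with family in {"gui", "plugin",
    "both"}, or ``None`` when no registered suffix matches. A single
    trailing underscore left on the prefix after suffix removal is
    stripped, so ``A_Clim.OUT`` and ``A.PRM`` share the prefix ``A``.
    """
    candidates = []
    for family, table in (("gui", GUI_SUFFIXES), ("plugin", PLUGIN_SUFFIXES)):
        for kind, suffix in table.items():
            if filename.endswith(suffix) and len(filename) > len(suffix):
                candidates.append((len(suffix), family, kind, suffix))
    if not candidates:
        return None
    candidates.sort(key=lambda c: -c[0])
    longest = candidates[0][0]
    top = [c for c in candidates if c[0] == longest]
    _, family, kind, suffix = top[0]
    if len(top) > 1:  # same suffix registered in both families (.PRM)
        family = "both"
    prefix = filename[: -len(suffix)]
    if prefix.endswith("_"):
        prefix = prefix[:-1]
    return prefix, kind, family


def _fmt_cell(value, width: int) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        text = SENTINEL_TEXT
    else:
        text = f"{float(value):.2f}"
    return text.rjust(width)


def write_table(path: Path, title: str, names: list[str], units: list[str],
                blocks: list[tuple[int | None, np.ndarray]]) -> None:
    """Write a dialect table file.

    ``blocks`` is a list of ``(run_number, array)``; a block whose run
    number is None is written without a ``Run: N`` header. Arrays are 2-D
    (rows x columns) aligned with ``names``; NaN prints as the sentinel.
    """
    if len(names) != len(units):
        raise ValueError("names and units must have equal length")
    widths = [max(len(n), len(u), 10) for n, u in zip(names, units)]
    lines = [title, ""]
    for run_no, arr in blocks:
        if run_no is not None:
            lines.append(f"Run: {run_no}")
        lines.append(" ".join(n.rjust(w) for n, w in zip(names, widths)))
        lines.append(" ".join(u.rjust(w) for u, w in zip(units, widths)))
        arr = np.asarray(arr, dtype=float)
        for row in arr:
            lines.append(" ".join(_fmt_cell(v, w) for v, w in zip(row, widths)))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_table(path: Path):
    """Parse a dialect table file into ``(title, names, units, blocks)``.

    ``blocks`` mirrors :func:`write_table`: a list of ``(run_number,
    DataFrame)`` where files without ``Run:`` headers yield one block with
    run number None. Sentinel cells become NaN.
    """
    path = Path(path)
    raw = path.read_text(encoding="utf-8").replace("\r\n", "\n").replace("\r", "\n")
    lines = raw.split("\n")
    if len(lines) < 4:
        raise ParseError("file too short for dialect (title, blank, headers)", path)
    title = lines[0]
    blocks: list[tuple[int | None, pd.DataFrame]] = []
    names: list[str] | None = None
    units: list[str] | None = None

    i = 2
    n = len(lines)

    def parse_block(start: int, run_no: int | None):
        nonlocal names, units
        i = start
        block_names = lines[i].split()
        if not block_names:
            raise ParseError("expected a variable-name header line", path, i + 1)
        i += 1
        if i >= n:
            raise ParseError("missing units header line", path, i + 1)
        block_units = lines[i].split()
        if len(block_units) != len(block_names):
            raise ParseError(
                f"units line has {len(block_units)} columns, "
                f"name line has {len(block_names)}", path, i + 1)
        if len(set(block_names)) != len(block_names):
            raise ParseError("duplicate column names in header", path, i)
        i += 1
        rows = []
        while i < n:
            line = lines[i]
            if not line.strip():
                i += 1
                continue
            if line.strip().startswith("Run:"):
                break
            cells = line.split()
            if len(cells) != len(block_names):
                raise ParseError(
                    f"row has {len(cells)} cells, expected {len(block_names)}",
                    path, i + 1)
            row = []
            for col, cell in zip(block_names, cells):
                try:
                    v = float(cell)
                except ValueError:
                    raise ParseError(
                        f"non-numeric cell {cell!r} in column {col}",
                        path, i + 1) from None
                row.append(np.nan if cell == SENTINEL_TEXT else v)
            rows.append(row)
            i += 1
        frame = pd.DataFrame(rows, columns=block_names, dtype=float)
        names, units = block_names, block_units
        blocks.append((run_no, frame))
        return i

    # skip leading blank lines after the title
    while i < n and not lines[i].strip():
        i += 1
    while i < n:
        stripped = lines[i].strip()
        if not stripped:
            i += 1
            continue
        if stripped.startswith("Run:"):
            try:
                run_no = int(stripped.split(":", 1)[1])
            except ValueError:
                raise ParseError(f"malformed block header {stripped!r}", path, i + 1) from None
            i = parse_block(i + 1, run_no)
        else:
            i = parse_block(i, None)
    if names is None:
        raise ParseError("no data block found", path)
    return title, names, units, blocks
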