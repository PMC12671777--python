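"""Discovery, matching and parsing of simulation output files.

A batch of output files is grouped into runs by shared filename prefix:
every file of one simulation run carries the same prefix followed by a
registered kind suffix (``.PRM``, ``Clim.OUT``, ``day.OUT``, ...). GUI
mode produces up to 10 files per run, plug-in (batch) mode 3. Metadata
encoded in the prefix as underscore-separated tokens (crop, location,
scenario, ...) is recovered by :func:`extract_metadata`.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dialect
from .errors import AmbiguityError, ParseError, ValidationError

logger = logging.getLogger(__name__)

MAX_SOIL_HORIZONS = 5

GUI_ONLY_KINDS = frozenset(dialect.GUI_SUFFIXES) - {"project"}
PLUGIN_ONLY_KINDS = frozenset(dialect.PLUGIN_SUFFIXES) - {"project"}


class RunDiscovery(list):
    """A list of :class:`RunFileSet` plus the paths no suffix matched."""

    def __init__(self, runs=(), unmatched=()):
        super().__init__(runs)
        self.unmatched: list[Path] = list(unmatched)


@dataclass
class RunFileSet:
    """The discovered files of one simulation run, keyed by file kind."""

    prefix: str
    mode: str  # "gui" | "plugin"
    files: dict[str, Path] = field(default_factory=dict)
    unmatched: list[Path] = field(default_factory=list)

    @property
    def daily_kinds(self) -> tuple[str, ...]:
        if self.mode == "gui":
            return tuple(k for k in dialect.DAILY_KINDS_GUI if k in self.files)
        return ("day",) if "day" in self.files else ()

    @property
    def seasonal_kind(self) -> str | None:
        for kind in ("run", "season"):
            if kind in self.files:
                return kind
        return None

    @property
    def project_path(self) -> Path | None:
        return self.files.get("project") or self.files.get("project_single")


@dataclass
class RunMetadata:
    """Metadata tokens decoded from a run's filename prefix."""

    run_id: str
    tokens: list[str]
    fields: dict[str, str]


@dataclass
class ProjectRecord:
    """Contents of a project (.PRM/.PRO) file."""

    run_id: str
    n_runs: int
    sim_start: datetime.date
    sim_end: datetime.date
    crop_start: datetime.date
    crop_end: datetime.date
    input_files: dict[str, str]
    soil_horizons: int
    params: dict[str, str]


@dataclass
class TableFragment:
    """A parsed data table from one output file."""

    kind: str
    dataset: str  # "daily" | "seasonal"
    columns: list[str]
    units: dict[str, str]
    frame: pd.DataFrame


def discover_runs(paths, mode: str | None = None) -> RunDiscovery:
    """Group output files into runs by prefix/suffix matching.

    Files are assigned their kind by the longest registered suffix that
    matches; files sharing a prefix form one run. Partial file sets are
    allowed (a warning is logged naming the absent kinds); paths with no
    registered suffix are collected in ``unmatched`` on the returned
    :class:`RunDiscovery` (and mirrored on each run set). A prefix whose
    files span both the GUI-only and plug-in-only families raises
    :class:`AmbiguityError`.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValidationError("at least one path is required")
    if mode not in (None, "gui", "plugin"):
        raise ValidationError(f"mode must be 'gui' or 'plugin', got {mode!r}")

    unmatched: list[Path] = []
    by_prefix: dict[str, dict[str, Path]] = {}
    families: dict[str, set[str]] = {}
    for path in sorted(paths):
        m = dialect.match_suffix(path.name)
        if m is None:
            unmatched.append(path)
            continue
        prefix, kind, family = m
        slot = by_prefix.setdefault(prefix, {})
        if kind in slot and slot[kind] != path:
            raise ValidationError(
                f"prefix {prefix!r} has two files of kind {kind!r}: "
                f"{slot[kind]} and {path}")
        slot[kind] = path
        if family != "both":
            families.setdefault(prefix, set()).add(family)

    runs = []
    for prefix in sorted(by_prefix):
        fams = families.get(prefix, set())
        kinds = set(by_prefix[prefix])
        if fams == {"gui", "plugin"} or (kinds & GUI_ONLY_KINDS and kinds & PLUGIN_ONLY_KINDS):
            raise AmbiguityError(
                f"prefix {prefix!r} matches both GUI and plug-in file families")
        run_mode = mode or (next(iter(fams)) if fams else None)
        if run_mode is None:
            # only mode-neutral files (.PRM) present; batch mode is the default
            run_mode = "plugin"
            logger.warning("prefix %r: mode indeterminate from suffixes, assuming %s",
                           prefix, run_mode)
        expected = set(dialect.GUI_SUFFIXES if run_mode == "gui" else dialect.PLUGIN_SUFFIXES)
        if run_mode == "plugin":
            # a project is either .PRM or .PRO, never both expected
            expected -= {"project_single"} if "project" in kinds else {"project"}
        absent = expected - kinds
        if absent:
            logger.warning("run %r: %d file kind(s) absent: %s",
                           prefix, len(absent), ", ".join(sorted(absent)))
        runs.append(RunFileSet(prefix=prefix, mode=run_mode,
                               files=dict(by_prefix[prefix]),
                               unmatched=list(unmatched)))
    if unmatched:
        logger.warning("%d path(s) matched no registered suffix: %s",
                       len(unmatched), ", ".join(p.name for p in unmatched))
    return RunDiscovery(runs, unmatched)


def extract_metadata(prefix: str, token_names: list[str] | None = None) -> RunMetadata:
    """Split a run prefix into underscore-separated metadata tokens.

    With ``token_names`` the tokens are mapped positionally to those
    names (counts must match); without, tokens are auto-named
    ``token1..tokenN``.
    """
    if not prefix:
        raise ValidationError("prefix must be nonempty")
    tokens = prefix.split("_")
    if token_names is not None:
        if len(token_names) != len(tokens):
            raise ValidationError(
                f"token_names has {len(token_names)} names but prefix "
                f"{prefix!r} has {len(tokens)} tokens")
        names = list(token_names)
    else:
        names = [f"token{i + 1}" for i in range(len(tokens))]
    return RunMetadata(run_id=prefix, tokens=tokens, fields=dict(zip(names, tokens)))


def _parse_date(value: str, path, line_no: int) -> datetime.date:
    parts = value.split()
    if len(parts) != 3:
        raise ParseError(f"malformed date {value!r} (expected 'DD MM YYYY')", path, line_no)
    try:
        d, m, y = (int(p) for p in parts)
        return datetime.date(y, m, d)
    except ValueError as exc:
        raise ParseError(f"invalid date {value!r}: {exc}", path, line_no) from None


def read_project(path) -> ProjectRecord:
    """Parse a project (.PRM/.PRO) file into a :class:`ProjectRecord`.

    Unknown ``key = value`` entries are preserved in ``params``.
    """
    path = Path(path)
    m = dialect.match_suffix(path.name)
    run_id = m[0] if m else path.stem
    entries: dict[str, tuple[str, int]] = {}
    lines = path.read_text(encoding="utf-8").splitlines()
    for i, line in enumerate(lines, start=1):
        if i <= 2 or not line.strip():
            continue
        if "=" not in line:
            raise ParseError(f"expected 'key = value', got {line.strip()!r}", path, i)
        key, value = (s.strip() for s in line.split("=", 1))
        entries[key] = (value, i)

    def take_date(key: str) -> datetime.date:
        if key not in entries:
            raise ParseError(
                f"mandatory period date {key!r} missing", path, len(lines))
        value, line_no = entries.pop(key)
        return _parse_date(value, path, line_no)

    sim_start = take_date("FirstDaySim")
    sim_end = take_date("LastDaySim")
    crop_start = take_date("FirstDayCrop")
    crop_end = take_date("LastDayCrop")
    if sim_end < sim_start:
        raise ValidationError(
            f"simulation period end {sim_end} precedes start {sim_start}")
    if crop_end < crop_start:
        raise ValidationError(
            f"growing period end {crop_end} precedes start {crop_start}")

    n_runs = int(entries.pop("NumberOfRuns", ("1", 0))[0])
    horizons_raw, horizons_line = entries.pop("SoilHorizons", ("1", 0))
    soil_horizons = int(horizons_raw)
    if not 1 <= soil_horizons <= MAX_SOIL_HORIZONS:
        raise ValidationError(
            f"soil_horizons must be in 1..{MAX_SOIL_HORIZONS}, got {soil_horizons} "
            f"({path}:{horizons_line})")

    input_files = {}
    for key in ("ClimateFile", "CropFile", "SoilFile", "ManagementFile"):
        if key in entries:
            input_files[key] = entries.pop(key)[0]
    params = {k: v for k, (v, _) in entries.items()}
    return ProjectRecord(run_id=run_id, n_runs=n_runs, sim_start=sim_start,
                         sim_end=sim_end, crop_start=crop_start, crop_end=crop_end,
                         input_files=input_files, soil_horizons=soil_horizons,
                         params=params)


def _season_index_from_dap(frame: pd.DataFrame) -> np.ndarray:
    """Recover 1-based season indices from DAP resets in a daily table."""
    dap = frame["DAP"].to_numpy()
    starts = np.ones(len(dap), dtype=bool)
    starts[1:] = dap[1:] < dap[:-1]
    starts[0] = True
    return np.cumsum(starts.astype(int))


def _attach_dates(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    frame["date"] = pd.to_datetime({
        "year": frame["Year"].astype(int),
        "month": frame["Month"].astype(int),
        "day": frame["Day"].astype(int),
    })
    return frame


def read_daily(path, kind: str) -> TableFragment:
    """Parse a daily output file of the given registered kind.

    Plug-in ``day`` files may hold several ``Run: N`` blocks; GUI daily
    files hold the seasons back to back, and the 1-based season index is
    recovered from the DAP column resetting. The -9.00 sentinel becomes
    a missing value.
    """
    if kind not in dialect.DAILY_KINDS_GUI and kind != "day":
        raise ValidationError(f"{kind!r} is not a registered daily kind")
    _, names, units, blocks = dialect.read_table(Path(path))
    for key in dialect.DAILY_KEYS:
        if key not in names:
            raise ParseError(f"daily file lacks key column {key!r}", path)
    frames = []
    for run_no, frame in blocks:
        frame = frame.copy()
        if run_no is not None:
            frame["season_index"] = run_no
        frames.append(frame)
    frame = pd.concat(frames, ignore_index=True)
    if "season_index" not in frame.columns:
        if len(frame):
            frame["season_index"] = _season_index_from_dap(frame)
        else:
            frame["season_index"] = pd.Series(dtype=int)
    if len(frame):
        frame = _attach_dates(frame)
    else:
        frame["date"] = pd.Series(dtype="datetime64[ns]")
    return TableFragment(kind=kind, dataset="daily", columns=list(names),
                         units=dict(zip(names, units)), frame=frame)


def read_seasonal(path, kind: str = "season") -> TableFragment:
    """Parse a seasonal summary file (GUI ``Run.OUT`` or plug-in
    ``season.OUT``) into one row per season."""
    _, names, units, blocks = dialect.read_table(Path(path))
    for key in dialect.SEASONAL_KEYS:
        if key not in names:
            raise ParseError(f"seasonal file lacks key column {key!r}", path)
    frame = pd.concat([b for _, b in blocks], ignore_index=True)
    if len(frame) and frame["Run"].duplicated().any():
        dupes = frame.loc[frame["Run"].duplicated(), "Run"].astype(int).tolist()
        raise ParseError(f"duplicate season keys: {sorted(set(dupes))}", path)
    frame = frame.copy()
    frame["season_index"] = frame["Run"].astype(int) if len(frame) else pd.Series(dtype=int)
    return TableFragment(kind=kind, dataset="seasonal", columns=list(names),
                         units=dict(zip(names, units)), frame=frame)
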