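"""Combining parsed runs into tidy tables, filtering, renaming, export.

The three combined tables — project, seasonal, daily — each carry the
metadata columns first (``run_id`` plus the named prefix tokens),
followed by the variable columns. Keys are ``run_id`` (project),
``(run_id, season_index)`` (seasonal) and ``(run_id, season_index,
date)`` (daily).
"""

from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import readers
from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CombinedData:
    """The three tidy tables assembled from a batch of runs."""

    project_table: pd.DataFrame
    seasonal_table: pd.DataFrame
    daily_table: pd.DataFrame
    provenance: list[Path] = field(default_factory=list)

    def table(self, name: str) -> pd.DataFrame:
        try:
            return {"project": self.project_table, "seasonal": self.seasonal_table,
                    "daily": self.daily_table}[name]
        except KeyError:
            raise ValidationError(
                f"dataset must be one of project/seasonal/daily, got {name!r}") from None


def _metadata_frame(meta: readers.RunMetadata) -> dict[str, str]:
    return {"run_id": meta.run_id, **meta.fields}


def combine(runsets, token_names: list[str] | None = None) -> CombinedData:
    """Parse every run's files and assemble the three combined tables.

    Prefix metadata is joined onto every row; fragments of one dataset
    class are concatenated across runs, with variables missing in some
    runs becoming missing values. All prefixes must decode to the same
    number of tokens.
    """
    runsets = list(runsets)
    if not runsets:
        raise ValidationError("at least one run set is required")

    if token_names is None:
        counts = {rs.prefix: len(rs.prefix.split("_")) for rs in runsets}
        if len(set(counts.values())) > 1:
            offenders = sorted(counts, key=counts.get)
            raise ValidationError(
                "inconsistent metadata token counts across prefixes: "
                + ", ".join(f"{p}({counts[p]})" for p in offenders))

    metas, offenders = [], []
    for rs in runsets:
        try:
            metas.append(readers.extract_metadata(rs.prefix, token_names))
        except ValidationError:
            offenders.append(rs.prefix)
    if offenders:
        raise ValidationError(
            "prefixes with mismatched metadata token counts: " + ", ".join(offenders))

    project_rows, seasonal_frames, daily_frames, provenance = [], [], [], []
    for rs, meta in zip(runsets, metas):
        md = _metadata_frame(meta)
        ppath = rs.project_path
        if ppath is not None:
            rec = readers.read_project(ppath)
            row = dict(md)
            row.update({
                "n_runs": rec.n_runs,
                "sim_start": rec.sim_start, "sim_end": rec.sim_end,
                "crop_start": rec.crop_start, "crop_end": rec.crop_end,
                "soil_horizons": rec.soil_horizons,
            })
            row.update(rec.input_files)
            row.update(rec.params)
            project_rows.append(row)
            provenance.append(ppath)

        skind = rs.seasonal_kind
        if skind is not None:
            frag = readers.read_seasonal(rs.files[skind], skind)
            frame = frag.frame.assign(**md)
            seasonal_frames.append(frame)
            provenance.append(rs.files[skind])

        per_kind = []
        for kind in rs.daily_kinds:
            frag = readers.read_daily(rs.files[kind], kind)
            per_kind.append(frag.frame)
            provenance.append(rs.files[kind])
        if per_kind:
            daily = per_kind[0]
            keys = ["season_index", "date"] + readers.dialect.DAILY_KEYS
            for other in per_kind[1:]:
                extra = [c for c in other.columns if c not in daily.columns or c in keys]
                daily = daily.merge(other[extra], on=keys, how="outer")
            daily_frames.append(daily.assign(**md))

    meta_cols = ["run_id"] + (list(metas[0].fields) if metas else [])

    def finish(frames, key_cols):
        if not frames:
            return pd.DataFrame(columns=meta_cols)
        table = pd.concat(frames, ignore_index=True, sort=False)
        ordered = meta_cols + key_cols + [c for c in table.columns
                                          if c not in meta_cols + key_cols]
        table = table[ordered]
        dup = table.duplicated(subset=meta_cols[:1] + key_cols)
        if dup.any():
            raise ValidationError(
                f"duplicate (run_id, {', '.join(key_cols)}) keys in combined table")
        return table

    if project_rows:
        project_table = pd.DataFrame(project_rows)
        ordered = meta_cols + [c for c in project_table.columns if c not in meta_cols]
        project_table = project_table[ordered]
        if project_table["run_id"].duplicated().any():
            raise ValidationError("duplicate run_id keys in project table")
    else:
        project_table = pd.DataFrame(columns=meta_cols)

    seasonal_table = finish(seasonal_frames, ["season_index"])
    daily_table = finish(daily_frames, ["season_index", "date"])
    return CombinedData(project_table=project_table, seasonal_table=seasonal_table,
                        daily_table=daily_table, provenance=provenance)


_COMPARATORS = {
    "==": operator.eq, "!=": operator.ne, "<": operator.lt,
    "<=": operator.le, ">": operator.gt, ">=": operator.ge,
}


def filter_rows(table: pd.DataFrame, predicate_spec) -> pd.DataFrame:
    """Filter rows by a conjunction of simple predicates.

    ``predicate_spec`` is an iterable of ``(column, comparator, value)``
    triples with comparators ``== != < <= > >=`` and ``in`` (membership
    in an iterable of values). The input table is left untouched.
    """
    mask = pd.Series(True, index=table.index)
    for column, comp, value in predicate_spec:
        if column not in table.columns:
            raise ValidationError(f"unknown column {column!r} in filter")
        col = table[column]
        if comp == "in":
            mask &= col.isin(list(value))
        elif comp in _COMPARATORS:
            mask &= _COMPARATORS[comp](col, value)
        else:
            raise ValidationError(f"unknown comparator {comp!r}")
    return table.loc[mask].copy()


def rename_variable(table: pd.DataFrame, old: str, new: str) -> pd.DataFrame:
    """Rename one column; values are untouched. Errors on a missing
    source column or a name collision."""
    if old not in table.columns:
        raise ValidationError(f"unknown column {old!r}")
    if new in table.columns:
        raise ValidationError(f"column {new!r} already exists")
    return table.rename(columns={old: new})


def export_table(table: pd.DataFrame, path, format: str = "csv") -> Path:
    """Export a table as RFC-4180 CSV (header row, missing as empty
    field). Round-trips through :func:`pandas.read_csv`."""
    if format != "csv":
        raise ValidationError(f"unsupported export format {format!r}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, lineterminator="\r\n")
    return path
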