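"""Scatter / time-series and box plots with optional LOESS smoothing.

Plots are rendered headlessly with matplotlib. Because pixel output is
brittle to compare, every render also produces a machine-checkable
:class:`PlotData` sidecar (written as JSON next to the image) recording
the panel list, per-series point counts and, for boxplots, the
five-number summaries with the 1.5·IQR whisker rule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ValidationError

DEFAULT_SPAN = 0.75
LOESS_GRID = 100


@dataclass(frozen=True)
class PlotSpec:
    """Declarative description of one plot."""

    x_var: str
    y_var: str
    geometry: str = "scatter"  # "scatter" | "boxplot"
    color_group: str | None = None
    facet_group: str | None = None
    smoother: str = "none"     # "none" | "loess"
    span: float = DEFAULT_SPAN
    title: str = ""
    x_label: str | None = None
    y_label: str | None = None
    output: str | Path = "plot.png"
    format: str = "png"        # "png" | "svg"
    width_in: float = 8.0
    height_in: float = 5.0
    dpi: int = 120

    def __post_init__(self):
        if self.geometry not in ("scatter", "boxplot"):
            raise ValidationError(f"geometry must be scatter or boxplot, got {self.geometry!r}")
        if self.smoother not in ("none", "loess"):
            raise ValidationError(f"smoother must be none or loess, got {self.smoother!r}")
        if not 0 < self.span <= 1:
            raise ValidationError(f"span must be in (0, 1], got {self.span}")
        if self.format not in ("png", "svg"):
            raise ValidationError(f"format must be png or svg, got {self.format!r}")


@dataclass
class SeriesData:
    label: str
    n_points: int
    box: dict | None = None  # five-number summary for boxplot series


@dataclass
class PlotData:
    """Machine-checkable sidecar describing what was drawn."""

    geometry: str
    panels: list[str] = field(default_factory=list)
    series: dict[str, list[SeriesData]] = field(default_factory=dict)
    image: str = ""

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def five_number_summary(values: np.ndarray) -> dict:
    """Min, Q1, median, Q3, max plus 1.5·IQR whiskers.

    Quartiles use linear interpolation (the type-7 convention shared by
    numpy's default and matplotlib's boxplot).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValidationError("no data for box summary")
    q1, med, q3 = (float(q) for q in np.percentile(v, [25, 50, 75]))
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return {
        "min": float(v.min()), "q1": q1, "median": med, "q3": q3,
        "max": float(v.max()),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "n_outliers": int(v.size - inside.size),
    }


def loess_smooth(x, y, span: float = DEFAULT_SPAN) -> pd.DataFrame:
    """LOESS: locally weighted linear regression with tricube weights.

    At each of ``LOESS_GRID`` evaluation points spanning [min x, max x]
    the fit uses the ``ceil(span * n)`` nearest observations, weighted
    by the tricube kernel of scaled distance. When the window covers
    the whole sample (span = 1) the weights are uniform and the fit
    reduces to the global least-squares line. Returns a DataFrame with
    columns ``x`` and ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("loess requires finite x and y")
    if not 0 < span <= 1:
        raise ValidationError(f"span must be in (0, 1], got {span}")
    n = x.size
    q = max(2, math.ceil(span * n))
    minimum = max(3, q)
    if n < minimum:
        raise ValidationError(f"loess needs at least {minimum} points, got {n}")

    grid = np.linspace(x.min(), x.max(), LOESS_GRID)
    fitted = np.empty(LOESS_GRID)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    for i, x0 in enumerate(grid):
        d = np.abs(xs - x0)
        if q >= n:
            w = np.ones(n)
        else:
            cut = np.partition(d, q - 1)[q - 1]
            h = cut if cut > 0 else 1.0
            u = np.clip(d / h, 0.0, 1.0)
            w = (1.0 - u**3) ** 3
            w[d > cut] = 0.0
        sw = w.sum()
        xw = (w * xs).sum() / sw
        yw = (w * ys).sum() / sw
        sxx = (w * (xs - xw) ** 2).sum()
        if sxx <= 0:
            fitted[i] = yw
        else:
            b = (w * (xs - xw) * (ys - yw)).sum() / sxx
            fitted[i] = yw + b * (x0 - xw)
    return pd.DataFrame({"x": grid, "y": fitted})


def _series_split(frame: pd.DataFrame, spec: PlotSpec):
    if spec.color_group:
        for label, sub in frame.groupby(spec.color_group, sort=True, observed=True):
            yield str(label), sub
    else:
        yield "all", frame


def render(spec: PlotSpec, data: pd.DataFrame) -> tuple[Path, PlotData]:
    """Render the plot described by ``spec`` from a combined table.

    Writes the image plus a ``<image>.json`` sidecar and returns
    ``(image_path, PlotData)``. The input table is not modified.
    """
    for col in filter(None, (spec.x_var, spec.y_var, spec.color_group, spec.facet_group)):
        if col not in data.columns:
            raise ValidationError(f"unknown column {col!r}")
    frame = data.dropna(subset=[spec.y_var])
    if spec.geometry == "scatter":
        frame = frame.dropna(subset=[spec.x_var])
    if frame.empty:
        raise ValidationError("no data to plot")
    if spec.geometry == "boxplot" and spec.x_var == spec.y_var:
        raise ValidationError("boxplot needs a categorical x distinct from y")

    if spec.facet_group:
        panel_labels = [str(v) for v in
                        sorted(frame[spec.facet_group].dropna().unique(), key=str)]
        panels = [(lbl, frame[frame[spec.facet_group].astype(str) == lbl])
                  for lbl in panel_labels]
    else:
        panels = [("all", frame)]

    n_panels = len(panels)
    ncols = min(3, n_panels)
    nrows = math.ceil(n_panels / ncols)
    fig, axes = plt.subplots(nrows, ncols, squeeze=False,
                             figsize=(spec.width_in, spec.height_in),
                             dpi=spec.dpi, sharey=True)
    plot_data = PlotData(geometry=spec.geometry)

    for ax_index, (panel_label, sub) in enumerate(panels):
        ax = axes[ax_index // ncols][ax_index % ncols]
        plot_data.panels.append(panel_label)
        series_list = []
        if spec.geometry == "scatter":
            for label, s in _series_split(sub, spec):
                xv = pd.to_numeric(s[spec.x_var]).to_numpy()
                yv = pd.to_numeric(s[spec.y_var]).to_numpy()
                ax.scatter(xv, yv, s=12, alpha=0.7, label=label)
                if spec.smoother == "loess" and len(xv) >= max(3, math.ceil(spec.span * len(xv))) and len(np.unique(xv)) >= 3:
                    curve = loess_smooth(xv, yv, spec.span)
                    ax.plot(curve["x"], curve["y"], lw=2)
                series_list.append(SeriesData(label=label, n_points=int(len(s))))
        else:
            positions, labels_ = [], []
            for pos, (label, s) in enumerate(_series_split(sub, spec), start=1):
                groups = s.groupby(s[spec.x_var].astype(str), sort=True)
                for sub_label, g in groups:
                    yv = pd.to_numeric(g[spec.y_var]).to_numpy()
                    box = five_number_summary(yv)
                    tag = sub_label if label == "all" else f"{label}/{sub_label}"
                    series_list.append(SeriesData(label=tag, n_points=int(len(g)), box=box))
            box_groups = sub.groupby(sub[spec.x_var].astype(str), sort=True)
            data_lists = [pd.to_numeric(g[spec.y_var]).dropna().to_numpy()
                          for _, g in box_groups]
            ax.boxplot(data_lists, tick_labels=[k for k, _ in box_groups], whis=1.5)
        if panel_label != "all":
            ax.set_title(panel_label)
        ax.set_xlabel(spec.x_label or spec.x_var)
        ax.set_ylabel(spec.y_label or spec.y_var)
        if spec.color_group and spec.geometry == "scatter":
            ax.legend(fontsize="small")
        plot_data.series[panel_label] = series_list

    for extra in range(n_panels, nrows * ncols):
        axes[extra // ncols][extra % ncols].set_visible(False)
    if spec.title:
        fig.suptitle(spec.title)
    fig.tight_layout()

    out = Path(spec.output)
    if out.suffix.lstrip(".") != spec.format:
        out = out.with_suffix(f".{spec.format}")
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, format=spec.format)
    plt.close(fig)
    plot_data.image = str(out)
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(plot_data.to_json(), encoding="utf-8")
    return out, plot_data
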