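"""Factorial scenario studies.

A study is a full factorial over named factors (location, sowing date,
management, emission scenario, climate model, ...). One file set is
generated per cell of the Cartesian product; its filename prefix is the
crop label and the cell's level labels joined by underscores in factor
order, which is exactly the metadata convention the readers decode.
Per-level parameter overrides let each factor act on the weather or
crop parameters (e.g. a scenario raising the warming trend, a sowing
factor moving the sowing day).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

from ..errors import ValidationError
from ..readers import RunFileSet
from .crop import ToyCropParams, simulate_run
from .weather import WeatherParams, generate_weather
from .writers import write_gui_fileset, write_plugin_fileset

_WEATHER_FIELDS = set(WeatherParams.__dataclass_fields__)
_CROP_FIELDS = set(ToyCropParams.__dataclass_fields__)


@dataclass(frozen=True)
class StudyDesign:
    """A named full-factorial design.

    ``factors`` maps factor name -> ordered level labels; ``overrides``
    maps factor name -> level label -> {parameter: value}, where each
    parameter must be a field of :class:`WeatherParams` or
    :class:`ToyCropParams`. Level labels must not contain underscores
    (reserved as the prefix metadata separator).
    """

    crop: str = "Maize"
    factors: dict[str, list[str]] = field(default_factory=dict)
    overrides: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.factors:
            raise ValidationError("design needs at least one factor")
        if "_" in self.crop or not self.crop:
            raise ValidationError(f"crop label invalid: {self.crop!r}")
        for name, levels in self.factors.items():
            if not levels:
                raise ValidationError(f"factor {name!r} has no levels")
            for label in levels:
                if "_" in label:
                    raise ValidationError(
                        f"level label {label!r} of factor {name!r} contains an "
                        "underscore (reserved as metadata separator)")
        for factor, per_level in self.overrides.items():
            if factor not in self.factors:
                raise ValidationError(f"override references unknown factor {factor!r}")
            for label, params in per_level.items():
                if label not in self.factors[factor]:
                    raise ValidationError(
                        f"override references unknown level {label!r} of {factor!r}")
                for key in params:
                    if key not in _WEATHER_FIELDS and key not in _CROP_FIELDS:
                        raise ValidationError(
                            f"override {key!r} is not a weather or crop parameter")

    @property
    def token_names(self) -> list[str]:
        return ["crop"] + list(self.factors)

    def cells(self):
        """Iterate (prefix, {factor: label}) over the factor product."""
        names = list(self.factors)
        for combo in itertools.product(*(self.factors[n] for n in names)):
            labels = dict(zip(names, combo))
            prefix = "_".join([self.crop] + list(combo))
            yield prefix, labels

    def n_cells(self) -> int:
        n = 1
        for levels in self.factors.values():
            n *= len(levels)
        return n


def _apply_overrides(design: StudyDesign, labels: dict[str, str],
                     weather: WeatherParams, crop: ToyCropParams):
    w_kw: dict[str, float] = {}
    c_kw: dict[str, float] = {}
    for factor, label in labels.items():
        for key, value in design.overrides.get(factor, {}).get(label, {}).items():
            (w_kw if key in _WEATHER_FIELDS else c_kw)[key] = value
    return (weather.replace(**w_kw) if w_kw else weather,
            crop.replace(**c_kw) if c_kw else crop)


def generate_study(design: StudyDesign, weather_params: WeatherParams,
                   crop_params: ToyCropParams, out_dir, *,
                   mode: str = "plugin") -> list[RunFileSet]:
    """Generate one file set per cell of the design's factor product.

    Deterministic for fixed parameters: each cell's weather seed is
    derived from the base seed and the cell's position in the product,
    so distinct cells (e.g. distinct climate models) see distinct but
    reproducible weather draws.
    """
    if mode not in ("gui", "plugin"):
        raise ValidationError(f"mode must be 'gui' or 'plugin', got {mode!r}")
    out_dir = Path(out_dir)
    crop_params = crop_params.replace(name=design.crop)
    write = write_gui_fileset if mode == "gui" else write_plugin_fileset
    runsets = []
    for index, (prefix, labels) in enumerate(design.cells()):
        weather, crop = _apply_overrides(design, labels, weather_params, crop_params)
        weather = weather.replace(seed=(weather.seed * 100003 + index) % (2**31))
        seasons = simulate_run(generate_weather(weather), crop)
        runsets.append(write(seasons, out_dir, prefix))
    return runsets


def moldova_design(scenarios=("RCP26", "RCP85")) -> StudyDesign:
    """The package's reference factorial design: a Moldova-like study of
    3 locations x 3 sowing dates x 2 management practices x len(scenarios)
    emission scenarios x 3 climate models (108 cells per crop with both
    scenarios)."""
    factors = {
        "location": ["Soroca", "Chisinau", "Cahul"],
        "sowing": ["26Apr", "11May", "26May"],
        "management": ["Opt", "NonOpt"],
        "scenario": list(scenarios),
        "gcm": ["HadGEM2", "MPIESM", "NorESM1"],
    }
    overrides = {
        "location": {
            "Soroca": {"base_tmin": 3.0, "base_tmax": 15.0},
            "Chisinau": {"base_tmin": 4.0, "base_tmax": 16.0},
            "Cahul": {"base_tmin": 5.0, "base_tmax": 17.0},
        },
        "sowing": {
            "26Apr": {"sowing_doy": 116},
            "11May": {"sowing_doy": 131},
            "26May": {"sowing_doy": 146},
        },
        "management": {
            "Opt": {"cc_max": 0.9, "hi": 0.48},
            "NonOpt": {"cc_max": 0.75, "hi": 0.44},
        },
        "scenario": {
            "RCP26": {"warming_trend": 0.1},
            "RCP85": {"warming_trend": 0.5},
        },
        "gcm": {
            "HadGEM2": {"eto_base": 3.1},
            "MPIESM": {"eto_base": 3.0},
            "NorESM1": {"eto_base": 2.9},
        },
    }
    overrides["scenario"] = {k: v for k, v in overrides["scenario"].items()
                             if k in factors["scenario"]}
    return StudyDesign(crop="Maize", factors=factors, overrides=overrides)
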