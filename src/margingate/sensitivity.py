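"""Local sensitivity analysis of the effective margin.

Two modes over a :class:`~margingate.scenarios.ScenarioSpec`:

- ``oat_sweep``: one-at-a-time variation — each parameter swept over its
  grid with all others held at their nominal scenario values;
- ``combined_sweep``: full-factorial enumeration of the Cartesian product
  of all grids (capped, default 10^6 cells).

Parameters are addressed by path: ``baseline_margin``, ``compression``
(the scenario's single compression modifier), ``chronic_shift:<name>`` or
``acute_shift:<name>`` (a shift modifier by name).

The default illustrative grids (compression {0.50, 0.56, 0.62};
inflammation {0, 2.0, 6.0} mV; hot-spot {0, 3.2} mV) are chosen to be
consistent with the reported one-at-a-time (~5.0-7.0 mV) and combined
(~3.7-8.3 mV) effective-margin spans; they are a documented default, not a
reproduction of any published grid.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .core import DomainError, Modifier, ModifierKind, apply_scenario
from .scenarios import ScenarioSpec

DEFAULT_CELL_CAP = 10**6

_KIND_FOR_PREFIX = {
    "chronic_shift": ModifierKind.CHRONIC_SHIFT,
    "acute_shift": ModifierKind.ACUTE_SHIFT,
}


class ConfigurationError(ValueError):
    """A grid refers to a parameter the scenario does not have."""


class GridSizeError(ValueError):
    """The combined product exceeds the enumeration cap."""


@dataclass(frozen=True)
class ParameterGrid:
    """A finite ascending list of values for one addressable parameter."""

    parameter: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        values = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", values)
        if not values:
            raise DomainError(f"grid for {self.parameter!r} is empty")
        if any(not math.isfinite(v) for v in values):
            raise DomainError(f"grid for {self.parameter!r} contains non-finite values")
        if list(values) != sorted(values):
            raise DomainError(f"grid for {self.parameter!r} must be ascending")
        if self.parameter == "baseline_margin":
            if values[0] <= 0:
                raise DomainError("baseline_margin grid values must be > 0")
        elif self.parameter == "compression":
            if values[0] <= 0 or values[-1] > 1:
                raise DomainError("compression grid values must lie in (0, 1]")
        elif self.parameter.split(":", 1)[0] in _KIND_FOR_PREFIX:
            if values[0] < 0:
                raise DomainError(f"shift grid {self.parameter!r} values must be >= 0 mV")
        else:
            raise DomainError(
                f"unknown parameter path {self.parameter!r}; expected baseline_margin, "
                "compression, chronic_shift:<name> or acute_shift:<name>"
            )


@dataclass(frozen=True)
class PerParameter:
    parameter: str
    min_margin: float
    max_margin: float
    nominal_margin: float


@dataclass(frozen=True)
class SensitivityReport:
    mode: str  # "oat" | "combined"
    per_parameter: tuple[PerParameter, ...]
    overall_min: float
    overall_max: float
    at_min: dict
    at_max: dict
    n_evaluated: int
    evaluations: tuple[tuple[dict, float], ...]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per evaluated cell."""
        rows = []
        for point, margin in self.evaluations:
            rows.append(
                {
                    "mode": self.mode,
                    "parameter": ";".join(point),
                    "values": ";".join(repr(v) for v in point.values()),
                    "effective_margin": margin,
                }
            )
        return pd.DataFrame(rows, columns=["mode", "parameter", "values", "effective_margin"])

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode,
                "per_parameter": [
                    {
                        "parameter": p.parameter,
                        "min_margin": p.min_margin,
                        "max_margin": p.max_margin,
                        "nominal_margin": p.nominal_margin,
                    }
                    for p in self.per_parameter
                ],
                "overall": {"min": self.overall_min, "max": self.overall_max},
                "at_min": self.at_min,
                "at_max": self.at_max,
                "n_evaluated": self.n_evaluated,
            },
            indent=2,
        )


def _nominal_value(spec: ScenarioSpec, parameter: str) -> float:
    if parameter == "baseline_margin":
        return spec.baseline_margin
    if parameter == "compression":
        comps = [m for m in spec.modifiers if m.enabled and m.kind is ModifierKind.COMPRESSION]
        if len(comps) != 1:
            raise ConfigurationError(
                f"scenario {spec.id!r} has {len(comps)} enabled compression modifiers; "
                "the 'compression' path requires exactly one"
            )
        return comps[0].magnitude
    prefix, _, name = parameter.partition(":")
    kind = _KIND_FOR_PREFIX.get(prefix)
    if kind is None or not name:
        raise ConfigurationError(f"malformed parameter path {parameter!r}")
    for m in spec.modifiers:
        if m.enabled and m.kind is kind and m.name == name:
            return m.magnitude
    raise ConfigurationError(
        f"scenario {spec.id!r} has no enabled {prefix} modifier named {name!r}"
    )


def _with_value(spec: ScenarioSpec, parameter: str, value: float) -> ScenarioSpec:
    if parameter == "baseline_margin":
        return replace(spec, baseline_margin=value)
    if parameter == "compression":
        mods = tuple(
            replace(m, magnitude=value)
            if m.enabled and m.kind is ModifierKind.COMPRESSION
            else m
            for m in spec.modifiers
        )
        return replace(spec, modifiers=mods)
    prefix, _, name = parameter.partition(":")
    kind = _KIND_FOR_PREFIX[prefix]
    mods = tuple(
        replace(m, magnitude=value)
        if m.enabled and m.kind is kind and m.name == name
        else m
        for m in spec.modifiers
    )
    return replace(spec, modifiers=mods)


def _evaluate(spec: ScenarioSpec, assignment: dict) -> float:
    for parameter, value in assignment.items():
        spec = _with_value(spec, parameter, value)
    return apply_scenario(spec.baseline_margin, spec.modifiers).effective_margin


def oat_sweep(spec: ScenarioSpec, grids: Iterable[ParameterGrid]) -> SensitivityReport:
    """Vary each gridded parameter alone, all others at nominal.

    The nominal value is added to each grid if absent, so the nominal margin
    is always among the evaluated cells.
    """
    grids = list(grids)
    per_parameter: list[PerParameter] = []
    evaluations: list[tuple[dict, float]] = []
    for grid in grids:
        nominal = _nominal_value(spec, grid.parameter)
        values = sorted(set(grid.values) | {nominal})
        margins = []
        for v in values:
            margin = _evaluate(spec, {grid.parameter: v})
            evaluations.append(({grid.parameter: v}, margin))
            margins.append(margin)
        nominal_margin = margins[values.index(nominal)]
        per_parameter.append(
            PerParameter(grid.parameter, min(margins), max(margins), nominal_margin)
        )
    return _finalize("oat", per_parameter, evaluations)


def combined_sweep(
    spec: ScenarioSpec,
    grids: Iterable[ParameterGrid],
    cell_cap: int = DEFAULT_CELL_CAP,
) -> SensitivityReport:
    """Full-factorial enumeration of the Cartesian product of all grids."""
    grids = list(grids)
    for grid in grids:
        _nominal_value(spec, grid.parameter)  # validate addressability
    size = math.prod(len(g.values) for g in grids) if grids else 0
    if size > cell_cap:
        raise GridSizeError(
            f"combined grid has {size} cells, exceeding the cap of {cell_cap}"
        )
    evaluations: list[tuple[dict, float]] = []
    parameters = [g.parameter for g in grids]
    for combo in itertools.product(*(g.values for g in grids)):
        assignment = dict(zip(parameters, combo))
        evaluations.append((assignment, _evaluate(spec, assignment)))
    return _finalize("combined", [], evaluations)


def _finalize(
    mode: str,
    per_parameter: Sequence[PerParameter],
    evaluations: Sequence[tuple[dict, float]],
) -> SensitivityReport:
    if not evaluations:
        raise DomainError("no grid cells evaluated")
    # strict < / > keeps the first-enumerated (lexicographically first) tie-winner
    at_min, overall_min = evaluations[0]
    at_max, overall_max = evaluations[0]
    for point, margin in evaluations[1:]:
        if margin < overall_min:
            at_min, overall_min = point, margin
        if margin > overall_max:
            at_max, overall_max = point, margin
    return SensitivityReport(
        mode=mode,
        per_parameter=tuple(per_parameter),
        overall_min=overall_min,
        overall_max=overall_max,
        at_min=dict(at_min),
        at_max=dict(at_max),
        n_evaluated=len(evaluations),
        evaluations=tuple((dict(p), m) for p, m in evaluations),
    )


def default_grids() -> list[ParameterGrid]:
    """Illustrative default grids around the main scenario's nominal values."""
    return [
        ParameterGrid("compression", (0.50, 0.56, 0.62)),
        ParameterGrid("chronic_shift:inflammation", (0.0, 2.0, 6.0)),
        ParameterGrid("acute_shift:hot_spot", (0.0, 3.2)),
    ]
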