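"""Cumulative excitability-margin model.

The excitability margin of a neuron is the distance from rest to spike
threshold, ``dV_margin = V_thr - V_rest`` (mV).  Pro-excitatory influences
are translated into voltage-equivalent terms and composed in three fixed
phases:

1. **chronic_shift** — sustained depolarizations of the resting potential
   (e.g. a stress-associated inflammatory component, +2.0 mV), subtracted
   from the baseline margin *before* compression;
2. **compression** — a dimensionless scaling of the remaining reserve,
   parameterized from the chronic-restraint-stress rheobase ratio
   ``gamma_rh = I_rh,CRS / I_rh,ctrl ~ 0.56``;
3. **acute_shift** — transient threshold-lowering terms (e.g. the
   CREB-dependent engram "hot-spot", +3.2 mV), subtracted *after*
   compression.

With one modifier of each kind the composition reduces to

    dV_eff,final = gamma_rh * (dV_margin,0 - dV_rest,infl,stress) - dV_hot

All voltages are millivolts; internal arithmetic is unrounded, and
``round_half_up`` provides the one-decimal half-up rounding used when
comparing against printed literature values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Iterable, NamedTuple, Union


class DomainError(ValueError):
    """A model quantity left its domain of validity."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero upward, as printed values in the literature are.

    Python's builtin ``round`` uses banker's rounding (5.25 -> 5.2); printed
    one-decimal comparisons here require 5.25 -> 5.3.
    """
    if not math.isfinite(x):
        raise DomainError(f"cannot round non-finite value {x!r}")
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


def compute_margin(v_thr: float, v_rest: float) -> float:
    """Static excitability margin ``dV_margin = v_thr - v_rest`` in mV.

    Raises :class:`DomainError` for non-finite inputs or ``v_thr <= v_rest``
    (a non-positive margin is outside the model's domain).
    """
    if not (math.isfinite(v_thr) and math.isfinite(v_rest)):
        raise DomainError(
            f"non-finite membrane potentials: v_thr={v_thr!r}, v_rest={v_rest!r}"
        )
    if v_thr <= v_rest:
        raise DomainError(
            f"spike threshold must lie above rest: v_thr={v_thr} mV <= v_rest={v_rest} mV"
        )
    return v_thr - v_rest


def gamma_from_rheobase(i_rh_stress: float, i_rh_ctrl: float) -> float:
    """Compression coefficient from a stressed/control rheobase pair.

    ``gamma_rh = I_rh,stress / I_rh,ctrl`` (dimensionless; both currents in
    the same, arbitrary units).  A ratio > 1 (margin-widening) is returned
    as-is but is rejected when used as a compression :class:`Modifier`.
    """
    for label, value in (("i_rh_stress", i_rh_stress), ("i_rh_ctrl", i_rh_ctrl)):
        if not math.isfinite(value) or value <= 0:
            raise DomainError(f"rheobase current must be finite and > 0: {label}={value!r}")
    return i_rh_stress / i_rh_ctrl


@dataclass(frozen=True)
class MembraneState:
    """Resting potential / spike threshold pair, or a margin-only baseline.

    The baseline state used throughout is margin-only (the literature prints
    the vCA1 margin 18.4 mV without separate potentials).
    """

    margin: float
    v_rest: float | None = None
    v_thr: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.margin) or self.margin <= 0:
            raise DomainError(f"margin must be finite and > 0 mV, got {self.margin!r}")
        if (self.v_rest is None) != (self.v_thr is None):
            raise DomainError("v_rest and v_thr must be given together or not at all")
        if self.v_rest is not None and self.v_thr is not None:
            derived = compute_margin(self.v_thr, self.v_rest)
            if derived != self.margin:
                raise DomainError(
                    f"margin {self.margin} mV != v_thr - v_rest = {derived} mV"
                )

    @classmethod
    def from_potentials(cls, v_rest: float, v_thr: float) -> "MembraneState":
        return cls(margin=compute_margin(v_thr, v_rest), v_rest=v_rest, v_thr=v_thr)

    @classmethod
    def from_margin(cls, margin: float) -> "MembraneState":
        return cls(margin=margin)


class ModifierKind(str, Enum):
    COMPRESSION = "compression"
    CHRONIC_SHIFT = "chronic_shift"
    ACUTE_SHIFT = "acute_shift"


@dataclass(frozen=True)
class Modifier:
    """One pro-excitatory hit.

    ``magnitude`` is a fraction in (0, 1] for ``compression`` and a
    depolarizing (margin-reducing) shift in mV >= 0 for the two shift kinds.
    """

    name: str
    kind: ModifierKind
    magnitude: float
    provenance: str = ""
    enabled: bool = True

    def __post_init__(self) -> None:
        kind = ModifierKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not math.isfinite(self.magnitude):
            raise DomainError(f"modifier {self.name!r}: non-finite magnitude")
        if kind is ModifierKind.COMPRESSION:
            if not (0 < self.magnitude <= 1):
                raise DomainError(
                    f"compression modifier {self.name!r} must have magnitude in (0, 1], "
                    f"got {self.magnitude} (>1 would widen the margin)"
                )
        elif self.magnitude < 0:
            raise DomainError(
                f"shift modifier {self.name!r} must have magnitude >= 0 mV "
                f"(depolarizing shifts are stored positive), got {self.magnitude}"
            )

    def disabled(self) -> "Modifier":
        return replace(self, enabled=False)


class DecompositionStep(NamedTuple):
    name: str
    before: float
    after: float


@dataclass(frozen=True)
class MarginResult:
    """Effective margin after a scenario, with a step-by-step decomposition."""

    baseline_margin: float
    effective_margin: float
    percent_reduction: float
    decomposition: tuple[DecompositionStep, ...]
    clamped: bool = False

    @property
    def effective_margin_printed(self) -> float:
        return round_half_up(self.effective_margin, 1)

    @property
    def percent_reduction_printed(self) -> float:
        return round_half_up(self.percent_reduction, 1)


def percent_reduction(baseline: float, effective: float) -> float:
    """Percent of the baseline margin lost: ``100 * (baseline - effective) / baseline``."""
    if not math.isfinite(baseline) or baseline <= 0:
        raise DomainError(f"baseline margin must be finite and > 0, got {baseline!r}")
    if not math.isfinite(effective) or effective < 0:
        raise DomainError(f"effective margin must be finite and >= 0, got {effective!r}")
    if effective > baseline:
        raise DomainError(
            f"effective margin {effective} mV exceeds baseline {baseline} mV; "
            "margin-widening scenarios are outside the reduction metric's domain"
        )
    return 100.0 * (baseline - effective) / baseline


def apply_scenario(
    baseline: Union[MembraneState, float],
    modifiers: Iterable[Modifier],
) -> MarginResult:
    """Compose modifiers onto a baseline margin in canonical phase order.

    Regardless of the input order: (1) enabled chronic shifts are subtracted
    from the baseline; (2) the remainder is multiplied by the product of
    enabled compression coefficients; (3) enabled acute shifts are
    subtracted.  A negative final margin is floored at 0 with ``clamped``
    set (so wide sensitivity sweeps never abort), but chronic shifts that
    consume the whole baseline reserve raise :class:`DomainError` — the
    compression of a non-positive reserve is not defined by the model.
    """
    m0 = baseline.margin if isinstance(baseline, MembraneState) else float(baseline)
    if not math.isfinite(m0) or m0 <= 0:
        raise DomainError(f"baseline margin must be finite and > 0 mV, got {m0!r}")

    mods = [m for m in modifiers if m.enabled]
    chronic = [m for m in mods if m.kind is ModifierKind.CHRONIC_SHIFT]
    compressions = [m for m in mods if m.kind is ModifierKind.COMPRESSION]
    acute = [m for m in mods if m.kind is ModifierKind.ACUTE_SHIFT]

    chronic_total = sum(m.magnitude for m in chronic)
    if chronic_total >= m0:
        raise DomainError(
            f"chronic shifts total {chronic_total} mV >= baseline {m0} mV; "
            "the pre-compression reserve would be non-positive"
        )

    steps: list[DecompositionStep] = []
    current = m0
    for m in chronic:
        nxt = current - m.magnitude
        steps.append(DecompositionStep(m.name, current, nxt))
        current = nxt
    for m in compressions:
        nxt = current * m.magnitude
        steps.append(DecompositionStep(m.name, current, nxt))
        current = nxt
    clamped = False
    for m in acute:
        raw = current - m.magnitude
        if raw < 0:
            raw = 0.0
            clamped = True
        steps.append(DecompositionStep(m.name, current, raw))
        current = raw

    return MarginResult(
        baseline_margin=m0,
        effective_margin=current,
        percent_reduction=percent_reduction(m0, current),
        decomposition=tuple(steps),
        clamped=clamped,
    )
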