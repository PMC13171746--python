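"""Catalog of transient depolarizing events and margin-exceedance analysis.

Six event classes with literature-reported amplitude summaries (all in mV
of somatic depolarization):

- ``nmda_spike_somatic``  gaussian 5.9 +/- 1.5   (local NMDA spikes)
- ``nmda_plateau``        range 3-23             (location-dependent NMDA spike/plateau)
- ``sharp_wave``          gaussian 4.1 +/- 2.3   (sharp wave-associated depolarizations)
- ``ripple``              range 1-4              (intracellular ripple amplitudes)
- ``burst``               range 10-25            (burst-associated depolarizations)
- ``place_field_hill``    range 5-20             (subthreshold place-field "hills")

Amplitude models: a reported range is taken uniform on [low, high]
(maximum-entropy choice); a mean +/- SD is taken gaussian truncated at 0
(depolarizations are positive).  Classification against a margin uses the
model's effective support — the range itself, or mean +/- 2 SD (clamped at
0) for gaussians; the 2-SD convention is an artifact convention and is
flagged in report output.  The comparison is made purely at amplitude
scale: no temporal structure, dendritic location, or inhibition enters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Union

import numpy as np
from scipy import stats

from .core import DomainError


class ConfigurationError(ValueError):
    """A reproducibility or method-selection contract was violated."""


@dataclass(frozen=True)
class GaussianAmplitude:
    """Mean +/- SD amplitude summary (mV), truncated at 0 when sampled."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean) and math.isfinite(self.sd)) or self.sd <= 0:
            raise DomainError(f"gaussian amplitude requires finite mean and sd > 0, got {self!r}")

    @property
    def support(self) -> tuple[float, float]:
        # effective support: mean +/- 2 sd, clamped at 0 (amplitudes are positive)
        return (max(0.0, self.mean - 2 * self.sd), self.mean + 2 * self.sd)


@dataclass(frozen=True)
class RangeAmplitude:
    """Reported min-max amplitude range (mV), modeled uniform."""

    low: float
    high: float

    def __post_init__(self) -> None:
        ok = math.isfinite(self.low) and math.isfinite(self.high)
        if not ok or not (0 <= self.low < self.high):
            raise DomainError(f"range amplitude requires 0 <= low < high, got {self!r}")

    @property
    def support(self) -> tuple[float, float]:
        return (self.low, self.high)


AmplitudeModel = Union[GaussianAmplitude, RangeAmplitude]


@dataclass(frozen=True)
class EventClass:
    name: str
    amplitude_model: AmplitudeModel
    provenance: str = ""


class CrossingStatus(str, Enum):
    CANNOT_CROSS = "cannot_cross"
    PARTIALLY_WITHIN = "partially_within"
    EXCEEDS = "exceeds"


@dataclass(frozen=True)
class CrossingAssessment:
    event: str
    margin: float
    status: CrossingStatus
    exceedance_probability: float | None = None


def builtin_events() -> list[EventClass]:
    return [
        EventClass("nmda_spike_somatic", GaussianAmplitude(5.9, 1.5),
                   "somatic equivalent of local NMDA spikes"),
        EventClass("nmda_plateau", RangeAmplitude(3.0, 23.0),
                   "location-dependent NMDA spike/plateau amplitudes"),
        EventClass("sharp_wave", GaussianAmplitude(4.1, 2.3),
                   "sharp wave-associated depolarizations"),
        EventClass("ripple", RangeAmplitude(1.0, 4.0),
                   "intracellular ripple amplitudes"),
        EventClass("burst", RangeAmplitude(10.0, 25.0),
                   "burst-associated depolarizations"),
        EventClass("place_field_hill", RangeAmplitude(5.0, 20.0),
                   "subthreshold place-field depolarization hills"),
    ]


def classify_crossing(margin: float, event: EventClass) -> CrossingAssessment:
    """Classify whether an event's amplitude support can reach the margin.

    ``exceeds`` if the entire support lies at or above the margin;
    ``cannot_cross`` if the entire support lies below it; otherwise
    ``partially_within``.
    """
    if not math.isfinite(margin) or margin < 0:
        raise DomainError(f"margin must be finite and >= 0 mV, got {margin!r}")
    low, high = event.amplitude_model.support
    if low >= margin:
        status = CrossingStatus.EXCEEDS
    elif high < margin:
        status = CrossingStatus.CANNOT_CROSS
    else:
        status = CrossingStatus.PARTIALLY_WITHIN
    return CrossingAssessment(event.name, margin, status)


def exceedance_probability(
    margin: float,
    event: EventClass,
    method: str = "analytic",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> float:
    """P(amplitude >= margin) under the event's amplitude model.

    ``analytic``: closed form — uniform mass above the margin for range
    models; normal upper tail renormalized to the positive half-line for
    gaussian models.  ``monte_carlo``: draws ``n_samples`` amplitudes from
    the same model (``seed`` is mandatory — reproducibility contract).
    """
    if not math.isfinite(margin) or margin < 0:
        raise DomainError(f"margin must be finite and >= 0 mV, got {margin!r}")
    model = event.amplitude_model

    if method == "analytic":
        if isinstance(model, RangeAmplitude):
            if margin <= model.low:
                return 1.0
            if margin >= model.high:
                return 0.0
            return (model.high - margin) / (model.high - model.low)
        # gaussian truncated at 0: P(X >= m | X >= 0)
        tail = stats.norm.sf(margin, loc=model.mean, scale=model.sd)
        norm = stats.norm.sf(0.0, loc=model.mean, scale=model.sd)
        return float(tail / norm)

    if method == "monte_carlo":
        if seed is None:
            raise ConfigurationError("monte_carlo requires an explicit seed")
        if n_samples < 1:
            raise ConfigurationError(f"n_samples must be >= 1, got {n_samples}")
        rng = np.random.default_rng(seed)
        if isinstance(model, RangeAmplitude):
            draws = rng.uniform(model.low, model.high, size=n_samples)
        else:
            a = (0.0 - model.mean) / model.sd  # truncate at 0
            draws = stats.truncnorm.rvs(
                a, np.inf, loc=model.mean, scale=model.sd,
                size=n_samples, random_state=rng,
            )
        return float(np.mean(draws >= margin))

    raise ConfigurationError(f"unknown method {method!r}; use 'analytic' or 'monte_carlo'")


def assess(
    margin: float,
    event: EventClass,
    with_probability: bool = False,
    method: str = "analytic",
    n_samples: int = 100_000,
    seed: int | None = None,
) -> CrossingAssessment:
    """Classification plus, on request, the exceedance probability."""
    base = classify_crossing(margin, event)
    if not with_probability:
        return base
    p = exceedance_probability(margin, event, method=method, n_samples=n_samples, seed=seed)
    return CrossingAssessment(base.event, base.margin, base.status, p)
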