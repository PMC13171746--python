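"""Synthetic neuron populations for end-to-end pipeline testing.

No experimental data enter this package; every stage is exercised on
synthetic populations whose central values match the printed vCA1 summary
statistics (baseline margin 18.4 mV, rheobase compression gamma ~ 0.56)
while the dispersion parameters (margin SD 2.0 mV, rheobase CV 0.2) are
documented artifact conventions, not literature claims.

Per neuron the generator draws:

- a baseline margin ~ Normal(margin_mean, margin_sd) truncated below at
  1 mV (a non-positive margin is outside the model's domain);
- a control rheobase ~ lognormal with mean ``rheobase_ctrl_mean`` and the
  stated coefficient of variation;
- a stressed rheobase = gamma_true * control * multiplicative lognormal
  noise with CV = rheobase_cv / 2 and unit mean, so the per-neuron ratio
  stress/control has expectation exactly gamma_true.

Spike threshold is fixed at a nominal -50 mV and the resting potential is
placed at threshold minus margin; only the margin is ever consumed
downstream, the potentials exist so exports carry a complete membrane
state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DomainError

_MARGIN_FLOOR_MV = 1.0


@dataclass(frozen=True)
class PopulationConfig:
    n_neurons: int
    margin_mean: float = 18.4
    margin_sd: float = 2.0
    gamma_true: float = 0.56
    rheobase_ctrl_mean: float = 100.0
    rheobase_cv: float = 0.2
    v_thr_nominal: float = -50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise DomainError(f"n_neurons must be >= 1, got {self.n_neurons}")
        if not math.isfinite(self.margin_mean) or self.margin_mean <= 0:
            raise DomainError(f"margin_mean must be > 0 mV, got {self.margin_mean}")
        if self.margin_sd < 0 or self.rheobase_cv < 0:
            raise DomainError("margin_sd and rheobase_cv must be >= 0")
        if not (0 < self.gamma_true <= 1):
            raise DomainError(f"gamma_true must be in (0, 1], got {self.gamma_true}")
        if self.rheobase_ctrl_mean <= 0:
            raise DomainError("rheobase_ctrl_mean must be > 0")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with mean 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=math.sqrt(sigma2), size=size)


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """One row per neuron: membrane state plus a paired control/stress rheobase.

    Columns: neuron_id, v_rest, v_thr, margin, i_rh_ctrl, i_rh_stress.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_neurons

    if config.margin_sd == 0:
        margins = np.full(n, config.margin_mean)
    else:
        # truncated-below gaussian by resampling; floor at 1 mV keeps every
        # neuron inside the model's domain
        margins = rng.normal(config.margin_mean, config.margin_sd, size=n)
        bad = margins < _MARGIN_FLOOR_MV
        while bad.any():
            margins[bad] = rng.normal(config.margin_mean, config.margin_sd, size=int(bad.sum()))
            bad = margins < _MARGIN_FLOOR_MV

    i_ctrl = config.rheobase_ctrl_mean * _lognormal_unit_mean(rng, config.rheobase_cv, n)
    noise = _lognormal_unit_mean(rng, config.rheobase_cv / 2, n)
    i_stress = config.gamma_true * i_ctrl * noise

    v_thr = np.full(n, config.v_thr_nominal)
    return pd.DataFrame(
        {
            "neuron_id": np.arange(n),
            "v_rest": v_thr - margins,
            "v_thr": v_thr,
            "margin": margins,
            "i_rh_ctrl": i_ctrl,
            "i_rh_stress": i_stress,
        }
    )


def export_population_csv(population: pd.DataFrame, path: str | Path, seed: int) -> None:
    """Write the population as CSV with the generating seed in a header comment."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed = {seed}\n")
        population.to_csv(fh, index=False)


def load_population_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


@dataclass(frozen=True)
class GammaEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    n: int


def recover_gamma(
    pairs: pd.DataFrame | np.ndarray,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> GammaEstimate:
    """Estimate the rheobase compression coefficient from paired currents.

    Point estimate: mean of per-neuron stress/control ratios.  Interval:
    seeded percentile bootstrap over neurons.
    """
    if isinstance(pairs, pd.DataFrame):
        ctrl = pairs["i_rh_ctrl"].to_numpy(float)
        stress = pairs["i_rh_stress"].to_numpy(float)
    else:
        arr = np.asarray(pairs, dtype=float)
        ctrl, stress = arr[:, 0], arr[:, 1]
    if ctrl.size < 2:
        raise DomainError(f"need >= 2 rheobase pairs, got {ctrl.size}")
    if (ctrl <= 0).any() or (stress <= 0).any():
        raise DomainError("rheobase currents must all be > 0")

    ratios = stress / ctrl
    estimate = float(ratios.mean())

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ratios.size, size=(n_boot, ratios.size))
    boot_means = ratios[idx].mean(axis=1)
    alpha = (1 - ci) / 2
    lo, hi = np.quantile(boot_means, [alpha, 1 - alpha])
    return GammaEstimate(estimate, float(lo), float(hi), int(ratios.size))
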