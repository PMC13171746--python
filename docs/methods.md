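# Methods

## Model

The package implements a phenomenological, voltage-domain model of
excitability-margin gating. The margin of a neuron is
`ΔV_margin = V_thr − V_rest` (mV), the minimal depolarization needed to
reach spike threshold from rest. Pro-excitatory influences enter as
voltage-equivalent terms of three kinds, composed in a canonical phase
order regardless of input order:

1. chronic depolarizing shifts of the resting potential, subtracted from
   the baseline margin;
2. compression of the remaining reserve by a dimensionless coefficient;
3. acute (transient) threshold-lowering shifts, subtracted last.

With one modifier per phase the composition is
`ΔV_eff,final = γ · (M₀ − Δchronic) − Δacute`, floored at 0 mV. The phase
placement generalizes the anchor case: inflammatory terms sit inside the
compression (they act on the standing margin that stress then compresses),
acute reactivation terms outside it (they act on the already-compressed
reserve). Any new modifier must declare its phase; multiple compression
coefficients multiply, multiple shifts of a phase add.

The model is explicitly *not* a biophysical membrane model: the
compression coefficient γ_rh is the chronic-restraint-stress rheobase
ratio `I_rh,CRS / I_rh,ctrl ≈ 0.56` used as a phenomenological scaling of
the voltage reserve, not a current-to-voltage conversion through input
resistance; no conductances, kinetics or inhibition are represented, and
changes in inhibitory tone are assumed already translated into the
voltage-equivalent shift terms.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| baseline margin M₀ | mV | 18.4 | reported static vCA1 pyramidal margin |
| compression γ_rh | — | 0.56 | chronic-stress rheobase ratio |
| inflammatory shift | mV | 2.0 | conservative chronic component, ≈ ⅓ of an acute-LPS depolarization |
| hot-spot shift ΔV_hot | mV | 3.2 | CREB-dependent engram-reactivation threshold reduction |

The scenario registry composes these into: `baseline`, `stress_only`,
`main` (all three hits → 5.984 mV, prints 6.0, −67.5 %), and
`strong_inflammation` (inflammatory shift at the full acute-LPS scale,
3 × 2.0 = 6.0 mV → 3.744 mV, prints 3.7). Two further variants are
**reconstructed**: the reported ~4.3 mV chronic pro-excitatory variant is
obtained with an additional chronic shift of 3.0 mV, and the reported
~1.7 mV acute-caffeine variant with an additional acute shift of 4.3 mV.
These magnitudes are inferred from the reported end results, not
themselves reported; the registry flags them `reconstructed=True`, report
writers star them, and strict verification never gates on them.

## Domain and numerical conventions

- All voltages in mV; no unit-conversion layer.
- A baseline margin ≤ 0 and chronic shifts that consume the entire
  baseline are domain errors (the compression of a non-positive reserve is
  undefined); a *final* margin driven below 0 by acute shifts is floored
  at 0 with a `clamped` flag instead, so wide sensitivity grids never
  abort mid-scan.
- Internal arithmetic is unrounded; comparisons against printed literature
  values use half-up rounding to one decimal (`round_half_up`), because
  Python's builtin banker's rounding disagrees on exact .x5 cases.
- Extrema ties in sweeps report the first-enumerated (lexicographically
  first) grid point; enumeration order is the given grid order with
  ascending values, so reports are deterministic.

## Sensitivity analysis

`oat_sweep` varies one parameter at a time (grids addressed as
`baseline_margin`, `compression`, `chronic_shift:<name>`,
`acute_shift:<name>`), always including the nominal value; `combined_sweep`
enumerates the full Cartesian product (capped at 10⁶ cells). The shipped
default grids — compression {0.50, 0.56, 0.62}, inflammation {0, 2.0, 6.0}
mV, hot-spot {0, 3.2} mV — are *illustrative*: they are chosen to bracket
the nominal values at plausible alternative magnitudes, and the
compression axis alone reproduces a 5.0–7.0 mV one-at-a-time band around
the nominal 5.984 mV. The reported combined span of ~3.7–8.3 mV depends on
alternative parameter sets that are not themselves published, so it is not
a fixed verification target; the default full product spans 3.0–11.4 mV,
which contains it.

## Event catalog and exceedance

Six transient depolarizing event classes carry literature-reported
amplitude summaries: somatic-equivalent NMDA spikes (gaussian
5.9 ± 1.5 mV), NMDA spike/plateau range (3–23 mV), sharp-wave
depolarizations (gaussian 4.1 ± 2.3 mV), intracellular ripples (1–4 mV),
burst-associated depolarizations (10–25 mV), place-field hills (5–20 mV).

- A reported range is modelled uniform on [low, high] — the
  maximum-entropy choice given only endpoints.
- A mean ± SD summary is modelled gaussian truncated at 0 and
  renormalized (depolarization amplitudes are positive).
- Crossing classification compares the model's *effective support* with
  the margin: the range itself, or mean ± 2 SD clamped at 0 for gaussians
  (an explicit artifact convention, flagged as such). Entire support at or
  above the margin ⇒ `exceeds`; entirely below ⇒ `cannot_cross`;
  otherwise `partially_within`.
- The exceedance probability `P(amplitude ≥ margin)` is available in
  closed form and by seeded Monte Carlo from the same model; the two agree
  within three binomial standard errors at 10⁵ draws across the catalog.

The comparison is purely at amplitude scale, as the model intends: no
temporal structure, dendritic location, conductance state, synchrony or
inhibition enters, so "exceeds" means *amplitude sufficiency*, not a
prediction that the event fires the cell.

## Synthetic populations

No experimental data enter the package; the generator provides the
statistical structure the pipeline assumes so every stage is testable.
Per neuron it draws a baseline margin ~ Normal(18.4, 2.0) mV truncated
below at 1 mV, a control rheobase ~ lognormal(mean 100, CV 0.2, arbitrary
current units), and a stressed rheobase = 0.56 × control × lognormal
noise with CV 0.1 and unit mean — so the per-neuron stress/control ratio
has expectation exactly γ_true and the mean-of-ratios estimator is
unbiased. The dispersion values (margin SD 2.0 mV, CV 0.2) are plausible
order-of-magnitude conventions for testing, not literature claims, and
are config-overridable. Spike threshold is fixed at a nominal −50 mV with
rest placed at threshold minus margin; only the margin is consumed
downstream.

What passing tests show: the composition arithmetic, sweep enumeration,
probability calculus and estimator behave correctly on data with the
assumed structure. What they do not show: anything about real vCA1
heterogeneity, covariance between margin and rheobase, or state
dependence — the generator draws margins and rheobases independently and
log-symmetrically, which real populations need not.

Problem sizes used by the default runs and tests — populations of
10²–10³ neurons, sweep grids of ≤ 18 cells, 10⁵ Monte Carlo draws — were
chosen as comfortably sufficient for the statistical checks involved
(e.g. the γ standard error at n = 500, CV 0.1 is ≈ 0.0025 against a 0.02
recovery tolerance).

## Reproducibility

Every stochastic component (population generation, bootstrap, Monte
Carlo) takes an explicit seed; Monte Carlo without a seed is a
configuration error. Report writing is atomic (write-then-rename), CSV
output is comma-separated UTF-8 with full-precision numbers plus a
`*_printed` one-decimal column, and rerunning the same configuration and
seed yields byte-identical payloads (manifest timestamp aside). Strict
runs exit nonzero if any non-reconstructed scenario fails to reproduce
its reported printed value.

## Limitations

- The model is static, phenomenological arithmetic over voltage
  equivalents; it cannot capture dynamics, adaptation, inhibition or
  network effects.
- Two scenario variants and all dispersion parameters are reconstructions
  or conventions, clearly flagged as such.
- The uniform and truncated-gaussian amplitude models are conventions over
  sparse published summaries (endpoints, mean ± SD), not fitted
  distributions.
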