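#!/usr/bin/env python
"""Synthetic-population check: is the stress compression recoverable?

Generates 1000 synthetic vCA1 neurons (margin 18.4 +/- 2.0 mV, paired
control/stress rheobase with true compression 0.56, CV 0.2), re-estimates
the compression coefficient from the paired rheobase currents with a
bootstrap interval, and pushes every neuron through the main scenario.
Writes results/population_summary.json plus a 200-neuron sample population
as results/population.csv (the summary uses the full n = 1000).

Finding: the mean-of-ratios estimator recovers gamma ~ 0.56 well within
0.02 at n = 1000, and the population-mean effective margin sits near the
single-neuron 5.984 mV value.
"""

from pathlib import Path

from margingate import PopulationConfig, export_population_csv, generate_population
from margingate.report import RunConfig, run

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    config = RunConfig(
        out_dir=OUT, seed=SEED, population=PopulationConfig(n_neurons=1000, seed=SEED)
    )
    run(config, sections=("population",))
    export_population_csv(
        generate_population(PopulationConfig(n_neurons=200, seed=SEED)),
        OUT / "population.csv",
        seed=SEED,
    )
    print((OUT / "population_summary.json").read_text())
    print(f"wrote {OUT / 'population.csv'}")


if __name__ == "__main__":
    main()
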