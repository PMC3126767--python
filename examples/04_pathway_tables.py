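"""Co-occurrence tables and unfolding pathways for a simulated dataset.

Reproduces the shape of the study's co-occurrence analysis: main peaks
co-occur in most curves, side peaks rarely co-occur with one another,
and each curve's 0/1 event signs concatenate into a pathway string.
"""

from fdcurve.pipeline import PipelineConfig, run_pipeline
from fdcurve.presets import br_simulation_config
from fdcurve.simulate import simulate_dataset

config = br_simulation_config(seed=1)
curves, _ = simulate_dataset(config)
result = run_pipeline(curves, PipelineConfig())

pos = result.matrix.positions
for name, table in result.cooccurrence_tables.items():
    print(f"\n{name} co-occurrence (out of {table.n_curves} curves):")
    for subset, count in zip(table.subsets, table.counts):
        label = " & ".join(f"{pos[e]:.0f}aa" for e in subset)
        print(f"  {label:28s} {count:2d}")

print("\nunfolding pathways (region strings: main first, then sides):")
for pathway, count in sorted(result.pathways.items(), key=lambda kv: -kv[1]):
    print(f"  {pathway:14s} x{count}")
print(
    "\nPairwise main-peak co-occurrence stays at or above half the curves,\n"
    "while side peaks co-occur with each other only rarely - side peaks are\n"
    "alternative intermediates, not a fixed part of the pathway."
)
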