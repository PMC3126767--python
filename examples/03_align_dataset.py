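"""Align unfolding events across a simulated 26-curve bR dataset.

Runs the full pipeline (denoise -> encode -> detect -> align) and prints
the consensus events with their support, the per-curve shifts, and the
main/side classification.
"""

from fdcurve.pipeline import PipelineConfig, run_pipeline
from fdcurve.presets import br_simulation_config
from fdcurve.simulate import simulate_dataset

config = br_simulation_config(seed=1)
curves, annotations = simulate_dataset(config)
result = run_pipeline(curves, PipelineConfig())

print("consensus events (26 curves):")
labels = {l.event_id: l for l in result.labels}
for eid, pos in result.matrix.positions.items():
    lab = labels[eid]
    print(
        f"  {eid}: {pos:6.1f} aa  support {lab.frequency:2d}/26  "
        f"{lab.label:4s}  region {lab.region}"
    )

shifts = [a.shift - result.matrix.reference_shift for a in result.alignments]
print(f"\nper-curve shifts span [{min(shifts):.0f}, {max(shifts):.0f}] aa "
      "(the cantilever attachment offsets, re-referenced)")
print(
    "\nEvents supported by at least half the curves are main peaks (pairwise\n"
    "helix unfolding); the rest are side peaks (unfolding intermediates)."
)
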