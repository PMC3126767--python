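"""Simulate one bacteriorhodopsin-like F-D curve and detect its events.

Builds a single synthetic retraction curve with known unfolding events,
denoises it, encodes it into A/B/C fragments, and prints the detected
events with their WLC contour lengths (in amino acids).
"""

import numpy as np

from fdcurve import denoise, encode
from fdcurve.events import detect_events
from fdcurve.presets import br_simulation_config
from fdcurve.simulate import simulate_curve

config = br_simulation_config(seed=1)
rng = np.random.default_rng(1)
raw, truth, offset = simulate_curve(config, rng, "demo")

print(f"simulated curve: {raw.n_samples} samples, attachment offset {offset:.1f} aa")
print("ground truth events (offset-free positions):")
for t in truth:
    print(f"  {t.position_aa:6.1f} aa  {t.kind:4s}  rendered as {t.rendered}")

curve = denoise(raw)
_, frags = encode(curve)
print(f"\nfragment sequence: {frags.pattern()}")

events = detect_events(curve)
print("\ndetected events (positions include the attachment offset):")
for ev in events:
    side = "" if ev.side_position_aa is None else f", side at {ev.side_position_aa:.1f} aa"
    print(
        f"  type {ev.event_type:>3s}: main at {ev.main_position_aa:6.1f} aa "
        f"(peak {ev.peak_force:.0f} pN{side})"
    )
print(
    "\nSubtracting the offset, each main/side position should sit within a few\n"
    "amino acids of a ground-truth event; the contour length names the last\n"
    "unfolded residue of the protein at that rupture."
)
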