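"""Fit the Worm-Like Chain model to a rising force limb.

Generates a noisy WLC limb with a known contour length (148 aa, the
single-step unfolding of the E-D helix pair in bR) and recovers it with
a one-parameter least-squares fit.
"""

import numpy as np

from fdcurve.events import fit_wlc
from fdcurve.preprocess import DenoisedCurve
from fdcurve.wlc import NM_PER_AA, wlc_force

L_true = 148 * NM_PER_AA  # 53.28 nm
x = np.linspace(5.0, 50.0, 400)
rng = np.random.default_rng(0)
force = wlc_force(x, L_true) + rng.normal(0, 5.0, x.size)

curve = DenoisedCurve(
    curve_id="limb", distance=x, force=force, window=51,
    metadata={"force_noise_sd": 5.0},
)
fit = fit_wlc(curve, (0, x.size - 1))

print(f"true contour length : {L_true:.2f} nm = 148 aa")
print(f"fitted contour length: {fit.L:.2f} nm = {fit.L_aa:.1f} aa")
print(f"residual sum of squares: {fit.rss:.0f} pN^2 over {fit.n_points} points")
print(
    "\nThe fitted L converts to amino acids at 0.36 nm/aa; the ~0.5 nm window\n"
    "of agreement is what lets events be matched across curves within 5 aa."
)
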