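"""Worm-Like Chain (WLC) polymer elasticity model.

The WLC interpolation formula relates the stretching force F to the
extension x of a polymer with contour length L and persistence length p:

    F(x) = (kBT / p) * [ 1 / (4 (1 - x/L)^2) - 1/4 + x/L ]

F is in pN when p and x are in nm and kBT in pN*nm.  The force is zero at
x = 0, strictly increasing in x, and diverges as x -> L.  Unfolded
polypeptide contour length converts to amino acids at ~0.36 nm/aa.
"""

from __future__ import annotations

import numpy as np

#: thermal energy at room temperature (~298 K), pN*nm
KBT_ROOM = 4.114
#: persistence length commonly used for unfolded polypeptide, nm
DEFAULT_PERSISTENCE = 0.4
#: contour length of one amino acid along the stretched backbone, nm
NM_PER_AA = 0.36


def wlc_force(x, L, p=DEFAULT_PERSISTENCE, kBT=KBT_ROOM):
    """Force (pN) of a WLC with contour length ``L`` at extension ``x`` (nm).

    ``x`` may be a scalar or array; every value must satisfy 0 <= x < L.

    Raises
    ------
    ValueError
        If ``x`` is outside [0, L) or parameters are non-positive.
    """
    if L <= 0 or p <= 0 or kBT <= 0:
        raise ValueError(f"L, p, kBT must be positive (got L={L}, p={p}, kBT={kBT})")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x >= L):
        raise ValueError(f"extension must satisfy 0 <= x < L={L}")
    t = x / L
    f = (kBT / p) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    return f if f.ndim else float(f)


def wlc_extension_fraction(F, p=DEFAULT_PERSISTENCE, kBT=KBT_ROOM):
    """Relative extension t = x/L at which the WLC force equals ``F`` (pN).

    Inverts the interpolation formula numerically (monotone bisection);
    accepts scalars or arrays, F >= 0.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ValueError("force must be non-negative")
    scalar = F.ndim == 0
    F = np.atleast_1d(F)
    lo = np.zeros_like(F)
    hi = np.full_like(F, 1.0 - 1e-12)
    for _ in range(80):  # bisection: monotone, bracketed, ~1e-24 resolution
        mid = 0.5 * (lo + hi)
        fmid = (kBT / p) * (0.25 / (1.0 - mid) ** 2 - 0.25 + mid)
        high = fmid > F
        hi[high] = mid[high]
        lo[~high] = mid[~high]
    t = 0.5 * (lo + hi)
    return float(t[0]) if scalar else t
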