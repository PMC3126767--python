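"""Denoising, resampling, and overall-length filtering of F-D curves.

Each raw curve is modelled as a 2-D parametric curve c(x) = [dist(x),
force(x)] over the acquisition timeline x.  Both channels are smoothed
independently with robust locally weighted linear regression (RLOWESS,
bisquare reweighting) over a span of ``window`` raw samples, then linearly
interpolated on the timeline to a fixed 50,000-point representation.

Dataset filtering keeps curves whose overall unfolded length falls in a
configured amino-acid window (default 180-220 aa at 0.36 nm/aa), which for
bacteriorhodopsin selects molecules picked up by the C-terminus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ConfigError
from .io import RawCurve
from .wlc import NM_PER_AA

DEFAULT_WINDOW = 51
DEFAULT_RESAMPLE = 50_000
#: robust (bisquare) reweighting iterations for RLOWESS
ROBUST_ITERATIONS = 5
#: fraction of trailing samples assumed to be detached baseline
TAIL_FRACTION = 0.05
#: noise floor = NOISE_SIGMA x std(force) over the detached tail
NOISE_SIGMA = 3.0


@dataclass
class DenoisedCurve:
    """A smoothed, fixed-length (n_resample) curve representation."""

    curve_id: str
    distance: np.ndarray
    force: np.ndarray
    window: int
    n_raw: int | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_resample(self) -> int:
        return self.distance.size

    @property
    def min_feature_samples(self) -> int:
        """Shortest force feature the smoothing can represent, in
        resampled samples (half the window, scaled by the resampling)."""
        if not self.n_raw:
            return 1
        return max(1, int(0.5 * self.window * self.n_resample / self.n_raw))


def denoise(
    curve: RawCurve,
    window: int = DEFAULT_WINDOW,
    n_resample: int = DEFAULT_RESAMPLE,
    robust_iters: int = ROBUST_ITERATIONS,
) -> DenoisedCurve:
    """RLOWESS-smooth both channels over the timeline and resample.

    ``window`` is a span in raw samples; it must be odd and satisfy
    3 <= window < n_samples (an even window is an explicit error, not
    auto-incremented).  The smoothed channels are linearly interpolated
    jointly on the timeline index to ``n_resample`` points, so they remain
    paired; resampled endpoints equal the smoothed endpoints.
    """
    n = curve.n_samples
    if window % 2 == 0:
        raise ConfigError(f"window must be odd, got {window}")
    if window < 3 or window >= n:
        raise ConfigError(f"window must satisfy 3 <= window < n_samples={n}")
    x = np.arange(n, dtype=float)
    frac = window / n
    smooth_d = lowess(curve.distance, x, frac=frac, it=robust_iters, return_sorted=False)
    smooth_f = lowess(curve.force, x, frac=frac, it=robust_iters, return_sorted=False)
    t = np.linspace(0.0, n - 1.0, n_resample)
    metadata = dict(curve.metadata)
    # robust raw-noise scale from the smoothing residuals (MAD-based)
    resid = curve.force - smooth_f
    metadata["force_noise_sd"] = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    return DenoisedCurve(
        curve_id=curve.curve_id,
        distance=np.interp(t, x, smooth_d),
        force=np.interp(t, x, smooth_f),
        window=window,
        n_raw=n,
        metadata=metadata,
    )


#: variance reduction factor of locally weighted linear smoothing
_LOWESS_VAR_FACTOR = 1.2


def tail_noise_floor(
    force: np.ndarray,
    tail_fraction: float = TAIL_FRACTION,
    sigma: float = NOISE_SIGMA,
) -> float:
    """``sigma`` times the force standard deviation over the final
    ``tail_fraction`` of samples (assumed detached baseline)."""
    ntail = max(2, int(round(tail_fraction * force.size)))
    return sigma * float(np.std(force[-ntail:]))


def noise_floor(curve, sigma: float = NOISE_SIGMA) -> float:
    """Force threshold below which samples are considered baseline.

    For a :class:`DenoisedCurve` carrying the raw-residual noise scale,
    the floor is ``sigma`` times the standard deviation expected of the
    *smoothed* noise (raw sd shrunk by the smoothing span).  A plain
    force array, or a curve without that metadata, falls back to the
    trailing-baseline estimate, which is far noisier because the
    smoothed tail holds only a handful of independent values.
    """
    if isinstance(curve, np.ndarray):
        return tail_noise_floor(curve, sigma=sigma)
    sd = curve.metadata.get("force_noise_sd") if curve.metadata else None
    if sd is None or not curve.window:
        return tail_noise_floor(curve.force, sigma=sigma)
    return sigma * float(sd) * float(np.sqrt(_LOWESS_VAR_FACTOR / curve.window))


def overall_length_aa(
    curve: DenoisedCurve,
    aa_nm: float = NM_PER_AA,
    sigma: float = NOISE_SIGMA,
) -> float:
    """Overall unfolded length of a curve in amino acids.

    The maximum tip-sample separation at which the force still exceeds the
    noise floor *over a sustained run*, divided by the nm/aa conversion.
    Because the smoothed noise is correlated over the smoothing span,
    isolated excursions shorter than half the smoothing window (in
    resampled samples) are not treated as signal.  A flat curve returns 0.
    """
    floor = noise_floor(curve, sigma=sigma)
    above = curve.force > max(floor, 0.0)
    if not np.any(above):
        return 0.0
    min_run = curve.min_feature_samples
    edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
    starts, ends = edges[::2], edges[1::2]  # exclusive ends
    good = np.flatnonzero(ends - starts >= min_run)
    if good.size == 0:
        return 0.0
    last = ends[good[-1]] - 1
    return float(curve.distance[last]) / aa_nm


def write_denoised(curve: DenoisedCurve, path, precision: int = 6) -> None:
    """Persist a denoised curve as TSV with its metadata in comments."""
    with open(path, "w") as fh:
        fh.write(f"# window = {curve.window}\n")
        if curve.n_raw:
            fh.write(f"# n_raw = {curve.n_raw}\n")
        sd = curve.metadata.get("force_noise_sd")
        if sd is not None:
            fh.write(f"# force_noise_sd = {sd:.6g}\n")
        fh.write("distance_nm\tforce_pN\n")
        fmt = f"%.{precision}f\t%.{precision}f\n"
        for d, f in zip(curve.distance, curve.force):
            fh.write(fmt % (d, f))


def read_denoised(path) -> DenoisedCurve:
    """Load a curve written by :func:`write_denoised`."""
    from .io import read_curve

    raw = read_curve(path)
    meta = raw.metadata
    return DenoisedCurve(
        curve_id=raw.curve_id,
        distance=raw.distance,
        force=raw.force,
        window=int(meta.get("window", DEFAULT_WINDOW)),
        n_raw=int(meta["n_raw"]) if "n_raw" in meta else None,
        metadata={
            k: (float(v) if k == "force_noise_sd" else v)
            for k, v in meta.items()
            if k not in ("window", "n_raw", "header")
        },
    )


def filter_curves(
    dataset: list[DenoisedCurve],
    min_aa: float = 180.0,
    max_aa: float = 220.0,
    aa_nm: float = NM_PER_AA,
):
    """Keep curves whose overall length lies in [min_aa, max_aa] (inclusive).

    Returns ``(kept, rejections)`` where rejections is a list of
    ``(curve_id, length_aa)`` for the excluded curves.
    """
    if not min_aa < max_aa:
        raise ConfigError("min_aa must be < max_aa")
    kept, rejections = [], []
    for curve in dataset:
        length = overall_length_aa(curve, aa_nm=aa_nm)
        if min_aa <= length <= max_aa:
            kept.append(curve)
        else:
            rejections.append((curve.curve_id, length))
    return kept, rejections
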