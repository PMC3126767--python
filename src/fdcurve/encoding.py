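"""Derivative-space encoding of F-D curves into A/B/C fragments.

A denoised curve is re-parameterised by arc length after min-max
normalisation of both axes, so the tangent components (dist', force')
are bounded in [-1, 1].  The derivative space is discretised into
``n_bins`` uniform bins per axis; a maximal run of samples sharing the
same (dx_bin, dy_bin) pair forms one *derivative cell*, annotated with
the arc length it covers.  Cells covering less than a fraction
``t_small`` of the total arc length are pruned (merged into the
preceding retained cell).

Retained cells are then banded by their force-derivative bin into
rising / constant / falling, and transitions between maximal bands emit
symbolic fragments:

* ``A`` - local force maximum (a rupture peak),
* ``B`` - local force minimum (the separator between events),
* ``C`` - a cliff of constant force interrupting a monotone stretch.

Because min-max normalisation removes any translation of the curve, the
fragment sequence is exactly invariant under translation of the input,
and multiplying force by a positive constant leaves it unchanged too.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, DegenerateCurveError, EncodingError
from .preprocess import DenoisedCurve


@dataclass(frozen=True)
class EncodingConfig:
    """Parameters of the derivative discretisation.

    n_bins
        Bins per derivative axis over [-1, 1].
    t_small
        Minimum arc length of a retained cell, as a fraction of the total
        curve arc length.
    const_band
        Half-width, in bins, of the "constant force" band around the
        zero-force-derivative bin.
    """

    n_bins: int = 1000
    t_small: float = 0.005
    const_band: int = 445
    #: half-width (in samples) of the secant used for the tangent estimate,
    #: as a fraction of the unit-speed sample count; tempers residual
    #: smoothing noise in the derivative without blurring transitions
    deriv_halfwin_frac: float = 0.002

    def __post_init__(self):
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")
        if not 0.0 <= self.t_small < 1.0:
            raise ConfigError("t_small must be in [0, 1)")
        if not 1 <= self.const_band < self.n_bins / 2:
            raise ConfigError("const_band must be in [1, n_bins/2)")
        if not 0.0 <= self.deriv_halfwin_frac < 0.1:
            raise ConfigError("deriv_halfwin_frac must be in [0, 0.1)")


@dataclass
class UnitCurve:
    """Arc-length (unit-speed) parameterised, min-max normalised curve.

    ``index_map`` maps each unit-speed sample back to a (fractional)
    sample index of the originating denoised curve, and ``force_orig``
    keeps the un-normalised force for peak extraction.
    """

    curve_id: str
    distance: np.ndarray
    force: np.ndarray
    ds: float
    index_map: np.ndarray
    force_orig: np.ndarray
    total_arc: float


@dataclass
class DerivativeCell:
    """One derivative cell: a bin pair plus the arc length it covers.

    ``start_index``/``end_index`` are the covered sample span of the
    denoised curve (inclusive).
    """

    dx_bin: int
    dy_bin: int
    arc_length: float
    start_index: int
    end_index: int


@dataclass(frozen=True)
class Fragment:
    kind: str  # 'A' | 'B' | 'C'
    start_index: int
    end_index: int
    peak_index: int


@dataclass
class FragmentSeq:
    curve_id: str
    fragments: list[Fragment] = field(default_factory=list)

    def pattern(self) -> str:
        return "".join(f.kind for f in self.fragments)


def to_unit_speed(curve: DenoisedCurve, n_points: int | None = None) -> UnitCurve:
    """Re-parameterise a curve at unit speed on min-max normalised axes.

    Both axes are scaled to [0, 1]; the samples are re-spaced so that
    consecutive points are equidistant in arc length.  On the result,
    |dist'| <= 1, |force'| <= 1, and dist'^2 + force'^2 = 1 (up to
    discretisation error).
    """
    d = np.asarray(curve.distance, dtype=float)
    f = np.asarray(curve.force, dtype=float)
    if d.size < 2:
        raise DegenerateCurveError("need at least 2 samples")
    d_ext = d.max() - d.min()
    f_ext = f.max() - f.min()
    if d_ext == 0 or f_ext == 0:
        raise DegenerateCurveError("curve has zero extent on an axis")
    dn = (d - d.min()) / d_ext
    fn = (f - f.min()) / f_ext
    seg = np.hypot(np.diff(dn), np.diff(fn))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = float(s[-1])
    n = n_points or d.size
    s_new = np.linspace(0.0, total, n)
    return UnitCurve(
        curve_id=curve.curve_id,
        distance=np.interp(s_new, s, dn),
        force=np.interp(s_new, s, fn),
        ds=total / (n - 1),
        index_map=np.interp(s_new, s, np.arange(d.size, dtype=float)),
        force_orig=np.interp(s_new, s, f),
        total_arc=total,
    )


def unit_derivatives(
    unit: UnitCurve, halfwin: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Tangent components (dist', force') of a unit-speed curve.

    With ``halfwin`` > 0 the tangent at each sample is the secant over
    +-halfwin samples (clipped at the ends), which suppresses residual
    noise in the derivative; the components are renormalised to unit
    length so they stay within [-1, 1].
    """
    n = unit.distance.size
    if halfwin > 0:
        idx = np.arange(n)
        lo = np.clip(idx - halfwin, 0, n - 1)
        hi = np.clip(idx + halfwin, 0, n - 1)
        dd = unit.distance[hi] - unit.distance[lo]
        df = unit.force[hi] - unit.force[lo]
    else:
        dd = np.gradient(unit.distance, unit.ds)
        df = np.gradient(unit.force, unit.ds)
    norm = np.hypot(dd, df)
    norm[norm == 0] = 1.0
    return dd / norm, df / norm


def derivative_bin(d: np.ndarray, n_bins: int) -> np.ndarray:
    """Uniform bin index over [-1, 1]: floor((d+1)/2 * n_bins), clamped."""
    idx = np.floor((np.asarray(d) + 1.0) / 2.0 * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def derivative_cells(unit: UnitCurve, config: EncodingConfig) -> list[DerivativeCell]:
    """Discretise a unit-speed curve into derivative cells.

    A new cell opens exactly when either bin index changes; each cell
    records the arc length it covers and its sample span in the denoised
    curve.  A perfectly linear curve yields exactly one cell.
    """
    halfwin = int(round(config.deriv_halfwin_frac * unit.distance.size))
    dd, df = unit_derivatives(unit, halfwin=halfwin)
    bx = derivative_bin(dd, config.n_bins)
    by = derivative_bin(df, config.n_bins)
    change = np.flatnonzero((np.diff(bx) != 0) | (np.diff(by) != 0)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [bx.size]])  # exclusive
    n = bx.size
    cells = []
    for a, b in zip(starts, ends):
        # arc counts sample *intervals*, so the final cell has one fewer
        n_intervals = min(b, n - 1) - a
        cells.append(
            DerivativeCell(
                dx_bin=int(bx[a]),
                dy_bin=int(by[a]),
                arc_length=float(n_intervals * unit.ds),
                start_index=int(round(unit.index_map[a])),
                end_index=int(round(unit.index_map[b - 1])),
            )
        )
    return cells


def prune_small_cells(
    cells: list[DerivativeCell], config: EncodingConfig
) -> list[DerivativeCell]:
    """Merge cells covering less than t_small of the total arc length.

    A small cell is absorbed by the preceding retained cell (its arc
    length added, the span extended); the first cell is never pruned.
    Raises :class:`EncodingError` when every cell falls below the
    threshold (over-aggressive ``t_small``).
    """
    if not cells:
        raise EncodingError("empty cell sequence")
    total = sum(c.arc_length for c in cells)
    threshold = config.t_small * total
    if all(c.arc_length < threshold for c in cells):
        raise EncodingError(
            f"all {len(cells)} cells below t_small={config.t_small}; "
            "threshold is over-aggressive for this curve"
        )
    out = [replace(cells[0])]
    for cell in cells[1:]:
        if cell.arc_length < threshold:
            prev = out[-1]
            prev.arc_length += cell.arc_length
            prev.end_index = cell.end_index
        else:
            out.append(replace(cell))
    return out


def _band(dy_bin: int, config: EncodingConfig) -> str:
    center = config.n_bins // 2
    if dy_bin > center + config.const_band:
        return "r"
    if dy_bin < center - config.const_band:
        return "f"
    return "c"


def _coalesce(runs: list[dict]) -> list[dict]:
    out: list[dict] = []
    for run in runs:
        if out and out[-1]["band"] == run["band"]:
            out[-1]["end"] = run["end"]
            out[-1]["arc"] += run["arc"]
        else:
            out.append(dict(run))
    return out


def _arc_smooth(runs: list[dict], threshold: float) -> list[dict]:
    """Merge runs covering less arc than ``threshold`` into neighbours,
    smallest first, re-coalescing equal-band neighbours."""
    runs = [dict(r) for r in runs]
    while len(runs) > 1:
        small = [i for i, r in enumerate(runs) if r["arc"] < threshold]
        if not small:
            break
        i = min(small, key=lambda k: runs[k]["arc"])
        if 0 < i < len(runs) - 1 and runs[i - 1]["band"] == runs[i + 1]["band"]:
            runs[i - 1]["arc"] += runs[i]["arc"] + runs[i + 1]["arc"]
            runs[i - 1]["end"] = runs[i + 1]["end"]
            del runs[i : i + 2]
        elif i == 0:
            runs[1]["arc"] += runs[0]["arc"]
            runs[1]["start"] = runs[0]["start"]
            del runs[0]
        elif i == len(runs) - 1:
            runs[i - 1]["arc"] += runs[i]["arc"]
            runs[i - 1]["end"] = runs[i]["end"]
            del runs[i]
        else:
            j = i - 1 if runs[i - 1]["arc"] >= runs[i + 1]["arc"] else i + 1
            runs[j]["arc"] += runs[i]["arc"]
            if j < i:
                runs[j]["end"] = runs[i]["end"]
            else:
                runs[j]["start"] = runs[i]["start"]
            del runs[i]
    return runs


def band_runs(
    cells: list[DerivativeCell],
    config: EncodingConfig,
    force: np.ndarray | None = None,
    min_trend_force: float = 0.0,
) -> list[dict]:
    """Arc-smoothed maximal rising/constant/falling runs over cells.

    Each cell is banded by its force-derivative bin and consecutive
    same-band cells coalesce into runs carrying the summed arc length.
    Two cleanups then remove noise texture: rising/falling runs whose
    net force change stays below ``min_trend_force`` are relabelled
    constant (residual noise cannot sustain a real limb or rupture), and
    runs covering less than ``t_small`` of the total arc length are
    merged into their neighbours.  The relabelling runs first so that a
    noise-chopped plateau can coalesce into one constant run before the
    arc threshold is applied.
    """
    runs: list[dict] = [
        {
            "band": _band(c.dy_bin, config),
            "start": c.start_index,
            "end": c.end_index,
            "arc": c.arc_length,
        }
        for c in cells
    ]
    runs = _coalesce(runs)
    if force is not None and min_trend_force > 0:
        for run in runs:
            if run["band"] in ("r", "f"):
                net = abs(float(force[run["end"]]) - float(force[run["start"]]))
                if net < min_trend_force:
                    run["band"] = "c"
        runs = _coalesce(runs)
    total = sum(r["arc"] for r in runs)
    return _arc_smooth(runs, config.t_small * total)


def classify_fragments(
    cells: list[DerivativeCell],
    config: EncodingConfig,
    force: np.ndarray | None = None,
    curve_id: str = "",
    min_trend_force: float = 0.0,
) -> FragmentSeq:
    """Reduce a cell sequence to A/B/C fragments.

    Cells are banded rising/constant/falling by their force-derivative
    bin and coalesced into arc-smoothed maximal runs (see
    :func:`band_runs`); the runs are reduced to fragments:

    * rising -> falling emits ``A`` at the transition (peak);
    * falling -> rising emits ``B`` (valley);
    * a constant run between two rising runs or two falling runs emits
      ``C`` (a cliff interrupting a monotone stretch);
    * a constant run between rising and falling is a rounded peak top and
      emits ``A``; between falling and rising it is a flat valley floor
      and emits ``B``;
    * leading/trailing runs that complete no transition emit nothing.

    ``force`` (denoised force values, indexed by the cell spans) is used
    to place ``peak_index`` at the extreme force inside each fragment;
    without it the span midpoint is used.  With ``min_trend_force`` > 0
    (and ``force`` given), rising/falling runs whose net force change
    stays below that threshold are relabelled constant before emission -
    residual noise cannot sustain a real rupture or limb, so such runs
    are plateau or baseline texture.
    """

    def extreme(lo: int, hi: int, which: str) -> int:
        if force is None or hi < lo:
            return (lo + hi) // 2
        seg = force[lo : hi + 1]
        off = int(np.argmax(seg) if which == "max" else np.argmin(seg))
        return lo + off

    runs = band_runs(cells, config, force=force, min_trend_force=min_trend_force)

    fragments: list[Fragment] = []
    for i, run in enumerate(runs):
        if run["band"] == "c":
            prev = runs[i - 1] if i > 0 else None
            nxt = runs[i + 1] if i + 1 < len(runs) else None
            if prev is None or nxt is None:
                continue  # baseline lead-in / tail
            pair = (prev["band"], nxt["band"])
            if pair in (("r", "r"), ("f", "f")):
                peak = extreme(run["start"], run["end"], "max")
                fragments.append(Fragment("C", run["start"], run["end"], peak))
            elif pair == ("r", "f"):
                # a flat top wide enough to survive arc smoothing is a
                # cliff whose end coincides with the rupture: C then A
                peak = extreme(run["end"], nxt["start"], "max")
                fragments.append(Fragment("C", run["start"], run["end"], run["end"]))
                fragments.append(Fragment("A", run["end"], max(peak, run["end"]), max(peak, run["end"])))
            elif pair == ("f", "r"):
                valley = extreme(run["start"], run["end"], "min")
                fragments.append(Fragment("B", run["start"], run["end"], valley))
        elif i + 1 < len(runs) and runs[i + 1]["band"] != "c":
            nxt = runs[i + 1]
            if run["band"] == "r" and nxt["band"] == "f":
                peak = extreme(run["start"], nxt["end"], "max")
                fragments.append(Fragment("A", run["start"], peak, peak))
            elif run["band"] == "f" and nxt["band"] == "r":
                valley = extreme(run["start"], nxt["end"], "min")
                fragments.append(Fragment("B", valley, valley, valley))

    # enforce ordered, non-overlapping spans
    cleaned: list[Fragment] = []
    for frag in fragments:
        if cleaned and frag.start_index <= cleaned[-1].end_index:
            frag = replace(frag, start_index=min(cleaned[-1].end_index + 1, frag.end_index))
        cleaned.append(frag)
    return FragmentSeq(curve_id=curve_id, fragments=cleaned)


def encode(
    curve: DenoisedCurve, config: EncodingConfig | None = None
) -> tuple[list[DerivativeCell], FragmentSeq]:
    """Full encoding chain: unit-speed -> cells -> fragments.

    The fragment classifier consumes the full arc-annotated cell
    sequence and applies the ``t_small`` arc threshold at the band-run
    level (see :func:`band_runs`), so no cell-level information is
    discarded before banding.
    """
    config = config or EncodingConfig()
    from .preprocess import noise_floor

    unit = to_unit_speed(curve)
    cells = derivative_cells(unit, config)
    frags = classify_fragments(
        cells,
        config,
        force=curve.force,
        curve_id=curve.curve_id,
        min_trend_force=2.0 * noise_floor(curve),
    )
    return cells, frags
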