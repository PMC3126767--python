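"""Unfolding-event grammar and Worm-Like Chain contour-length fits.

Fragment sequences parse into three event types (one event per ``A``):

* type I   - a bare main peak ``AB``;
* type II  - ``CAB``: a constant-force cliff directly before the peak,
  the side peak being the ``CA`` part (stepwise unfolding);
* type III - ``ACB``: a cliff in the drop after the peak, the side peak
  being ``AC`` (one helix unfolds gradually, the next all-or-none).

Each peak's rising limb is fitted with the WLC interpolation formula,
with the persistence length and thermal energy held fixed, to obtain the
contour length L of the already-unfolded polypeptide; L converts to a
position in the amino-acid sequence at 0.36 nm/aa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import preprocess
from .encoding import Fragment, FragmentSeq
from .errors import FitError
from .preprocess import DenoisedCurve
from .wlc import DEFAULT_PERSISTENCE, KBT_ROOM, NM_PER_AA, wlc_force

logger = logging.getLogger(__name__)

MIN_FIT_SAMPLES = 10
#: max sample gap between a C cliff and a following A for CAB adjacency
DEFAULT_ADJACENCY_GAP = 50
#: cap on fitted points per limb (evenly subsampled) for speed
MAX_FIT_POINTS = 500


@dataclass(frozen=True)
class WLCConfig:
    persistence: float = DEFAULT_PERSISTENCE
    kBT: float = KBT_ROOM
    aa_nm: float = NM_PER_AA


@dataclass
class WLCFit:
    """Result of a single-parameter (contour length) WLC fit."""

    L: float  # contour length, nm
    p: float  # persistence length, nm
    kBT: float  # thermal energy, pN*nm
    aa_nm: float  # conversion, nm per amino acid
    rss: float  # residual sum of squares, pN^2
    n_points: int

    @property
    def L_aa(self) -> float:
        return self.L / self.aa_nm


@dataclass
class EventSkeleton:
    """A typed event before WLC fits are attached."""

    event_type: str  # 'I' | 'II' | 'III'
    a_fragment: Fragment
    c_fragment: Fragment | None
    limb_start: int  # first sample of the main rising limb
    side_start: int = 0  # first sample of the side branch (type II)


@dataclass
class UnfoldingEvent:
    curve_id: str
    event_type: str
    main_fit: WLCFit
    side_fit: WLCFit | None
    main_position_aa: float
    side_position_aa: float | None
    peak_force: float

    def positions(self) -> list[float]:
        """All event positions (side first for type II, after for III)."""
        if self.side_position_aa is None:
            return [self.main_position_aa]
        return sorted([self.main_position_aa, self.side_position_aa])

    def to_record(self) -> dict:
        return {
            "curve_id": self.curve_id,
            "event_type": self.event_type,
            "main_position_aa": round(self.main_position_aa, 3),
            "side_position_aa": None
            if self.side_position_aa is None
            else round(self.side_position_aa, 3),
            "peak_force_pN": round(self.peak_force, 3),
            "main_L_nm": round(self.main_fit.L, 4),
            "main_rss": round(self.main_fit.rss, 3),
            "side_L_nm": None if self.side_fit is None else round(self.side_fit.L, 4),
        }


def parse_events(
    frags: FragmentSeq, adjacency_gap: int = DEFAULT_ADJACENCY_GAP
) -> list[EventSkeleton]:
    """Scan a fragment sequence left to right into typed event skeletons.

    One event is emitted per ``A`` fragment.  A ``C`` that is
    span-adjacent before an ``A`` (gap <= ``adjacency_gap`` samples) makes
    it type II; otherwise a ``C`` immediately after the ``A`` (before the
    closing ``B``) makes it type III.  A trailing ``A`` without a closing
    ``B`` still closes the final event (the last rupture may end at
    detachment).  Unconsumed ``C`` fragments are logged as orphans.
    """
    fragments = frags.fragments
    consumed = [False] * len(fragments)
    # pass 1: claim C's that serve as type II side cliffs
    ii_side: dict[int, int] = {}  # A index -> C index
    for i, frag in enumerate(fragments):
        if frag.kind != "A":
            continue
        j = i - 1
        if (
            j >= 0
            and fragments[j].kind == "C"
            and not consumed[j]
            and frag.start_index - fragments[j].end_index <= adjacency_gap
        ):
            ii_side[i] = j
            consumed[j] = True
    events: list[EventSkeleton] = []
    prev_boundary = 0  # sample after the previous event's fragments
    for i, frag in enumerate(fragments):
        if frag.kind == "B":
            prev_boundary = frag.end_index + 1
            continue
        if frag.kind != "A":
            continue
        consumed[i] = True
        if i in ii_side:
            # the main limb of a type II event starts after its cliff;
            # samples before the cliff belong to the side branch
            c = fragments[ii_side[i]]
            events.append(
                EventSkeleton(
                    "II", frag, c, limb_start=c.end_index + 1, side_start=prev_boundary
                )
            )
        elif i + 1 < len(fragments) and fragments[i + 1].kind == "C" and not consumed[i + 1]:
            c = fragments[i + 1]
            consumed[i + 1] = True
            events.append(EventSkeleton("III", frag, c, limb_start=prev_boundary))
        else:
            events.append(EventSkeleton("I", frag, None, limb_start=prev_boundary))
    orphans = [i for i, (f, c) in enumerate(zip(fragments, consumed)) if f.kind == "C" and not c]
    for i in orphans:
        logger.info(
            "%s: orphan C fragment at samples %d-%d ignored",
            frags.curve_id,
            fragments[i].start_index,
            fragments[i].end_index,
        )
    return events


def clean_fragments(
    frags: FragmentSeq,
    force: np.ndarray,
    floor: float,
    prominence_factor: float = 2.0,
    cliff_force_factor: float = 2.0,
) -> FragmentSeq:
    """Drop fragments that residual smoothing noise can produce.

    * an ``A`` whose force drop to the following minimum (before the
      next ``A`` or the curve end) is below ``prominence_factor`` times
      the noise floor is not a rupture;
    * a ``C`` whose mean force is below ``cliff_force_factor`` times the
      noise floor is baseline texture, not an unfolding intermediate;
    * after removals, runs of consecutive ``B`` collapse onto the
      lowest-force one, restoring A/B alternation.
    """
    fragments = list(frags.fragments)
    fragments = [
        f
        for f in fragments
        if not (
            f.kind == "C"
            and float(np.mean(force[f.start_index : f.end_index + 1])) < cliff_force_factor * floor
        )
    ]
    changed = True
    while changed:
        changed = False
        a_idx = [i for i, f in enumerate(fragments) if f.kind == "A"]
        for pos, i in enumerate(a_idx):
            peak = float(force[fragments[i].peak_index])
            end = (
                fragments[a_idx[pos + 1]].peak_index
                if pos + 1 < len(a_idx)
                else force.size - 1
            )
            drop = peak - float(np.min(force[fragments[i].peak_index : end + 1]))
            if drop < prominence_factor * floor:
                del fragments[i]
                changed = True
                break
    # collapse consecutive B fragments (no A between) onto the deepest one
    out: list[Fragment] = []
    for frag in fragments:
        if (
            frag.kind == "B"
            and out
            and out[-1].kind == "B"
        ):
            if float(force[frag.peak_index]) < float(force[out[-1].peak_index]):
                out[-1] = frag
            continue
        out.append(frag)
    return FragmentSeq(curve_id=frags.curve_id, fragments=out)


def _fit_wlc_arrays(
    x: np.ndarray, f: np.ndarray, p: float, kBT: float, aa_nm: float
) -> WLCFit:
    if x.size < MIN_FIT_SAMPLES:
        raise FitError(f"only {x.size} samples on limb (need >= {MIN_FIT_SAMPLES})")
    if np.max(f) <= 0:
        raise FitError("no positive forces on limb")
    if x.size > MAX_FIT_POINTS:
        idx = np.linspace(0, x.size - 1, MAX_FIT_POINTS).round().astype(int)
        x, f = x[idx], f[idx]
    xmax = float(np.max(x))
    if xmax <= 0:
        raise FitError("limb has non-positive extensions")

    def rss_of(u: float) -> float:
        # u = xmax / L in (0, 1)
        L = xmax / u
        resid = wlc_force(x, L, p, kBT) - f
        return float(np.dot(resid, resid))

    res = minimize_scalar(rss_of, bounds=(1e-4, 1.0 - 1e-9), method="bounded",
                          options={"xatol": 1e-10})
    if not res.success:
        raise FitError(f"WLC fit did not converge: {res.message}")
    u = float(res.x)
    if u <= 2e-4:
        raise FitError("WLC fit ran to the long-contour boundary (flat limb?)")
    L = xmax / u
    return WLCFit(L=L, p=p, kBT=kBT, aa_nm=aa_nm, rss=float(res.fun), n_points=x.size)


def fit_wlc(
    curve: DenoisedCurve,
    span: tuple[int, int],
    p: float = DEFAULT_PERSISTENCE,
    kBT: float = KBT_ROOM,
    aa_nm: float = NM_PER_AA,
) -> WLCFit:
    """Least-squares fit of the contour length L over a rising-limb span.

    ``span`` is an inclusive sample range of the denoised curve.  p and
    kBT are held fixed; only L varies.  Raises :class:`FitError` on
    degenerate input or non-convergence.
    """
    lo, hi = span
    x = curve.distance[lo : hi + 1]
    f = curve.force[lo : hi + 1]
    return _fit_wlc_arrays(np.asarray(x, float), np.asarray(f, float), p, kBT, aa_nm)


def _trimmed_limb(curve, lo, hi, floor, rel_frac=0.0):
    """Limb samples above the noise floor and, with ``rel_frac`` set,
    above that fraction of the limb's own top force (which shields the
    contour-length fit from any earlier branch or undetected plateau)."""
    x = curve.distance[lo : hi + 1]
    f = curve.force[lo : hi + 1]
    cut = floor
    if rel_frac > 0 and f.size:
        cut = max(floor, rel_frac * float(np.max(f)))
    keep = (f > cut) & (x > 0)
    return x[keep], f[keep]


def attach_fits(
    skeletons: list[EventSkeleton],
    curve: DenoisedCurve,
    config: WLCConfig | None = None,
    min_separation_aa: float = 5.0,
    limb_top_frac: float = 0.8,
) -> list[UnfoldingEvent]:
    """Fit the WLC model to each skeleton's limbs and build events.

    The main fit covers the rising limb ending at the A peak (for type II,
    the limb after the cliff).  The side fit covers the limb before the
    cliff (type II) or the cliff itself, referenced to its exit (type
    III).  Limbs are trimmed to forces above the curve's noise floor;
    events whose main fit fails are dropped with a log entry, and events
    are returned ordered by strictly increasing main position.
    """
    config = config or WLCConfig()
    floor = preprocess.noise_floor(curve)
    events: list[UnfoldingEvent] = []
    for sk in skeletons:
        a = sk.a_fragment
        peak_force = float(curve.force[a.peak_index])
        if peak_force <= floor:
            logger.info("%s: dropped sub-noise peak at sample %d", curve.curve_id, a.peak_index)
            continue
        try:
            x, f = _trimmed_limb(curve, sk.limb_start, a.peak_index, floor, limb_top_frac)
            main_fit = _fit_wlc_arrays(x, f, config.persistence, config.kBT, config.aa_nm)
        except FitError as err:
            main_fit = None
            if sk.event_type == "II":
                # the limb between cliff and rupture can be shorter than
                # the smoothing span; the cliff end then lies on the main
                # branch, so fit the trailing stretch of the cliff itself
                c = sk.c_fragment
                lo = c.start_index + int(0.7 * (c.end_index - c.start_index))
                try:
                    x, f = _trimmed_limb(curve, lo, c.end_index, floor)
                    main_fit = _fit_wlc_arrays(x, f, config.persistence, config.kBT, config.aa_nm)
                except FitError:
                    main_fit = None
            if main_fit is None:
                logger.info("%s: dropped event (main fit failed: %s)", curve.curve_id, err)
                continue
        side_fit = None
        side_pos = None
        if sk.event_type == "II":
            c = sk.c_fragment
            try:
                # stop half a smoothing span short of the cliff: the
                # rounded corner biases the contour length upward
                hi = max(sk.side_start, c.start_index - 1 - curve.min_feature_samples)
                x, f = _trimmed_limb(curve, sk.side_start, hi, floor, limb_top_frac)
                side_fit = _fit_wlc_arrays(x, f, config.persistence, config.kBT, config.aa_nm)
                side_pos = side_fit.L_aa
            except FitError as err:
                logger.info("%s: type II side fit failed (%s); kept as type I", curve.curve_id, err)
            if side_pos is not None and side_pos >= main_fit.L_aa:
                # a real intermediate always precedes its main rupture in
                # contour length; otherwise the "cliff" was noise texture
                # splitting one limb - discard it and refit the whole limb
                side_fit = side_pos = None
                try:
                    x, f = _trimmed_limb(curve, sk.side_start, a.peak_index, floor, limb_top_frac)
                    main_fit = _fit_wlc_arrays(x, f, config.persistence, config.kBT, config.aa_nm)
                except FitError:
                    pass
                logger.info("%s: inverted type II side discarded", curve.curve_id)
        elif sk.event_type == "III":
            c = sk.c_fragment
            lo = c.start_index + int(0.7 * (c.end_index - c.start_index))
            try:
                x, f = _trimmed_limb(curve, lo, c.end_index, floor)
                side_fit = _fit_wlc_arrays(x, f, config.persistence, config.kBT, config.aa_nm)
                side_pos = side_fit.L_aa
            except FitError as err:
                logger.info("%s: type III side fit failed (%s); kept as type I", curve.curve_id, err)
        event_type = sk.event_type if side_fit is not None else "I"
        events.append(
            UnfoldingEvent(
                curve_id=curve.curve_id,
                event_type=event_type,
                main_fit=main_fit,
                side_fit=side_fit,
                main_position_aa=main_fit.L_aa,
                side_position_aa=side_pos,
                peak_force=peak_force,
            )
        )
    events.sort(key=lambda e: e.main_position_aa)
    # noise can split one rupture into near-identical peaks; keep the
    # strongest event of any cluster closer than min_separation
    ordered: list[UnfoldingEvent] = []
    for ev in events:
        if ordered and ev.main_position_aa - ordered[-1].main_position_aa < min_separation_aa:
            if ev.peak_force > ordered[-1].peak_force:
                ordered[-1] = ev
            logger.info(
                "%s: merged duplicate event near %.1f aa", curve.curve_id, ev.main_position_aa
            )
            continue
        ordered.append(ev)
    return ordered


def detect_events(
    curve: DenoisedCurve,
    enc_config=None,
    wlc_config: WLCConfig | None = None,
) -> list[UnfoldingEvent]:
    """Encode a denoised curve and return its fitted unfolding events."""
    from .encoding import encode

    _, frags = encode(curve, enc_config)
    frags = clean_fragments(frags, curve.force, preprocess.noise_floor(curve))
    skeletons = parse_events(frags)
    return attach_fits(skeletons, curve, wlc_config)
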