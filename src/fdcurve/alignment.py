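"""Progressive alignment of per-curve event positions.

Every event position is expressed in amino acids (the WLC contour
length).  Because the cantilever can attach anywhere within a terminal
stretch of the protein, all events of a curve share one unknown offset;
alignment therefore searches a single per-curve shift S (|S| bounded,
default 30 aa) and matches events order-preservingly to the growing
consensus, counting a pair as matched when the shifted distance is
strictly less than the match window (default 5 aa).

Because attachment can only lengthen the tether, the consensus is
finally re-referenced so that the least-offset curve (the one with the
largest positive best shift) sits at zero shift; this pins consensus
positions to absolute contour lengths instead of the seed curve's
arbitrary offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError


@dataclass(frozen=True)
class AlignmentConfig:
    match_window: float = 5.0  # aa, strict "less than"
    max_shift: float = 30.0  # aa
    shift_step: float = 1.0  # aa
    match_score: float = 1.0
    mismatch_score: float = 0.0

    def __post_init__(self):
        if self.match_window <= 0 or self.max_shift < 0 or self.shift_step <= 0:
            raise ConfigError("invalid alignment configuration")


@dataclass
class CurveAlignment:
    curve_id: str
    shift: float  # S, applied uniformly to all curve events (aa)
    matches: list[tuple[int, int]]  # (curve event index, consensus column index)
    score: float


@dataclass
class EventMatrix:
    """Curves x consensus-events binary occupancy."""

    occupancy: pd.DataFrame  # index curve_ids, columns event ids, values 0/1
    positions: pd.Series  # mean consensus position (aa) per column
    reference_shift: float = 0.0

    @property
    def curve_ids(self) -> list[str]:
        return list(self.occupancy.index)

    @property
    def n_support(self) -> pd.Series:
        return self.occupancy.sum(axis=0)


def match_positions(a, b, window: float):
    """Order-preserving matching of two sorted position lists.

    Maximises the number of pairs with |a_i - b_j| < window; ties are
    broken by the smaller total absolute difference.  Returns
    ``(n_matches, total_abs_diff, pairs)`` with pairs as (i, j) tuples.
    """
    a = list(a)
    b = list(b)
    n, m = len(a), len(b)
    # dp[i][j] = best (matches, -total_diff) using a[:i], b[:j]
    dp = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = dp[i - 1][j] if dp[i - 1][j] >= dp[i][j - 1] else dp[i][j - 1]
            d = abs(a[i - 1] - b[j - 1])
            if d < window:
                prev = dp[i - 1][j - 1]
                cand = (prev[0] + 1, prev[1] - d)
                if cand > best:
                    best = cand
            dp[i][j] = best
    # traceback
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        cur = dp[i][j]
        if cur == dp[i - 1][j]:
            i -= 1
        elif cur == dp[i][j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    matches, neg_diff = dp[n][m]
    return matches, -neg_diff, pairs


def score_shift(curve_events, consensus, S: float, config: AlignmentConfig | None = None):
    """Score aligning ``curve_events`` shifted by S against ``consensus``.

    Returns ``(score, pairs, total_abs_diff)``; the score is
    match_score * #matches + mismatch_score * #unmatched curve events.
    """
    config = config or AlignmentConfig()
    shifted = [p + S for p in curve_events]
    matches, diff, pairs = match_positions(shifted, consensus, config.match_window)
    score = config.match_score * matches + config.mismatch_score * (len(shifted) - matches)
    return score, pairs, diff


def best_shift(
    curve_events, consensus, config: AlignmentConfig | None = None, curve_id: str = ""
) -> CurveAlignment:
    """Exhaustive search over S in [-max_shift, +max_shift].

    The shift grid is stepped by ``shift_step``.  Ties in score are
    broken by the smaller total positional discrepancy of the matched
    pairs, then by smaller |S|: with unit match scores many shifts tie
    on the match count, and the discrepancy is what actually pins the
    alignment (preferring small |S| first would bias every shift toward
    zero by up to the match window).
    """
    config = config or AlignmentConfig()
    if len(curve_events) == 0 or len(consensus) == 0:
        return CurveAlignment(curve_id=curve_id, shift=0.0, matches=[], score=0.0)
    n_steps = int(np.floor(config.max_shift / config.shift_step + 1e-9))
    shifts = [k * config.shift_step for k in range(-n_steps, n_steps + 1)]
    shifts.sort(key=lambda s: (abs(s), s))  # equal (score, diff): smaller |S| wins
    best = None  # (score, diff, S, pairs)
    for S in shifts:
        score, pairs, diff = score_shift(curve_events, consensus, S, config)
        if best is None or score > best[0] or (score == best[0] and diff < best[1] - 1e-12):
            best = (score, diff, S, pairs)
    score, _, S, pairs = best
    return CurveAlignment(curve_id=curve_id, shift=S, matches=pairs, score=score)


def progressive_align(
    event_lists: dict,
    config: AlignmentConfig | None = None,
    re_reference: bool = True,
):
    """Align per-curve event position lists into a consensus.

    ``event_lists`` maps curve_id to a sorted list of event positions
    (aa).  Curves are processed in descending event-count order (ties in
    input order); the first curve seeds the consensus, each later curve
    is aligned with :func:`best_shift`, matched consensus positions are
    updated to the running mean of supporting shifted positions, and
    unmatched curve events open new consensus columns.

    Returns ``(EventMatrix, list[CurveAlignment])``.  With
    ``re_reference`` (default), consensus positions are re-expressed
    relative to the least-offset curve (see module docstring).
    """
    config = config or AlignmentConfig()
    if not event_lists:
        raise ConfigError("progressive_align needs at least one curve")
    order = sorted(event_lists, key=lambda cid: -len(event_lists[cid]))

    columns: list[dict] = []  # {'pos': float, 'support': [positions], 'members': {cid}}
    alignments: list[CurveAlignment] = []
    for cid in order:
        positions = sorted(float(p) for p in event_lists[cid])
        consensus_sorted = sorted(range(len(columns)), key=lambda k: columns[k]["pos"])
        consensus_positions = [columns[k]["pos"] for k in consensus_sorted]
        aln = best_shift(positions, consensus_positions, config, curve_id=cid)
        matched_curve_idx = set()
        for ei, cj in aln.matches:
            col = columns[consensus_sorted[cj]]
            col["support"].append(positions[ei] + aln.shift)
            col["pos"] = float(np.mean(col["support"]))
            col["members"].add(cid)
            matched_curve_idx.add(ei)
        for ei, pos in enumerate(positions):
            if ei not in matched_curve_idx:
                columns.append(
                    {"pos": pos + aln.shift, "support": [pos + aln.shift], "members": {cid}}
                )
        alignments.append(aln)

    # columns closer than the match window describe the same unfolding
    # event (two events of one curve are never that close): merge them
    columns.sort(key=lambda c: c["pos"])
    merged: list[dict] = []
    for col in columns:
        if merged and col["pos"] - merged[-1]["pos"] < config.match_window:
            prev = merged[-1]
            prev["support"].extend(col["support"])
            prev["members"] |= col["members"]
            prev["pos"] = float(np.mean(prev["support"]))
        else:
            merged.append(col)
    columns = merged

    ref = 0.0
    if re_reference and alignments:
        # attachment only adds length, so the curve with the largest
        # positive shift is closest to the true origin
        informative = [a.shift for a in alignments if len(a.matches) >= 2]
        ref = max(informative) if informative else max(a.shift for a in alignments)

    col_order = sorted(range(len(columns)), key=lambda k: columns[k]["pos"])
    ids = [f"e{j + 1}" for j in range(len(col_order))]
    positions_out = pd.Series(
        [columns[k]["pos"] - ref for k in col_order], index=ids, name="position_aa"
    )
    curve_ids = list(event_lists)
    occ = pd.DataFrame(0, index=curve_ids, columns=ids, dtype=int)
    for j, k in enumerate(col_order):
        for cid in columns[k]["members"]:
            occ.loc[cid, ids[j]] = 1
    matrix = EventMatrix(occupancy=occ, positions=positions_out, reference_shift=ref)
    return matrix, alignments
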