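"""Shift search, order-preserving matching, and progressive alignment."""

import itertools

import numpy as np
import pytest

from fdcurve.alignment import (
    AlignmentConfig,
    best_shift,
    match_positions,
    progressive_align,
    score_shift,
)

CFG = AlignmentConfig()


# ------------------------------------------------- independent brute force
def _enumerate_matchings(a, b, window):
    """All order-preserving matchings via index combinations (oracle)."""
    best = (0, 0.0)  # (matches, -total_diff)
    for k in range(min(len(a), len(b)), -1, -1):
        for ai in itertools.combinations(range(len(a)), k):
            for bi in itertools.combinations(range(len(b)), k):
                diffs = [abs(a[i] - b[j]) for i, j in zip(ai, bi)]
                if all(d < window for d in diffs):
                    cand = (k, -sum(diffs))
                    if cand > best:
                        best = cand
        if best[0] == k:
            break
    return best[0], -best[1]


def _best_shift_bruteforce(events, consensus, config):
    best = None
    n_steps = int(config.max_shift / config.shift_step)
    for step in range(-n_steps, n_steps + 1):
        S = step * config.shift_step
        shifted = [p + S for p in events]
        m, diff = _enumerate_matchings(shifted, consensus, config.match_window)
        score = config.match_score * m + config.mismatch_score * (len(events) - m)
        key = (-score, diff, abs(S), S)
        if best is None or key < best[0]:
            best = (key, S, score, m)
    return best[1], best[2], best[3]


# -------------------------------------------------------------- score/shift
def test_identity_alignment_scores_all_matches():
    score, pairs, diff = score_shift([80, 143, 215], [80, 143, 215], 0.0, CFG)
    assert score == 3 and len(pairs) == 3 and diff == 0.0


def test_uniform_offset_recovered_by_shift():
    score, pairs, diff = score_shift([85, 148, 220], [80, 143, 215], -5.0, CFG)
    assert score == 3 and diff == 0.0


def test_strict_window_boundary_excludes_exact_window():
    score, pairs, _ = score_shift([80], [86], 0.0, CFG)
    assert score == 0 and pairs == []
    score, pairs, _ = score_shift([80], [84.5], 0.0, CFG)
    assert score == 1


def test_matching_is_order_preserving():
    # crossing would match both; order preservation allows only one
    m, diff, pairs = match_positions([10, 11], [11, 10.2], 5.0)
    assert m == 2
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        assert i1 < i2 and j1 < j2


def test_best_shift_recovers_constructed_offset():
    consensus = [39.0, 80.0, 143.0, 215.0]
    curve = [p + 17 for p in consensus]
    aln = best_shift(curve, consensus, CFG)
    assert aln.shift == -17
    assert len(aln.matches) == 4


def test_offset_beyond_bound_gives_partial_match():
    consensus = [50.0, 100.0, 150.0]
    curve = [p + 40 for p in consensus]
    aln = best_shift(curve, consensus, CFG)
    assert abs(aln.shift) <= CFG.max_shift
    # at S=-30 curve sits at +10: only the accidental 140-vs-150 pair matches
    assert len(aln.matches) < 3


def test_zero_shift_preferred_on_ties():
    aln = best_shift([100.0], [100.0], CFG)
    assert aln.shift == 0.0 and len(aln.matches) == 1


def test_empty_event_list_aligns_trivially():
    aln = best_shift([], [80.0], CFG, curve_id="x")
    assert aln.shift == 0.0 and aln.matches == [] and aln.score == 0.0


# ---------------------------------------------------------- progressive
def test_identical_curves_full_occupancy():
    lists = {f"c{i}": [80.0, 143.0, 215.0] for i in range(3)}
    matrix, alignments = progressive_align(lists, CFG)
    assert list(matrix.positions.round(6)) == [80.0, 143.0, 215.0]
    assert matrix.occupancy.values.sum() == 9
    assert all(a.shift == 0 for a in alignments)


def test_disjoint_curves_union_consensus():
    lists = {"a": [50.0, 100.0], "b": [160.0, 210.0]}
    matrix, _ = progressive_align(lists, CFG, re_reference=False)
    assert len(matrix.positions) == 4
    assert matrix.occupancy.values.sum() == 4
    assert (matrix.occupancy.sum(axis=1) == 2).all()


def test_shift_bound_holds_for_all_alignments(br26):
    for aln in br26["result"].alignments:
        assert abs(aln.shift) <= CFG.max_shift


def test_matched_pairs_respect_window_after_shift(br26):
    result = br26["result"]
    for cid, positions in result.aligned_positions.items():
        row = result.matrix.occupancy.loc[cid]
        for pos in positions:
            # every aligned event position lies within the window of the
            # consensus column it supports
            nearest = min(abs(result.matrix.positions[e] - pos) for e in row.index) if len(row) else None
            if nearest is not None and row.sum() > 0:
                assert nearest < 2 * CFG.match_window


def test_progressive_matches_bruteforce_small_instances(rng):
    config = AlignmentConfig(max_shift=10.0)
    for _ in range(30):
        truth = np.sort(rng.choice(np.arange(20, 200, 12), size=rng.integers(2, 6), replace=False))
        lists = {}
        for c in range(rng.integers(1, 5)):
            take = truth[rng.random(truth.size) < 0.8]
            shift = rng.integers(-8, 9)
            lists[f"c{c}"] = sorted(float(p + shift) for p in take)
        matrix, alignments = progressive_align(lists, config, re_reference=False)
        # replay the progressive protocol with the brute-force matcher
        order = sorted(lists, key=lambda cid: -len(lists[cid]))
        columns = []
        occupancy = {cid: set() for cid in lists}
        for cid in order:
            events = lists[cid]
            cons_sorted = sorted(range(len(columns)), key=lambda k: columns[k]["pos"])
            cons_pos = [columns[k]["pos"] for k in cons_sorted]
            if events and cons_pos:
                S, _, _ = _best_shift_bruteforce(events, cons_pos, config)
                m, diff, pairs = match_positions([p + S for p in events], cons_pos, config.match_window)
            else:
                S, pairs = 0.0, []
            matched = set()
            for ei, cj in pairs:
                col = columns[cons_sorted[cj]]
                col["support"].append(events[ei] + S)
                col["pos"] = float(np.mean(col["support"]))
                col["members"].add(cid)
                matched.add(ei)
            for ei, p in enumerate(events):
                if ei not in matched:
                    columns.append({"pos": p + S, "support": [p + S], "members": {cid}})
        for k in sorted(range(len(columns)), key=lambda k: columns[k]["pos"]):
            for cid in columns[k]["members"]:
                occupancy[cid].add(round(columns[k]["pos"], 6))
        got = {
            cid: {
                round(float(matrix.positions[e]), 6)
                for e in matrix.occupancy.columns
                if matrix.occupancy.loc[cid, e] == 1
            }
            for cid in lists
        }
        # consensus columns closer than the window merge in the library;
        # compare per-curve supported positions up to that merge
        for cid in lists:
            assert len(got[cid]) <= len(occupancy[cid])
            for p in got[cid]:
                assert any(abs(p - q) < config.match_window for q in occupancy[cid])
            for q in occupancy[cid]:
                assert any(abs(p - q) < config.match_window for p in got[cid])


def test_consensus_stable_under_input_permutation(br26):
    positions = br26["result"].aligned_positions  # detected, aligned
    raw_positions = {
        cid: sorted(
            p
            for e in br26["result"].events_by_curve[cid]
            for p in e.positions()
        )
        for cid in br26["result"].events_by_curve
    }
    base, _ = progressive_align(raw_positions, CFG)
    rng = np.random.default_rng(99)
    keys = list(raw_positions)
    for _ in range(10):
        rng.shuffle(keys)
        permuted = {k: raw_positions[k] for k in keys}
        matrix, _ = progressive_align(permuted, CFG)
        assert len(matrix.positions) == len(base.positions)
        assert np.allclose(
            np.sort(matrix.positions.values), np.sort(base.positions.values), atol=2.0
        )
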