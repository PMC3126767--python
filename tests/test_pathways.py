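"""Main/side classification, co-occurrence counting, pathways, TP/FP."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdcurve.alignment import EventMatrix
from fdcurve.errors import ConfigError
from fdcurve.pathways import classify_peaks, cooccurrence, enumerate_pathways, evaluate
from fdcurve.presets import BR_REGION_WINDOWS

BR_POSITIONS = [39.0, 80.0, 97.0, 143.0, 167.0, 201.0, 215.0]
BR_FREQS = [9, 15, 4, 24, 10, 4, 26]


def make_matrix(freqs, positions, n_curves=26, rng=None):
    ids = [f"e{i + 1}" for i in range(len(positions))]
    occ = pd.DataFrame(0, index=[f"c{i}" for i in range(n_curves)], columns=ids)
    for j, freq in enumerate(freqs):
        rows = np.arange(n_curves)
        if rng is not None:
            rng.shuffle(rows)
        occ.iloc[rows[:freq], j] = 1
    return EventMatrix(occupancy=occ, positions=pd.Series(positions, index=ids))


def test_published_frequencies_split_into_main_and_side():
    matrix = make_matrix(BR_FREQS, BR_POSITIONS)
    labels = classify_peaks(matrix, 0.5, BR_REGION_WINDOWS)
    mains = {l.position_aa for l in labels if l.label == "main"}
    sides = {l.position_aa for l in labels if l.label == "side"}
    assert mains == {80.0, 143.0, 215.0}
    assert sides == {39.0, 97.0, 167.0, 201.0}
    assert [l.region for l in labels] == [1, 1, 1, 2, 2, 3, 3]


def test_all_full_frequency_events_are_main():
    matrix = make_matrix([5, 5], [80.0, 143.0], n_curves=5)
    labels = classify_peaks(matrix)
    assert all(l.label == "main" for l in labels)


def test_threshold_boundary_inclusive():
    matrix = make_matrix([26, 25], [80.0, 143.0])
    labels = classify_peaks(matrix, main_threshold=1.0)
    assert [l.label for l in labels] == ["main", "side"]


def test_classify_invariant_to_row_order(rng):
    matrix = make_matrix(BR_FREQS, BR_POSITIONS, rng=rng)
    shuffled = EventMatrix(
        occupancy=matrix.occupancy.sample(frac=1.0, random_state=5),
        positions=matrix.positions,
    )
    a = [(l.label, l.frequency) for l in classify_peaks(matrix)]
    b = [(l.label, l.frequency) for l in classify_peaks(shuffled)]
    assert a == b


def test_cooccurrence_hand_example():
    occ = pd.DataFrame([[1, 1], [1, 0], [0, 1]], columns=["e1", "e2"],
                       index=["a", "b", "c"])
    matrix = EventMatrix(occupancy=occ, positions=pd.Series([80.0, 143.0], index=["e1", "e2"]))
    table = cooccurrence(matrix, [("e1",), ("e2",), ("e1", "e2")])
    assert table.counts == [2, 2, 1]
    with pytest.raises(ConfigError):
        cooccurrence(matrix, [("nope",)])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_cooccurrence_matches_bruteforce_and_is_monotone(seed):
    rng = np.random.default_rng(seed)
    occ = pd.DataFrame(
        rng.integers(0, 2, size=(20, 5)),
        columns=[f"e{i}" for i in range(1, 6)],
        index=[f"c{i}" for i in range(20)],
    )
    matrix = EventMatrix(occupancy=occ, positions=pd.Series(np.arange(5) * 30.0 + 40, index=occ.columns))
    subsets = [tuple(s) for r in (1, 2, 3) for s in itertools.combinations(occ.columns, r)]
    table = cooccurrence(matrix, subsets)
    counts = dict(zip(table.subsets, table.counts))
    for subset, count in counts.items():
        brute = sum(1 for _, row in occ.iterrows() if all(row[e] == 1 for e in subset))
        assert count == brute
        for e in subset:  # monotone under subset extension
            smaller = tuple(x for x in subset if x != e)
            if smaller:
                assert count <= counts[smaller]


def test_pathway_of_mains_only_curve():
    matrix = make_matrix([0, 26, 0, 26, 0, 0, 26], BR_POSITIONS)
    labels = classify_peaks(matrix, 0.5, BR_REGION_WINDOWS)
    pathways = enumerate_pathways(matrix, labels, BR_REGION_WINDOWS)
    assert pathways == {"100 10 10": 26}


def test_pathway_combinations_counted_distinctly():
    # region-1 main always on with each side subset (4 options), region-2/3
    # main on, side of region 2 toggling (2 options) -> 8 distinct pathways
    ids = ["e1", "e2", "e3", "e4", "e5"]
    positions = pd.Series([39.0, 80.0, 97.0, 143.0, 167.0], index=ids)
    rows = []
    for s1, s2 in itertools.product([0, 1], repeat=2):
        for s3 in (0, 1):
            rows.append({"e1": s1, "e2": 1, "e3": s2, "e4": 1, "e5": s3})
    occ = pd.DataFrame(rows, index=[f"c{i}" for i in range(8)])
    matrix = EventMatrix(occupancy=occ, positions=positions)
    labels = classify_peaks(matrix, 0.9, BR_REGION_WINDOWS)
    pathways = enumerate_pathways(matrix, labels, BR_REGION_WINDOWS)
    assert len(pathways) == 8
    assert sum(pathways.values()) == 8


def test_pathway_empty_curve_counts_zero_string():
    occ = pd.DataFrame(
        [[1, 0], [0, 1], [0, 0]], columns=["e1", "e2"], index=["c0", "c1", "c2"]
    )
    matrix = EventMatrix(occupancy=occ, positions=pd.Series([80.0, 143.0], index=["e1", "e2"]))
    labels = classify_peaks(matrix, 0.3, BR_REGION_WINDOWS)
    pathways = enumerate_pathways(matrix, labels, BR_REGION_WINDOWS)
    # the event-free curve produces the all-zero pathway, counted separately
    zero = [p for p in pathways if set(p.replace(" ", "")) == {"0"}]
    assert zero and pathways[zero[0]] == 1
    assert sum(pathways.values()) == 3


def test_event_outside_regions_raises():
    matrix = make_matrix([3], [260.0], n_curves=5)
    labels = classify_peaks(matrix, 0.5, BR_REGION_WINDOWS)
    with pytest.raises(ConfigError, match="e1"):
        enumerate_pathways(matrix, labels, BR_REGION_WINDOWS)


# ---------------------------------------------------------------- evaluate
def test_evaluate_hand_examples():
    rep = evaluate({"c": [80.0, 143.0]}, {"c": [80.0, 143.0, 215.0]})
    assert (rep.TP, rep.FP, rep.FN) == (2, 0, 1)
    rep = evaluate({"c": [300.0]}, {"c": [80.0]})
    assert (rep.TP, rep.FP, rep.FN) == (0, 1, 1)


def test_evaluate_counts_are_consistent(rng):
    for _ in range(20):
        det = sorted(rng.uniform(0, 250, rng.integers(0, 8)))
        ann = sorted(rng.uniform(0, 250, rng.integers(0, 8)))
        rep = evaluate({"c": det}, {"c": ann})
        assert rep.TP + rep.FP == len(det)
        assert rep.TP + rep.FN == len(ann)
        # brute-force oracle for the max number of matched pairs
        best = 0
        for k in range(min(len(det), len(ann)), -1, -1):
            found = False
            for di in itertools.combinations(range(len(det)), k):
                for ai in itertools.combinations(range(len(ann)), k):
                    if all(abs(det[i] - ann[j]) < 5.0 for i, j in zip(di, ai)):
                        found = True
                        break
                if found:
                    break
            if found:
                best = k
                break
        assert rep.TP == best


def test_bernoulli_model_reproduces_main_side_contrast():
    """Independent draws at the published per-event rates keep pairwise
    main co-occurrence high and side co-occurrence low on average."""
    rng = np.random.default_rng(0)
    main_p = [15 / 26, 24 / 26, 26 / 26]
    side_p = [9 / 26, 4 / 26, 10 / 26, 4 / 26]
    main_pairs, side_pairs = [], []
    for _ in range(200):
        mains = rng.random((26, 3)) < main_p
        sides = rng.random((26, 4)) < side_p
        for i, j in itertools.combinations(range(3), 2):
            main_pairs.append((mains[:, i] & mains[:, j]).mean())
        for i, j in itertools.combinations(range(4), 2):
            side_pairs.append((sides[:, i] & sides[:, j]).mean())
    assert np.mean(main_pairs) >= 0.5
    assert np.mean(side_pairs) < 0.10
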