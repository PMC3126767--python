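"""Main/side peak classification, co-occurrence and pathway statistics.

After alignment, every curve is a row of 0/1 signs over the consensus
events.  High-frequency events (present in at least half the curves by
default) are *main peaks* - the pairwise unfolding of transmembrane
helix pairs - while lower-frequency events are *side peaks* marking
unfolding intermediates.  Co-occurrence counts over event subsets and
per-region pathway strings (main peak first, then side peaks by
position) summarise the unfolding behaviour of the dataset.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field


from .alignment import EventMatrix, match_positions
from .errors import ConfigError


@dataclass
class PeakLabel:
    event_id: str
    position_aa: float
    frequency: int  # number of supporting curves
    label: str  # 'main' | 'side'
    region: int | None  # 1-based region id, None if outside all windows


@dataclass
class CooccurrenceTable:
    subsets: list[tuple]
    counts: list[int]
    n_curves: int

    def as_fractions(self) -> list[float]:
        return [c / self.n_curves for c in self.counts]


@dataclass
class EvaluationReport:
    TP: int
    FP: int
    FN: int
    per_curve: dict = field(default_factory=dict)

    @property
    def precision(self) -> float:
        return self.TP / (self.TP + self.FP) if self.TP + self.FP else float("nan")

    @property
    def recall(self) -> float:
        return self.TP / (self.TP + self.FN) if self.TP + self.FN else float("nan")


def _region_of(position: float, region_windows) -> int | None:
    for r, (lo, hi) in enumerate(region_windows, start=1):
        last = r == len(region_windows)
        if lo <= position < hi or (last and position == hi):
            return r
    return None


def classify_peaks(
    matrix: EventMatrix,
    main_threshold: float = 0.5,
    region_windows=None,
) -> list[PeakLabel]:
    """Label each consensus event main or side by its frequency.

    An event supported by at least ``main_threshold`` of the curves
    (inclusive) is a main peak; the rest are side peaks.  Each event is
    also assigned a region id from the configured contour-length windows
    (None when no windows are given or the position falls outside).
    """
    n_curves = len(matrix.curve_ids)
    if n_curves == 0:
        raise ConfigError("empty matrix")
    labels = []
    support = matrix.n_support
    for event_id in matrix.occupancy.columns:
        freq = int(support[event_id])
        pos = float(matrix.positions[event_id])
        label = "main" if freq / n_curves >= main_threshold else "side"
        region = _region_of(pos, region_windows) if region_windows else None
        labels.append(PeakLabel(event_id, pos, freq, label, region))
    return labels


def cooccurrence(matrix: EventMatrix, subsets: list[tuple]) -> CooccurrenceTable:
    """Count, for each subset of event ids, curves containing all of them."""
    occ = matrix.occupancy
    counts = []
    for subset in subsets:
        for event_id in subset:
            if event_id not in occ.columns:
                raise ConfigError(f"unknown event id {event_id!r}")
        sub = occ[list(subset)]
        counts.append(int((sub.sum(axis=1) == len(subset)).sum()))
    return CooccurrenceTable(subsets=list(subsets), counts=counts, n_curves=len(occ))


def enumerate_pathways(
    matrix: EventMatrix, labels: list[PeakLabel], region_windows
) -> Counter:
    """Build per-curve pathway strings and count the distinct ones.

    Within each region the 0/1 signs are listed main peak first, then
    side peaks by ascending position; region strings are joined with
    spaces.  Raises when an event's position falls outside every window.
    """
    orphans = [lab.event_id for lab in labels if _region_of(lab.position_aa, region_windows) is None]
    if orphans:
        raise ConfigError(f"events outside all region windows: {orphans}")
    by_region: dict[int, list[PeakLabel]] = {}
    for lab in labels:
        region = _region_of(lab.position_aa, region_windows)
        by_region.setdefault(region, []).append(lab)
    region_order = {}
    for region in sorted(by_region):
        labs = by_region[region]
        mains = sorted((l for l in labs if l.label == "main"), key=lambda l: l.position_aa)
        sides = sorted((l for l in labs if l.label == "side"), key=lambda l: l.position_aa)
        region_order[region] = [l.event_id for l in mains + sides]
    pathways: Counter = Counter()
    for cid in matrix.curve_ids:
        row = matrix.occupancy.loc[cid]
        parts = []
        for region in sorted(region_order):
            parts.append("".join(str(int(row[eid])) for eid in region_order[region]))
        pathways["" if not parts else " ".join(parts)] += 1
    return pathways


def evaluate(
    detections: dict,
    annotations: dict,
    window: float = 5.0,
) -> EvaluationReport:
    """Compare detected peak positions against manual annotations.

    Both arguments map curve_id to sorted positions (aa).  Per curve, an
    order-preserving matching within the strict ``window`` is computed;
    matched detections are TP, unmatched detections FP, unmatched
    annotations FN.
    """
    TP = FP = FN = 0
    per_curve = {}
    for cid in sorted(set(detections) | set(annotations)):
        det = sorted(detections.get(cid, []))
        ann = sorted(annotations.get(cid, []))
        n_match, _, _ = match_positions(det, ann, window)
        tp = n_match
        fp = len(det) - n_match
        fn = len(ann) - n_match
        per_curve[cid] = {"TP": tp, "FP": fp, "FN": fn}
        TP += tp
        FP += fp
        FN += fn
    return EvaluationReport(TP=TP, FP=FP, FN=FN, per_curve=per_curve)
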