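"""End-to-end driver: denoise -> encode -> detect -> align -> statistics."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as curve_io
from .alignment import AlignmentConfig, EventMatrix, progressive_align
from .encoding import EncodingConfig
from .errors import FDCurveError
from .events import WLCConfig, detect_events
from .pathways import classify_peaks, cooccurrence, enumerate_pathways, evaluate
from .preprocess import DEFAULT_RESAMPLE, DEFAULT_WINDOW, denoise, filter_curves
from .presets import BR_REGION_WINDOWS
from .wlc import NM_PER_AA

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    window: int = DEFAULT_WINDOW
    n_resample: int = DEFAULT_RESAMPLE
    filter_lengths: bool = True
    min_aa: float = 180.0
    max_aa: float = 220.0
    aa_nm: float = NM_PER_AA
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    wlc: WLCConfig = field(default_factory=WLCConfig)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    main_threshold: float = 0.5
    region_windows: tuple = BR_REGION_WINDOWS


@dataclass
class PipelineResult:
    denoised: list
    rejections: list
    events_by_curve: dict
    matrix: object
    alignments: list
    labels: list
    cooccurrence_tables: dict
    pathways: object
    aligned_positions: dict
    evaluation: object | None = None


def event_positions(events) -> list[float]:
    """Flatten events to the sorted list of all peak positions (aa)."""
    out: list[float] = []
    for ev in events:
        out.extend(ev.positions())
    return sorted(out)


def run_pipeline(curves, config: PipelineConfig | None = None, annotations=None) -> PipelineResult:
    """Run the full analysis on a list of RawCurve.

    Stages: RLOWESS denoising, overall-length filtering, derivative
    encoding and event detection with WLC fits, progressive alignment,
    then main/side classification, co-occurrence tables and pathway
    enumeration.  With ``annotations`` (curve_id -> positions aa), a
    TP/FP/FN evaluation of the aligned detections is added.
    """
    config = config or PipelineConfig()
    if not curves:
        raise FDCurveError("no input curves")

    denoised = [denoise(c, window=config.window, n_resample=config.n_resample) for c in curves]
    if config.filter_lengths:
        kept, rejections = filter_curves(
            denoised, min_aa=config.min_aa, max_aa=config.max_aa, aa_nm=config.aa_nm
        )
    else:
        kept, rejections = denoised, []
    for cid, length in rejections:
        logger.info("rejected %s: overall length %.1f aa outside bounds", cid, length)
    if not kept:
        logger.warning("no curves pass the length filter; empty result")
        empty = EventMatrix(
            occupancy=pd.DataFrame(dtype=int),
            positions=pd.Series(dtype=float, name="position_aa"),
        )
        return PipelineResult(
            denoised=[],
            rejections=rejections,
            events_by_curve={},
            matrix=empty,
            alignments=[],
            labels=[],
            cooccurrence_tables={},
            pathways=None,
            aligned_positions={},
            evaluation=None,
        )

    events_by_curve = {}
    for curve in kept:
        try:
            events_by_curve[curve.curve_id] = detect_events(curve, config.encoding, config.wlc)
        except FDCurveError as err:
            logger.warning("detection failed on %s: %s", curve.curve_id, err)
            events_by_curve[curve.curve_id] = []

    positions = {cid: event_positions(evs) for cid, evs in events_by_curve.items()}
    matrix, alignments = progressive_align(positions, config.alignment)
    labels = classify_peaks(matrix, config.main_threshold, config.region_windows)

    mains = [l.event_id for l in labels if l.label == "main"]
    sides = [l.event_id for l in labels if l.label == "side"]
    subsets = {
        "main": [(m,) for m in mains]
        + [tuple(p) for p in itertools.combinations(mains, 2)]
        + ([tuple(mains)] if len(mains) > 2 else []),
        "side": [(s,) for s in sides]
        + [tuple(p) for p in itertools.combinations(sides, 2)]
        + ([tuple(sides)] if len(sides) > 2 else []),
        "side_main": [(s, m) for s in sides for m in mains],
    }
    tables = {name: cooccurrence(matrix, subs) for name, subs in subsets.items() if subs}
    try:
        pathways = enumerate_pathways(matrix, labels, config.region_windows)
    except FDCurveError as err:
        logger.warning("pathway enumeration skipped: %s", err)
        pathways = None

    shift_by_curve = {a.curve_id: a.shift for a in alignments}
    aligned_positions = {
        cid: sorted(p + shift_by_curve.get(cid, 0.0) - matrix.reference_shift for p in pos)
        for cid, pos in positions.items()
    }
    evaluation = None
    if annotations is not None:
        evaluation = evaluate(
            aligned_positions, annotations, window=config.alignment.match_window
        )
    return PipelineResult(
        denoised=kept,
        rejections=rejections,
        events_by_curve=events_by_curve,
        matrix=matrix,
        alignments=alignments,
        labels=labels,
        cooccurrence_tables=tables,
        pathways=pathways,
        aligned_positions=aligned_positions,
        evaluation=evaluation,
    )


def write_bundle(result: PipelineResult, out_dir) -> dict:
    """Persist the full result bundle (events JSON, matrix/co-occurrence/
    pathway TSVs, shift report) into ``out_dir``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = curve_io.write_results(result.events_by_curve, result.matrix, out_dir)

    pos = result.matrix.positions.round(2)
    pos_path = out_dir / "consensus_events.tsv"
    frame = pd.DataFrame(
        {
            "position_aa": pos,
            "n_support": result.matrix.n_support,
            "label": [l.label for l in result.labels],
            "region": [l.region for l in result.labels],
        }
    )
    frame.index.name = "event_id"
    frame.to_csv(pos_path, sep="\t")
    paths["consensus"] = pos_path

    rows = []
    for name, table in result.cooccurrence_tables.items():
        for subset, count in zip(table.subsets, table.counts):
            positions = "&".join(str(round(float(result.matrix.positions[e]))) for e in subset)
            rows.append(
                {
                    "table": name,
                    "events": "&".join(subset),
                    "positions_aa": positions,
                    "count": count,
                    "n_curves": table.n_curves,
                }
            )
    co_path = out_dir / "cooccurrence.tsv"
    pd.DataFrame(rows).to_csv(co_path, sep="\t", index=False)
    paths["cooccurrence"] = co_path

    if result.pathways is not None:
        pw_path = out_dir / "pathways.tsv"
        pd.DataFrame(
            sorted(result.pathways.items(), key=lambda kv: (-kv[1], kv[0])),
            columns=["pathway", "count"],
        ).to_csv(pw_path, sep="\t", index=False)
        paths["pathways"] = pw_path

    shift_path = out_dir / "shifts.tsv"
    pd.DataFrame(
        [
            {
                "curve_id": a.curve_id,
                "shift_aa": a.shift - result.matrix.reference_shift,
                "n_matches": len(a.matches),
                "score": a.score,
            }
            for a in result.alignments
        ]
    ).to_csv(shift_path, sep="\t", index=False)
    paths["shifts"] = shift_path

    if result.evaluation is not None:
        import json

        ev_path = out_dir / "evaluation.json"
        with open(ev_path, "w") as fh:
            json.dump(
                {
                    "TP": result.evaluation.TP,
                    "FP": result.evaluation.FP,
                    "FN": result.evaluation.FN,
                    "per_curve": result.evaluation.per_curve,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        paths["evaluation"] = ev_path
    return paths
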