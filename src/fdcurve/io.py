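"""Reading and writing force-distance curve files.

A curve file is a TSV/CSV with one optional header line and either two
columns (tip-sample separation nm, force pN) or, in the ``raw_channels``
dialect, two AFM channels (cantilever deflection nm, Z-sensor nm) from
which force and separation are derived with the cantilever spring
constant:

    force    = deflection * spring_constant      [pN]
    distance = z_sensor - deflection             [nm]

Comment lines starting with ``#`` may carry ``key = value`` metadata
(e.g. ``# spring_constant = 50``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, CurveParseError, DegenerateCurveError

MIN_SAMPLES = 10


@dataclass
class RawCurve:
    """One retraction trace: paired separation (nm) and force (pN) samples.

    Samples are kept in acquisition order (the experimental timeline);
    distance monotonicity is not enforced on raw input because noise can
    reverse it locally.
    """

    curve_id: str
    distance: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.distance.shape != self.force.shape or self.distance.ndim != 1:
            raise ValueError("distance and force must be equal-length 1-D arrays")
        if self.distance.size == 0:
            raise ValueError("curve has no samples")
        if not (np.all(np.isfinite(self.distance)) and np.all(np.isfinite(self.force))):
            raise ValueError("curve contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.distance.size


def derive_channels(deflection, z_sensor, spring_constant):
    """Derive (distance nm, force pN) from raw AFM channels.

    force[i] = deflection[i] * spring_constant,
    distance[i] = z_sensor[i] - deflection[i].
    """
    deflection = np.asarray(deflection, dtype=float)
    z_sensor = np.asarray(z_sensor, dtype=float)
    if deflection.shape != z_sensor.shape:
        raise ConfigError("deflection and z_sensor must have equal length")
    if spring_constant <= 0:
        raise ConfigError(f"spring_constant must be positive, got {spring_constant}")
    force = deflection * spring_constant
    distance = z_sensor - deflection
    return distance, force


def _split(line: str) -> list[str]:
    sep = "\t" if "\t" in line else ","
    return [tok.strip() for tok in line.split(sep)]


def read_curve(
    path,
    dialect: str = "two_column",
    spring_constant: float | None = None,
    units: str = "nm_pN",
    invert_force: bool = False,
) -> RawCurve:
    """Read one curve file.

    Parameters
    ----------
    dialect : {"two_column", "raw_channels"}
        ``two_column`` files hold (distance nm, force pN); ``raw_channels``
        files hold (deflection nm, z_sensor nm) and require a spring
        constant (pN/nm), either as the ``spring_constant`` argument or as
        a ``# spring_constant = <k>`` header comment.
    units : {"nm_pN", "m_N"}
        SI input (m, N) is converted to nm/pN.
    invert_force : bool
        Flip the force sign for instruments that record pulling as negative.
    """
    if dialect not in ("two_column", "raw_channels"):
        raise ConfigError(f"unknown dialect {dialect!r}")
    if units not in ("nm_pN", "m_N"):
        raise ConfigError(f"unknown units {units!r}")
    path = Path(path)
    metadata: dict = {"source": str(path)}
    col_a: list[float] = []
    col_b: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    metadata[key.strip()] = val.strip()
                continue
            tokens = _split(line)
            if len(tokens) < 2:
                raise CurveParseError(f"{path}: line {lineno}: expected 2 columns")
            try:
                a, b = float(tokens[0]), float(tokens[1])
            except ValueError:
                # a single non-numeric leading line is a column header
                if not header_seen and not col_a:
                    header_seen = True
                    metadata["header"] = tokens
                    continue
                raise CurveParseError(
                    f"{path}: line {lineno}: non-numeric value in {tokens!r}"
                ) from None
            col_a.append(a)
            col_b.append(b)
    if len(col_a) < MIN_SAMPLES:
        raise DegenerateCurveError(
            f"{path}: only {len(col_a)} samples (need >= {MIN_SAMPLES})"
        )
    a = np.array(col_a)
    b = np.array(col_b)
    if units == "m_N":
        a *= 1e9
        b *= 1e12 if dialect == "two_column" else 1e9
    if dialect == "two_column":
        distance, force = a, b
    else:
        k = spring_constant
        if k is None and "spring_constant" in metadata:
            k = float(metadata["spring_constant"])
        if k is None:
            raise ConfigError(f"{path}: raw_channels dialect needs a spring constant")
        metadata["spring_constant"] = float(k)
        distance, force = derive_channels(a, b, k)
    if invert_force:
        force = -force
    return RawCurve(curve_id=path.stem, distance=distance, force=force, metadata=metadata)


def write_curve(curve: RawCurve, path, precision: int = 6) -> None:
    """Write a curve as two-column TSV at fixed decimal precision."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("distance_nm\tforce_pN\n")
        fmt = f"%.{precision}f\t%.{precision}f\n"
        for d, f in zip(curve.distance, curve.force):
            fh.write(fmt % (d, f))


def write_results(events_by_curve: dict, matrix, out_dir) -> dict:
    """Persist detected events (JSON) and the event matrix (TSV).

    ``events_by_curve`` maps curve_id -> list of UnfoldingEvent; ``matrix``
    is an EventMatrix (or None).  Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    records = []
    for curve_id in sorted(events_by_curve):
        for ev in events_by_curve[curve_id]:
            records.append(ev.to_record())
    events_path = out_dir / "events.json"
    with open(events_path, "w") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["events"] = events_path

    matrix_path = out_dir / "event_matrix.tsv"
    if matrix is not None:
        matrix.occupancy.to_csv(matrix_path, sep="\t")
    else:
        pd.DataFrame().to_csv(matrix_path, sep="\t")
    paths["matrix"] = matrix_path
    return paths


def read_events_json(path) -> dict:
    """Load an events.json file back into per-curve records (plain dicts)."""
    with open(path) as fh:
        records = json.load(fh)
    by_curve: dict[str, list] = {}
    for rec in records:
        by_curve.setdefault(rec["curve_id"], []).append(rec)
    return by_curve


def read_event_matrix(matrix_path, consensus_path):
    """Load an EventMatrix from the TSVs written by the align stage."""
    from .alignment import EventMatrix

    occ = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cons = pd.read_csv(consensus_path, sep="\t", index_col=0)
    return EventMatrix(
        occupancy=occ.astype(int),
        positions=cons["position_aa"].astype(float),
    )


def read_annotations(path) -> dict:
    """Read a TSV of manual annotations (curve_id, position_aa[, label])."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["curve_id"]), []).append(float(row["position_aa"]))
    return {k: sorted(v) for k, v in out.items()}


def write_annotations(annotations: dict, path) -> None:
    rows = []
    for curve_id in sorted(annotations):
        for rec in annotations[curve_id]:
            if isinstance(rec, dict):
                rows.append({"curve_id": curve_id, **rec})
            else:
                rows.append({"curve_id": curve_id, "position_aa": float(rec)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
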