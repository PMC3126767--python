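"""Synthetic SMFS retraction curves with known ground truth.

Curves are rendered as consecutive Worm-Like Chain branches on a uniform
tip-sample-separation grid: each included unfolding event contributes a
branch with contour length (position_aa + attachment offset) * nm/aa that
rises until the branch force reaches the event's rupture force, then the
trace drops onto the next branch (or to baseline after the last event).

Side events are rendered, where geometry permits, as constant-force
cliffs (plateaus) welded into the neighbouring main event's limb - a
plateau *before* the next main rupture produces the CAB morphology
(type II), a plateau in the drop *after* the previous main produces ACB
(type III); otherwise a side is rendered as a standalone sawtooth peak.
Gaussian force noise and a per-curve uniform attachment offset complete
the picture.  The ground-truth annotation records the included events at
their offset-free positions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import RawCurve, write_annotations, write_curve
from .wlc import DEFAULT_PERSISTENCE, KBT_ROOM, NM_PER_AA, wlc_extension_fraction, wlc_force


@dataclass(frozen=True)
class EventSpec:
    """One event of the simulated unfolding pattern.

    ``rupture_force`` of None means a force is drawn uniformly from the
    configuration's ``force_range`` for every curve.
    """

    position_aa: float
    occurrence_prob: float
    kind: str = "main"  # 'main' | 'side'
    rupture_force: float | None = None


@dataclass(frozen=True)
class SimulationConfig:
    events: tuple[EventSpec, ...]
    n_curves: int = 26
    n_samples_raw: int = 1600
    noise_sd: float = 8.0
    max_offset_aa: float = 30.0
    persistence: float = DEFAULT_PERSISTENCE
    kBT: float = KBT_ROOM
    aa_nm: float = NM_PER_AA
    plateau_fraction: float = 1.0
    force_range: tuple[float, float] = (100.0, 200.0)
    #: a side becomes a cliff only if the adjacent main is closer than this
    cliff_max_gap_aa: float = 60.0
    #: cliff (intermediate) force as a fraction of the flanking rupture
    cliff_force_frac: tuple[float, float] = (0.45, 0.70)
    #: grid headroom beyond the longest possible contour length
    grid_margin: float = 1.15
    seed: int | None = None

    def __post_init__(self):
        events = tuple(sorted(self.events, key=lambda e: e.position_aa))
        object.__setattr__(self, "events", events)
        positions = [e.position_aa for e in events]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ConfigError("event positions must be strictly increasing")
        for e in events:
            if not 0.0 <= e.occurrence_prob <= 1.0:
                raise ConfigError("occurrence probabilities must be in [0, 1]")
            if e.kind not in ("main", "side"):
                raise ConfigError(f"unknown event kind {e.kind!r}")
        if self.max_offset_aa < 0 or self.noise_sd < 0:
            raise ConfigError("max_offset_aa and noise_sd must be non-negative")
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ConfigError("plateau_fraction must be in [0, 1]")

    @property
    def x_max_nm(self) -> float:
        if not self.events:
            return self.grid_margin * (50.0 + self.max_offset_aa) * self.aa_nm
        last = self.events[-1].position_aa
        return self.grid_margin * (last + self.max_offset_aa) * self.aa_nm


@dataclass
class SimulatedEvent:
    """Ground-truth record of one rendered event (offset-free position)."""

    position_aa: float
    kind: str
    rendered: str  # 'peak' | 'cliff_before' | 'cliff_after'
    rupture_force: float


def _rupture_extension(L: float, F: float, cfg: SimulationConfig) -> float:
    return L * wlc_extension_fraction(F, cfg.persistence, cfg.kBT)


def simulate_curve(
    config: SimulationConfig, rng: np.random.Generator, curve_id: str = "sim"
) -> tuple[RawCurve, list[SimulatedEvent], float]:
    """Draw and render one curve; returns (curve, truth, offset_aa)."""
    offset = rng.uniform(0.0, config.max_offset_aa)
    included = [e for e in config.events if rng.random() < e.occurrence_prob]
    x = np.linspace(0.0, config.x_max_nm, config.n_samples_raw)
    force = np.zeros_like(x)
    truth: list[SimulatedEvent] = []

    drawn: list[EventSpec] = []
    for e in included:
        f = e.rupture_force
        if f is None:
            f = rng.uniform(*config.force_range)
        drawn.append(replace(e, rupture_force=f))

    # decide rendering of each included event
    rendered: list[str] = []
    for i, e in enumerate(drawn):
        mode = "peak"
        if e.kind == "side" and rng.random() < config.plateau_fraction:
            nxt = drawn[i + 1] if i + 1 < len(drawn) else None
            prv = drawn[i - 1] if i > 0 else None
            if (
                nxt is not None
                and nxt.kind == "main"
                and nxt.position_aa - e.position_aa <= config.cliff_max_gap_aa
            ):
                mode = "cliff_before"
            elif (
                prv is not None
                and prv.kind == "main"
                and e.position_aa - prv.position_aa <= config.cliff_max_gap_aa
                and rendered[i - 1] == "peak"
            ):
                mode = "cliff_after"
        rendered.append(mode)

    # a cliff is an unfolding intermediate: it gives way well below the
    # rupture force of the flanking main barrier
    forces = [e.rupture_force for e in drawn]
    for i, mode in enumerate(rendered):
        if mode == "cliff_before":
            forces[i] = rng.uniform(*config.cliff_force_frac) * forces[i + 1]
        elif mode == "cliff_after":
            forces[i] = rng.uniform(*config.cliff_force_frac) * forces[i - 1]

    L = [(e.position_aa + offset) * config.aa_nm for e in drawn]
    if L and config.grid_margin * L[-1] > config.x_max_nm + 1e-9:
        raise ConfigError("events beyond grid extent; increase grid_margin or x range")

    # segment boundaries: walk events left to right
    x_cursor = 0.0
    for i, e in enumerate(drawn):
        mode = rendered[i]
        if mode == "cliff_before":
            # branch i up to the cliff force, plateau until the next branch
            x_s = max(_rupture_extension(L[i], forces[i], config), x_cursor)
            x_j = max(_rupture_extension(L[i + 1], forces[i], config), x_s)
            sel = (x > x_cursor) & (x <= x_s)
            force[sel] = wlc_force(x[sel], L[i], config.persistence, config.kBT)
            force[(x > x_s) & (x <= x_j)] = forces[i]
            x_cursor = x_j
        elif mode == "cliff_after":
            # plateau welded into the drop of the previous main
            x_c = _rupture_extension(L[i], forces[i], config)
            force[(x > x_cursor) & (x <= x_c)] = forces[i]
            x_cursor = x_c
        else:
            x_r = _rupture_extension(L[i], e.rupture_force, config)
            sel = (x > x_cursor) & (x <= x_r)
            force[sel] = wlc_force(x[sel], L[i], config.persistence, config.kBT)
            x_cursor = x_r
        truth.append(
            SimulatedEvent(
                position_aa=e.position_aa,
                kind=e.kind,
                rendered=mode,
                rupture_force=forces[i],
            )
        )

    if config.noise_sd > 0:
        force = force + rng.normal(0.0, config.noise_sd, force.size)
    curve = RawCurve(
        curve_id=curve_id,
        distance=x,
        force=force,
        metadata={"offset_aa": offset, "simulated": True},
    )
    return curve, truth, offset


def simulate_dataset(config: SimulationConfig, out_dir=None):
    """Simulate ``config.n_curves`` independent curves.

    Returns ``(curves, annotations)`` where annotations maps curve_id to a
    list of ground-truth event records (dicts).  With ``out_dir`` set, the
    curves are written as two-column TSV plus an ``annotations.tsv``;
    identical seeds yield byte-identical files.
    """
    rng = np.random.default_rng(config.seed)
    curves: list[RawCurve] = []
    annotations: dict[str, list[dict]] = {}
    width = max(3, len(str(max(config.n_curves - 1, 0))))
    for i in range(config.n_curves):
        curve_id = f"sim_{i:0{width}d}"
        curve, truth, offset = simulate_curve(config, rng, curve_id)
        curves.append(curve)
        annotations[curve_id] = [
            {
                "position_aa": ev.position_aa,
                "label": ev.kind,
                "rendered": ev.rendered,
                "rupture_force_pN": round(ev.rupture_force, 3),
            }
            for ev in truth
        ]
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for curve in curves:
            write_curve(curve, out_dir / f"{curve.curve_id}.tsv")
        write_annotations(annotations, out_dir / "annotations.tsv")
    return curves, annotations
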