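"""Reference configuration for the bacteriorhodopsin (bR) unfolding study.

bR unfolds through three main peaks (pairwise unfolding of transmembrane
helix pairs E&D, B&C, and helix A) near contour lengths 80, 143 and
215 aa, plus four lower-frequency side peaks (unfolding intermediates)
near 39, 97, 167 and 201 aa.  The occurrence probabilities below are the
published per-event frequencies out of 26 experimental curves; the
co-occurrence count tables are the published reference values used by
the worked examples and the acceptance checks.
"""

from __future__ import annotations

from .simulate import EventSpec, SimulationConfig

N_CURVES_BR = 26

#: (position_aa, count-out-of-26, kind)
BR_EVENT_TABLE = (
    (39, 9, "side"),
    (80, 15, "main"),
    (97, 4, "side"),
    (143, 24, "main"),
    (167, 10, "side"),
    (201, 4, "side"),
    (215, 26, "main"),
)

BR_EVENTS = tuple(
    EventSpec(position_aa=pos, occurrence_prob=count / N_CURVES_BR, kind=kind)
    for pos, count, kind in BR_EVENT_TABLE
)

#: contour-length windows (aa) of the three structural regions:
#: helices E&D, helices B&C, helix A
BR_REGION_WINDOWS = ((30.0, 110.0), (110.0, 180.0), (180.0, 240.0))

#: published pairwise/triple co-occurrence counts among the main peaks
BR_MAIN_COOCCURRENCE = {
    (80,): 15,
    (143,): 24,
    (215,): 26,
    (80, 143): 14,
    (80, 215): 15,
    (143, 215): 24,
    (80, 143, 215): 14,
}

#: published co-occurrence counts among the side peaks
BR_SIDE_COOCCURRENCE = {
    (39,): 9,
    (97,): 4,
    (167,): 10,
    (201,): 4,
    (39, 97): 2,
    (39, 167): 1,
    (97, 167): 2,
    (97, 201): 1,
    (167, 201): 1,
    (39, 97, 167, 201): 0,
}

#: published side-with-main co-occurrence counts
BR_SIDE_MAIN_COOCCURRENCE = {
    (39, 80): 6,
    (39, 143): 8,
    (97, 80): 2,
    (97, 143): 4,
    (167, 143): 10,
    (167, 215): 10,
    (201, 143): 4,
    (201, 215): 4,
}


def br_simulation_config(seed: int | None = None, **overrides) -> SimulationConfig:
    """The bR-like study preset: 26 curves, ~1,600 raw samples each."""
    kwargs = dict(events=BR_EVENTS, n_curves=N_CURVES_BR, seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
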