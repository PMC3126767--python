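"""Shared fixtures: synthetic curves and a session-wide bR pipeline run."""

from __future__ import annotations

import numpy as np
import pytest

from fdcurve.encoding import DerivativeCell, derivative_bin
from fdcurve.pipeline import PipelineConfig, run_pipeline
from fdcurve.preprocess import DenoisedCurve
from fdcurve.presets import br_simulation_config
from fdcurve.simulate import simulate_dataset

#: bin indices representing steep rise / steep fall / flat on the default
#: 1000-bin grid (dy' = +-0.99 and 0)
RISE_BIN = int(derivative_bin(np.array(0.99), 1000))
FALL_BIN = int(derivative_bin(np.array(-0.99), 1000))
CONST_BIN = int(derivative_bin(np.array(0.0), 1000))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_denoised(distance, force, curve_id="test", window=51, n_raw=None, noise_sd=None):
    """Wrap plain arrays in a DenoisedCurve (synthetic, no smoothing)."""
    metadata = {}
    if noise_sd is not None:
        metadata["force_noise_sd"] = noise_sd
    return DenoisedCurve(
        curve_id=curve_id,
        distance=np.asarray(distance, float),
        force=np.asarray(force, float),
        window=window,
        n_raw=n_raw,
        metadata=metadata,
    )


def make_cells(band_pattern, arcs=None, span=1000):
    """Build a cell sequence from a band pattern like "rcf".

    Each symbol becomes one cell with the matching force-derivative bin;
    spans are laid out contiguously, ``span`` samples per cell.
    """
    bins = {"r": RISE_BIN, "f": FALL_BIN, "c": CONST_BIN}
    cells = []
    pos = 0
    for i, sym in enumerate(band_pattern):
        arc = 1.0 if arcs is None else arcs[i]
        cells.append(
            DerivativeCell(
                dx_bin=CONST_BIN,
                dy_bin=bins[sym],
                arc_length=arc,
                start_index=pos,
                end_index=pos + span - 1,
            )
        )
        pos += span
    return cells


@pytest.fixture(scope="session")
def br26():
    """The 26-curve bR-like reference dataset (fixed seed) with its
    ground-truth annotations and the full pipeline result."""
    config = br_simulation_config(seed=7)
    curves, annotations = simulate_dataset(config)
    positions = {
        cid: sorted(r["position_aa"] for r in recs) for cid, recs in annotations.items()
    }
    result = run_pipeline(curves, PipelineConfig(), annotations=positions)
    return {
        "config": config,
        "curves": curves,
        "annotations": annotations,
        "positions": positions,
        "result": result,
    }
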