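"""Deterministic toy spike trains for exercising the analysis layer.

These generators produce spike data with known ground truth (phase
precession slope, correlogram lag, spatial spike-time gradients) without
running the network simulator, so every measurement procedure can be
validated against analytically known answers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dynamics import THETA_PERIOD, SpikeRecord
from .geometry import Arena, PlaceCellGrid, build_grid, wrap_angle


def make_record(layer_events: dict, grids: dict, duration: float) -> SpikeRecord:
    """Assemble a SpikeRecord from {layer: (ids, times)} arrays."""
    frames = []
    for layer, (ids, times) in layer_events.items():
        frames.append(
            pd.DataFrame(
                {"layer": layer, "neuron_id": np.asarray(ids, int),
                 "t_ms": np.asarray(times, float)}
            )
        )
    events = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["t_ms", "layer", "neuron_id"], kind="stable")
        .reset_index(drop=True)
    )
    return SpikeRecord(events=events, grids=grids, duration=duration,
                       fingerprint="synthetic")


def precessing_spikes(slope: float, onset: float = 0.0, n_spikes: int = 10,
                      speed: float = 20.0):
    """Spike times/positions of one cell with exact phase precession.

    Generates spikes at normalised positions x_k in [0, 1] whose theta
    phases follow (onset + slope * x_k) mod 2 pi on a straight run at
    ``speed`` cm/s through a 10-cm field.  Returns (times_ms, x_cm).
    """
    x = np.linspace(0.0, 1.0, n_spikes)
    phases = wrap_angle(onset + slope * x)
    # one spike per theta cycle at exactly the requested phase; positions
    # follow the normalised grid (10-cm field), so the regression's
    # first/last-spike normalisation reproduces x exactly
    t = np.arange(n_spikes) * THETA_PERIOD + phases / (2.0 * np.pi) * THETA_PERIOD
    pos = x * 10.0
    return t, pos


def poisson_train(rate_hz: float, duration_ms: float, seed: int = 0) -> np.ndarray:
    """Homogeneous Poisson spike train."""
    rng = np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    return np.sort(rng.uniform(0.0, duration_ms, n))


def lagged_pair(lag_ms: float, n_cycles: int = 20, jitter_ms: float = 0.0,
                seed: int = 0):
    """Two theta-locked trains where train B trails train A by ``lag_ms``.

    One spike per theta cycle each; optional Gaussian jitter.  Returns
    (times_a, times_b).
    """
    rng = np.random.default_rng(seed)
    base = np.arange(n_cycles) * THETA_PERIOD + 30.0
    a = base + rng.normal(0.0, jitter_ms, n_cycles)
    b = base + lag_ms + rng.normal(0.0, jitter_ms, n_cycles)
    return np.sort(a), np.sort(b)


def timed_grid_record(time_of_center, n_side: int = 8, arena_width: float = 80.0,
                      window_start: float = 0.0) -> SpikeRecord:
    """One spike per cell at a time given by a function of its centre.

    ``time_of_center(x, y)`` maps a field centre to a spike time offset
    (ms) added to ``window_start``.  Used to test spike-time gradient
    maps with constructed (e.g. linear or radial) time fields.
    """
    arena = Arena(arena_width, arena_width)
    grid = build_grid(arena, n_side, "CA3")
    grid.preferred_dirs = np.zeros(grid.n)
    times = np.array(
        [window_start + time_of_center(x, y) for x, y in grid.centers]
    )
    return make_record(
        {"CA3": (np.arange(grid.n), times)}, {"CA3": grid},
        duration=float(times.max() + 1.0),
    )
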