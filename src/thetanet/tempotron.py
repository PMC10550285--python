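"""Tempotron readout of theta-cycle spike patterns.

A tempotron is a leaky integrator neuron whose afferent weights are
trained by a spike-timing credit-assignment rule to fire on target
temporal patterns.  Here it reads the spikes of a place-cell population
within single theta cycles (100 ms) and serves to test whether the
hard-wired intrinsic sequence acts as a running-direction-invariant
landmark signature: a readout trained on the standing-still activity of a
looped location should detect that location from any direction of
approach.

Training uses only (+) patterns; weights therefore never decrease.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .dynamics import THETA_PERIOD, SpikeRecord
from .geometry import PlaceCellGrid

TAU_DECAY = 5.0   # ms
TAU_RISE = 1.25   # ms
V_THRESH = 2.0
LEARN_RATE = 0.01

#: kernel peak time t* = (tau tau_r / (tau - tau_r)) ln(tau / tau_r)
KERNEL_PEAK_TIME = (TAU_DECAY * TAU_RISE / (TAU_DECAY - TAU_RISE)) * np.log(
    TAU_DECAY / TAU_RISE
)
#: V_0 normalises the kernel peak to exactly 1
V0 = 1.0 / (
    np.exp(-KERNEL_PEAK_TIME / TAU_DECAY) - np.exp(-KERNEL_PEAK_TIME / TAU_RISE)
)


def kernel(dt) -> np.ndarray:
    """Double-exponential PSP kernel, normalised to peak 1; zero for dt < 0."""
    dt = np.asarray(dt, float)
    out = V0 * (np.exp(-dt / TAU_DECAY) - np.exp(-dt / TAU_RISE))
    return np.where(dt >= 0.0, out, 0.0)


@dataclass
class Pattern:
    """Afferent spike times within one theta cycle.

    afferents -- local afferent indices, one per spike
    times     -- spike times in ms relative to the cycle start
    """

    afferents: np.ndarray
    times: np.ndarray
    label: int = 1

    def __post_init__(self):
        self.afferents = np.asarray(self.afferents, dtype=np.intp)
        self.times = np.asarray(self.times, dtype=float)

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class Tempotron:
    """Readout neuron with adaptable afferent weights."""

    n_afferents: int
    weights: np.ndarray = field(default=None)
    dt: float = 0.1
    v_thresh: float = V_THRESH
    lr: float = LEARN_RATE
    t_pad: float = 10.0  # trace margin (ms) for jittered out-of-cycle spikes

    def __post_init__(self):
        if self.weights is None:
            self.weights = np.zeros(self.n_afferents)
        self.weights = np.asarray(self.weights, float)
        self._grid = np.arange(
            -self.t_pad, THETA_PERIOD + self.t_pad + self.dt / 2, self.dt
        )
        self._ktab = kernel(np.arange(0.0, 8.0 * TAU_DECAY, self.dt))

    # ------------------------------------------------------------------
    def _impulse_train(self, pattern: Pattern, weights=None) -> np.ndarray:
        w = self.weights if weights is None else weights
        imp = np.zeros(self._grid.size)
        idx = np.round((pattern.times + self.t_pad) / self.dt).astype(int)
        ok = (idx >= 0) & (idx < imp.size)
        np.add.at(imp, idx[ok], w[pattern.afferents[ok]])
        return imp

    def _trace(self, pattern: Pattern) -> np.ndarray:
        """Un-shunted soma potential on the time grid."""
        if pattern.n_spikes == 0:
            return np.zeros(self._grid.size)
        v = fftconvolve(self._impulse_train(pattern), self._ktab)
        return v[: self._grid.size]

    # ------------------------------------------------------------------
    def voltage_trace(self, pattern: Pattern):
        """Shunted voltage and first readout spike time (or None).

        The readout fires at the first upward crossing of the threshold;
        afferent spikes arriving after the crossing evoke no further PSPs
        (shunting), so the trace afterwards is the passive decay of the
        already-evoked potentials.
        """
        v_full = self._trace(pattern)
        above = v_full >= self.v_thresh
        if not above.any():
            return v_full, None
        k = int(np.argmax(above))
        t_spike = float(self._grid[k])
        keep = pattern.times <= t_spike
        shunted = Pattern(pattern.afferents[keep], pattern.times[keep], pattern.label)
        return self._trace(shunted), t_spike

    def fires(self, pattern: Pattern) -> bool:
        return bool(np.any(self._trace(pattern) >= self.v_thresh))

    # ------------------------------------------------------------------
    def train(self, patterns: list[Pattern], epochs: int = 100, seed: int = 0):
        """(+)-pattern-only training.

        For every presented pattern that fails to fire, each afferent is
        credited by the kernel evaluated between its spike times and the
        time of the voltage maximum: w_i += lr * sum_{t_f < t_max}
        K(t_max - t_f).  Presentation order is shuffled per epoch; training
        stops early once every pattern fires.  Returns the per-epoch
        fraction of patterns that fired.
        """
        rng = np.random.default_rng(seed)
        usable = [p for p in patterns if p.n_spikes > 0]
        if len(usable) < len(patterns):
            import warnings

            warnings.warn(
                f"skipping {len(patterns) - len(usable)} empty pattern(s)",
                stacklevel=2,
            )
        history = []
        for _ in range(epochs):
            order = rng.permutation(len(usable))
            n_fired = 0
            for k in order:
                p = usable[k]
                v = self._trace(p)
                if v.max() >= self.v_thresh:
                    n_fired += 1
                    continue
                if v.max() <= 1e-12:
                    # degenerate flat trace (e.g. all-zero initial
                    # weights): credit every afferent spike at the
                    # kernel peak to bootstrap learning
                    np.add.at(self.weights, p.afferents, self.lr)
                    continue
                t_max = float(self._grid[int(np.argmax(v))])  # earliest tie
                before = p.times < t_max
                if not before.any():
                    continue
                np.add.at(
                    self.weights,
                    p.afferents[before],
                    self.lr * kernel(t_max - p.times[before]),
                )
            history.append(n_fired / len(usable))
            if n_fired == len(usable):
                break
        return history


# ---------------------------------------------------------------------------
# building patterns from simulations
# ---------------------------------------------------------------------------

def box_afferents(grid: PlaceCellGrid, center, half_width: float = 10.0) -> np.ndarray:
    """Ids of the place cells whose field centres lie in a square box."""
    c = np.asarray(center, float)
    inside = (np.abs(grid.centers[:, 0] - c[0]) <= half_width) & (
        np.abs(grid.centers[:, 1] - c[1]) <= half_width
    )
    return np.flatnonzero(inside)


def patterns_from_record(
    record: SpikeRecord,
    afferent_ids: np.ndarray,
    t_start: float = 0.0,
    n_cycles: int = 10,
    layer: str = "CA3",
) -> list[Pattern]:
    """Split a population's spikes into per-theta-cycle patterns.

    Afferent indices are local to ``afferent_ids`` (the tempotron's input
    space); spike times are relative to each cycle's start.
    """
    ev = record.events
    sub = ev[(ev["layer"] == layer) & np.isin(ev["neuron_id"], afferent_ids)]
    local = {int(gid): k for k, gid in enumerate(afferent_ids)}
    t = sub["t_ms"].to_numpy() - t_start
    ids = sub["neuron_id"].to_numpy()
    patterns = []
    for c in range(n_cycles):
        in_cycle = (t >= c * THETA_PERIOD) & (t < (c + 1) * THETA_PERIOD)
        patterns.append(
            Pattern(
                afferents=np.array([local[int(i)] for i in ids[in_cycle]], dtype=np.intp),
                times=t[in_cycle] - c * THETA_PERIOD,
            )
        )
    return patterns


def jitter_patterns(
    patterns: list[Pattern], n_jitter: int, sd_ms: float, rng
) -> list[list[Pattern]]:
    """``n_jitter`` noisy realisations of a pattern set.

    Each spike is jittered independently with N(0, sd^2); jittered times
    may leave the cycle window but stay assigned to their pattern.
    """
    out = []
    for _ in range(n_jitter):
        out.append(
            [
                Pattern(p.afferents, p.times + rng.normal(0.0, sd_ms, p.n_spikes))
                for p in patterns
            ]
        )
    return out


def evaluate_patterns(
    model: Tempotron,
    cycle_patterns: list[Pattern],
    n_jitter: int = 100,
    sd_ms: float = 2.0,
    seed: int = 0,
) -> float:
    """Detection accuracy over jittered realisations of a trajectory.

    A realisation counts as detected if any of its theta-cycle patterns
    elicits a readout spike; the accuracy is the detected fraction over
    ``n_jitter`` realisations.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    detected = 0
    for real in jitter_patterns(cycle_patterns, n_jitter, sd_ms, rng):
        if any(model.fires(p) for p in real):
            detected += 1
    return detected / n_jitter
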