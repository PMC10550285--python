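"""Measurement procedures for theta sequences.

Implements the full analysis stack applied to simulated spike trains:

* theta-phase assignment and circular-linear regression of phase against
  in-field position (phase precession: slope, onset, mean phase),
* cross-correlograms at 5-ms resolution in a +/-100 ms window, their
  4-12 Hz analytic-signal phase at zero lag ("correlation lag"),
* extrinsicity / intrinsicity of field pairs from opposite running
  directions,
* theta compression (circular-linear regression of lag phase against
  field-centre distance),
* best/worst and similar/dissimilar pair classification, and
* spike-time gradient maps over one theta cycle.

Sign convention: a pair correlogram histograms t_first - t_next, the lag
of the first-encountered cell relative to the next cell along the
trajectory, unless a fixed spatial axis ordering is requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, hilbert, sosfiltfilt

from .dynamics import THETA_PERIOD, SpikeRecord
from .geometry import PlaceCellGrid, circular_difference, wrap_angle

CORR_BIN = 5.0      # ms
CORR_WINDOW = 200.0  # ms total width -> lags in [-100, 100)
CORR_FS = 1000.0 / CORR_BIN  # 200 Hz
BAND = (4.0, 12.0)   # Hz
MIN_SPIKES = 6       # "more than 5 spikes" active-cell rule
OVERLAP_DISTANCE = 10.0  # cm, two 5-cm field radii


# ---------------------------------------------------------------------------
# phases and circular statistics
# ---------------------------------------------------------------------------

def spike_phase(t) -> np.ndarray:
    """Theta phase of spike times, 0 at the theta drive maxima (t = 0, 100...)."""
    return 2.0 * np.pi * np.mod(np.asarray(t, float), THETA_PERIOD) / THETA_PERIOD


def circular_mean(phases) -> float:
    z = np.mean(np.exp(1j * np.asarray(phases)))
    return float(wrap_angle(np.angle(z)))


def _resultant(phases, x, a):
    """Mean resultant length of (phi - a * x); a may be an array (grid)."""
    a = np.atleast_1d(np.asarray(a, float))
    z = np.exp(1j * (phases[None, :] - a[:, None] * x[None, :]))
    return np.abs(z.mean(axis=1))


def circlin_fit(phases, x, slope_bounds, n_grid: int = 1001):
    """Circular-linear regression by maximising the mean resultant length.

    Scans R(a) = |<exp(i(phi - a x))>| on a uniform slope grid spanning
    ``slope_bounds`` and refines the best grid point by golden-section
    search within one grid step.  Returns (slope, intercept, R).
    """
    phases = np.asarray(phases, float)
    x = np.asarray(x, float)
    lo, hi = slope_bounds
    grid = np.linspace(lo, hi, n_grid)
    R = _resultant(phases, x, grid)
    k = int(np.argmax(R))
    a_lo = grid[max(k - 1, 0)]
    a_hi = grid[min(k + 1, n_grid - 1)]
    # golden-section refinement of the (unimodal near the peak) resultant
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = a_hi - invphi * (a_hi - a_lo)
    d = a_lo + invphi * (a_hi - a_lo)
    for _ in range(40):
        if _resultant(phases, x, c)[0] > _resultant(phases, x, d)[0]:
            a_hi = d
        else:
            a_lo = c
        c = a_hi - invphi * (a_hi - a_lo)
        d = a_lo + invphi * (a_hi - a_lo)
    a_best = 0.5 * (a_lo + a_hi)
    z = np.mean(np.exp(1j * (phases - a_best * x)))
    return float(a_best), float(wrap_angle(np.angle(z))), float(np.abs(z))


def circ_lin_corr(phases, x, slope) -> float:
    """Circular-linear correlation at a fitted slope.

    Maps the linear variable onto the circle with the fitted frequency and
    computes the circular-circular correlation with the spike phases,
    signed by the slope direction.
    """
    phases = np.asarray(phases, float)
    if abs(slope) < 1e-12 or len(phases) < 2:
        return 0.0
    theta = wrap_angle(np.abs(slope) * np.asarray(x, float))
    pm = np.angle(np.mean(np.exp(1j * phases)))
    tm = np.angle(np.mean(np.exp(1j * theta)))
    num = np.sum(np.sin(phases - pm) * np.sin(theta - tm))
    den = np.sqrt(np.sum(np.sin(phases - pm) ** 2) * np.sum(np.sin(theta - tm) ** 2))
    if den == 0:
        return 0.0
    return float(np.sign(slope) * num / den)


# ---------------------------------------------------------------------------
# phase precession
# ---------------------------------------------------------------------------

@dataclass
class PrecessionFit:
    """Per-cell phase-precession fit on one traversal.

    slope is in radians per normalised field traversal ("per field size"),
    onset is the circular intercept at the entry of the traversed field,
    phases are wrapped to [0, 2 pi).
    """

    slope: float
    onset: float
    mean_phase: float
    rho: float
    n_spikes: int


#: slope search range: two theta cycles per normalised traversal
PRECESSION_SLOPE_BOUND = 4.0 * np.pi


def fit_precession(spike_times, spike_positions, heading=None) -> PrecessionFit | None:
    """Fit phase precession for one cell on one traversal.

    spike_positions may be scalar positions along the run or (n, 2) animal
    positions, in which case ``heading`` (radians) is used to project them
    onto the running direction.  Positions are normalised so the first
    spike maps to 0 and the last to 1.  Cells with fewer than 6 spikes are
    excluded (returns None rather than raising).
    """
    t = np.asarray(spike_times, float)
    if t.size < MIN_SPIKES:
        return None
    order = np.argsort(t)
    t = t[order]
    p = np.asarray(spike_positions, float)[order]
    if p.ndim == 2:
        if heading is None:
            raise ValueError("heading required to project 2-d positions")
        p = p @ np.array([np.cos(heading), np.sin(heading)])
    span = p[-1] - p[0]
    if abs(span) < 1e-9:
        x = np.zeros_like(p)
    else:
        x = (p - p[0]) / span
    phases = spike_phase(t)
    slope, onset, _ = circlin_fit(
        phases, x, (-PRECESSION_SLOPE_BOUND, PRECESSION_SLOPE_BOUND)
    )
    return PrecessionFit(
        slope=slope,
        onset=onset,
        mean_phase=circular_mean(phases),
        rho=circ_lin_corr(phases, x, slope),
        n_spikes=int(t.size),
    )


def population_precession(
    record: SpikeRecord,
    trajectory,
    layer: str = "CA3",
    min_spikes: int = MIN_SPIKES,
) -> pd.DataFrame:
    """Precession fits for every active cell of a layer on one run.

    Returns a table with one row per cell firing at least ``min_spikes``
    spikes: slope, onset, mean phase, circular-linear correlation, spike
    count, field centre and preferred direction.
    """
    grid = record.grids[layer]
    heading = float(trajectory.headings[0])
    times = trajectory.times
    spikes = record.spike_times(layer)
    rows = []
    for nid, st in spikes.items():
        if st.size < min_spikes:
            continue
        idx = np.clip(np.searchsorted(times, st), 0, len(times) - 1)
        fit = fit_precession(st, trajectory.positions[idx], heading)
        if fit is None:
            continue
        rows.append(
            {
                "neuron_id": nid,
                "slope": fit.slope,
                "onset": fit.onset,
                "mean_phase": fit.mean_phase,
                "rho": fit.rho,
                "n_spikes": fit.n_spikes,
                "x": grid.centers[nid, 0],
                "y": grid.centers[nid, 1],
                "preferred_dir": grid.preferred_dirs[nid],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_id", "slope", "onset", "mean_phase", "rho",
            "n_spikes", "x", "y", "preferred_dir",
        ],
    )


# ---------------------------------------------------------------------------
# cross-correlograms and correlation lag
# ---------------------------------------------------------------------------

@dataclass
class CrossCorrHistogram:
    """Histogram of spike-time lags at 5-ms resolution over +/-100 ms."""

    counts: np.ndarray
    bin_edges: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def empty(self) -> bool:
        return not np.any(self.counts)


def corr_bin_edges(bin_ms: float = CORR_BIN, window_ms: float = CORR_WINDOW):
    half = window_ms / 2.0
    return np.arange(-half, half + bin_ms / 2.0, bin_ms)


def cross_correlogram(
    spikes_a, spikes_b, bin_ms: float = CORR_BIN, window_ms: float = CORR_WINDOW
) -> CrossCorrHistogram:
    """Histogram of lags t_b - t_a over all spike pairs within the window.

    The caller fixes the sign convention by the argument order; pair
    pipelines in this module pass (next cell, first-encountered cell) so
    positive lags mean the first-encountered cell fires later.
    """
    edges = corr_bin_edges(bin_ms, window_ms)
    a = np.asarray(spikes_a, float)
    b = np.asarray(spikes_b, float)
    if a.size == 0 or b.size == 0:
        return CrossCorrHistogram(np.zeros(len(edges) - 1, dtype=int), edges)
    lags = (b[None, :] - a[:, None]).ravel()
    lags = lags[(lags >= edges[0]) & (lags < edges[-1])]
    counts, _ = np.histogram(lags, bins=edges)
    return CrossCorrHistogram(counts, edges)


def _bandpass_sos():
    return butter(2, BAND, btype="bandpass", fs=CORR_FS, output="sos")


def filtered_correlogram(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass (4-12 Hz) a correlogram, zero-padded to 3x its length.

    Returns (filtered padded signal, padded lag axis in ms).  Accepts a
    single histogram or a (n_pairs, n_bins) stack.
    """
    counts = np.asarray(counts, float)
    n = counts.shape[-1]
    pad = [(0, 0)] * (counts.ndim - 1) + [(n, n)]
    padded = np.pad(counts, pad)
    filtered = sosfiltfilt(_bandpass_sos(), padded, axis=-1)
    centers = corr_bin_edges()[:-1] + CORR_BIN / 2.0
    lags = np.concatenate(
        [centers[0] - CORR_BIN * np.arange(n, 0, -1), centers,
         centers[-1] + CORR_BIN * np.arange(1, n + 1)]
    )
    return filtered, lags


def correlation_lag(hist: CrossCorrHistogram | np.ndarray) -> float:
    """Phase at zero lag of the analytic signal of the band-passed histogram.

    Positive phase indicates the histogram mass (under this module's
    t_first - t_next convention) sits at negative lags, i.e. the
    first-encountered cell fires earlier within the theta cycle.  Returns
    NaN for an empty histogram.
    """
    counts = hist.counts if isinstance(hist, CrossCorrHistogram) else np.asarray(hist)
    return float(lag_phases(np.atleast_2d(counts))[0])


def lag_phases(counts: np.ndarray) -> np.ndarray:
    """Vectorised correlation-lag phase for a (n_pairs, n_bins) stack."""
    counts = np.asarray(counts, float)
    out = np.full(counts.shape[0], np.nan)
    ok = np.any(counts != 0, axis=-1)
    if not np.any(ok):
        return out
    filtered, lags = filtered_correlogram(counts[ok])
    analytic = hilbert(filtered, axis=-1)
    # interpolate the analytic signal at lag 0 (bin centres straddle zero)
    j = int(np.searchsorted(lags, 0.0))
    w = (0.0 - lags[j - 1]) / (lags[j] - lags[j - 1])
    z0 = (1.0 - w) * analytic[..., j - 1] + w * analytic[..., j]
    out[ok] = np.angle(z0)
    return out


def peak_lag(counts: np.ndarray, max_lag: float = 50.0) -> float:
    """Lag (ms) of the maximum of the band-passed correlogram near zero."""
    filtered, lags = filtered_correlogram(np.asarray(counts, float))
    sel = np.abs(lags) <= max_lag
    return float(lags[sel][np.argmax(filtered[..., sel])])


def ex_in(h_fwd, h_rev) -> tuple[float, float]:
    """Extrinsicity and intrinsicity of a field pair.

    Ex = (pearson(h_fwd, h_rev) + 1) / 2 compares the correlograms of the
    two opposite running directions; In uses the horizontally flipped
    reverse histogram.  Both lie in [0, 1]; a pair is classified extrinsic
    iff Ex > In.  Returns NaNs when either histogram has zero variance.
    """
    a = np.asarray(h_fwd.counts if isinstance(h_fwd, CrossCorrHistogram) else h_fwd, float)
    b = np.asarray(h_rev.counts if isinstance(h_rev, CrossCorrHistogram) else h_rev, float)
    if a.std() == 0 or b.std() == 0:
        return float("nan"), float("nan")
    ex = (np.corrcoef(a, b)[0, 1] + 1.0) / 2.0
    inn = (np.corrcoef(a, b[::-1])[0, 1] + 1.0) / 2.0
    return float(ex), float(inn)


# ---------------------------------------------------------------------------
# pair pipelines
# ---------------------------------------------------------------------------

def _active_spikes(record: SpikeRecord, layer: str, min_spikes: int):
    spikes = record.spike_times(layer)
    return {nid: st for nid, st in spikes.items() if st.size >= min_spikes}


def _pair_indices(ids, centers, heading, max_distance, ordering, reference_angle):
    """(first, next) ordered pairs of active cells with overlapping fields.

    ``ordering='encounter'`` orders each pair by the projection of the
    field centres onto the running direction; ``'axis'`` uses a fixed
    reference angle instead (used by the model variants where lag
    direction is defined spatially).
    """
    angle = heading if ordering == "encounter" else reference_angle
    unit = np.array([np.cos(angle), np.sin(angle)])
    proj = centers @ unit
    ii, jj = np.triu_indices(len(ids), k=1)
    d = np.linalg.norm(centers[ii] - centers[jj], axis=1)
    keep = d <= max_distance
    ii, jj, d = ii[keep], jj[keep], d[keep]
    swap = proj[ii] > proj[jj]
    first = np.where(swap, jj, ii)
    second = np.where(swap, ii, jj)
    return first, second, d


def pair_correlograms(
    record: SpikeRecord,
    trajectory,
    layer: str = "CA3",
    max_distance: float = OVERLAP_DISTANCE,
    min_spikes: int = MIN_SPIKES,
    ordering: str = "encounter",
    reference_angle: float = 0.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Correlograms of all overlapping active-cell pairs on one run.

    Returns (table, counts) where counts[k] is the lag histogram of pair k
    under the t_first - t_next convention and the table holds pair ids,
    centre distance and the orientation of the centre-difference vector
    (from the first-encountered to the next cell).
    """
    grid = record.grids[layer]
    heading = float(trajectory.headings[0])
    spikes = _active_spikes(record, layer, min_spikes)
    ids = np.array(sorted(spikes), dtype=int)
    if ids.size < 2:
        return (
            pd.DataFrame(columns=["id_first", "id_next", "distance", "orientation"]),
            np.zeros((0, len(corr_bin_edges()) - 1), dtype=int),
        )
    centers = grid.centers[ids]
    fi, se, dist = _pair_indices(
        ids, centers, heading, max_distance, ordering, reference_angle
    )
    edges = corr_bin_edges()
    counts = np.zeros((fi.size, len(edges) - 1), dtype=int)
    orient = np.empty(fi.size)
    for k in range(fi.size):
        t_first = spikes[ids[fi[k]]]
        t_next = spikes[ids[se[k]]]
        lags = (t_first[None, :] - t_next[:, None]).ravel()
        lags = lags[(lags >= edges[0]) & (lags < edges[-1])]
        counts[k], _ = np.histogram(lags, bins=edges)
        dc = centers[se[k]] - centers[fi[k]]
        orient[k] = np.arctan2(dc[1], dc[0])
    table = pd.DataFrame(
        {
            "id_first": ids[fi],
            "id_next": ids[se],
            "distance": dist,
            "orientation": wrap_angle(orient),
        }
    )
    return table, counts


def averaged_correlogram(
    record: SpikeRecord,
    trajectory,
    layer: str = "CA3",
    separation: float = 4.0,
    tolerance: float = 0.5,
    ordering: str = "encounter",
    reference_angle: float = 0.0,
    min_spikes: int = MIN_SPIKES,
) -> CrossCorrHistogram:
    """Average correlogram of pairs separated by ~4 cm along the trajectory.

    Pairs are selected by the projected centre distance along the running
    direction (within ``separation`` +/- ``tolerance``); each pair's
    histogram is normalised to unit sum before averaging so sparse pairs
    do not dominate.
    """
    grid = record.grids[layer]
    heading = float(trajectory.headings[0])
    spikes = _active_spikes(record, layer, min_spikes)
    ids = np.array(sorted(spikes), dtype=int)
    edges = corr_bin_edges()
    acc = np.zeros(len(edges) - 1)
    n_used = 0
    if ids.size >= 2:
        centers = grid.centers[ids]
        angle = heading if ordering == "encounter" else reference_angle
        unit = np.array([np.cos(angle), np.sin(angle)])
        proj = centers @ unit
        ii, jj = np.triu_indices(ids.size, k=1)
        dproj = proj[jj] - proj[ii]
        keep = np.abs(np.abs(dproj) - separation) <= tolerance
        for i, j in zip(ii[keep], jj[keep]):
            fi, se = (i, j) if proj[i] <= proj[j] else (j, i)
            t_first, t_next = spikes[ids[fi]], spikes[ids[se]]
            lags = (t_first[None, :] - t_next[:, None]).ravel()
            lags = lags[(lags >= edges[0]) & (lags < edges[-1])]
            h, _ = np.histogram(lags, bins=edges)
            s = h.sum()
            if s > 0:
                acc += h / s
                n_used += 1
    counts = acc / n_used if n_used else acc
    return CrossCorrHistogram(counts, edges)


def theta_compression(
    lag_phase_values, distances, slope_bound: float = 0.5
) -> tuple[float, float, int]:
    """Circular-linear regression of lag phase against field-centre distance.

    Returns (slope a in radians/cm, phase offset, n_pairs); (nan, nan, n)
    with fewer than 3 valid pairs.
    """
    phi = np.asarray(lag_phase_values, float)
    d = np.asarray(distances, float)
    ok = np.isfinite(phi) & np.isfinite(d)
    phi, d = phi[ok], d[ok]
    if phi.size < 3:
        return float("nan"), float("nan"), int(phi.size)
    a, phi0, _ = circlin_fit(phi, d, (-slope_bound, slope_bound))
    return float(a), float(phi0), int(phi.size)


def compression_slope(
    record: SpikeRecord, trajectory, layer: str = "CA3", **pair_kwargs
) -> tuple[float, pd.DataFrame]:
    """End-to-end theta-compression slope for one run.

    Builds all overlapping active pair correlograms, extracts their
    correlation-lag phases and regresses them against centre distance.
    Returns (slope, per-pair table with lag phases).
    """
    table, counts = pair_correlograms(record, trajectory, layer, **pair_kwargs)
    phases = lag_phases(counts)
    table = table.assign(lag_phase=phases)
    a, phi0, n = theta_compression(phases, table["distance"].to_numpy())
    return a, table


# ---------------------------------------------------------------------------
# pair direction classes and Ex/In population analysis
# ---------------------------------------------------------------------------

def classify_pairs(
    psi_i, psi_j, trajectory_angle, best_deg: float = 30.0, worst_deg: float = 150.0
) -> tuple[np.ndarray, np.ndarray]:
    """Best/worst and similar/dissimilar classes for field pairs.

    A pair is "both-best" when both preferred directions lie within 30 deg
    of the running direction, "both-worst" when both differ by more than
    150 deg; independently it is "similar"/"dissimilar" when the two
    preferred directions differ by less than 30 / more than 150 deg.
    Returns two label arrays (bw_class, sim_class) with "other" elsewhere.
    """
    psi_i = np.atleast_1d(np.asarray(psi_i, float))
    psi_j = np.atleast_1d(np.asarray(psi_j, float))
    best = np.deg2rad(best_deg)
    worst = np.deg2rad(worst_deg)
    di = circular_difference(psi_i, trajectory_angle)
    dj = circular_difference(psi_j, trajectory_angle)
    bw = np.where(
        (di < best) & (dj < best), "both-best",
        np.where((di > worst) & (dj > worst), "both-worst", "other"),
    )
    dij = circular_difference(psi_i, psi_j)
    sim = np.where(
        dij < best, "similar", np.where(dij > worst, "dissimilar", "other")
    )
    return bw, sim


def ex_in_table(
    record_fwd: SpikeRecord,
    record_rev: SpikeRecord,
    trajectory_fwd,
    layer: str = "CA3",
    max_distance: float = OVERLAP_DISTANCE,
    min_spikes: int = MIN_SPIKES,
) -> pd.DataFrame:
    """Extrinsicity/intrinsicity of all overlapping pairs from paired runs.

    ``record_fwd`` / ``record_rev`` are simulations of the same network on
    opposite running directions.  Pairs must be active (>5 spikes) in both
    runs.  The returned table carries Ex, In, the extrinsic/intrinsic
    class, centre distance and orientation, and the direction classes
    relative to the forward run.
    """
    grid = record_fwd.grids[layer]
    heading = float(trajectory_fwd.headings[0])
    sp_f = _active_spikes(record_fwd, layer, min_spikes)
    sp_r = _active_spikes(record_rev, layer, min_spikes)
    ids = np.array(sorted(set(sp_f) & set(sp_r)), dtype=int)
    rows = []
    if ids.size >= 2:
        centers = grid.centers[ids]
        fi, se, dist = _pair_indices(
            ids, centers, heading, max_distance, "encounter", 0.0
        )
        edges = corr_bin_edges()
        for k in range(fi.size):
            id_a, id_b = ids[fi[k]], ids[se[k]]

            def _hist(spikes, first, nxt):
                lags = (spikes[first][None, :] - spikes[nxt][:, None]).ravel()
                lags = lags[(lags >= edges[0]) & (lags < edges[-1])]
                return np.histogram(lags, bins=edges)[0]

            # encounter order swaps between the two running directions
            h_fwd = _hist(sp_f, id_a, id_b)
            h_rev = _hist(sp_r, id_b, id_a)
            ex, inn = ex_in(h_fwd, h_rev)
            if not np.isfinite(ex):
                continue
            dc = grid.centers[id_b] - grid.centers[id_a]
            rows.append(
                {
                    "id_first": id_a,
                    "id_next": id_b,
                    "distance": dist[k],
                    "orientation": wrap_angle(np.arctan2(dc[1], dc[0])),
                    "ex": ex,
                    "in": inn,
                    "psi_first": grid.preferred_dirs[id_a],
                    "psi_next": grid.preferred_dirs[id_b],
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "id_first", "id_next", "distance", "orientation",
            "ex", "in", "psi_first", "psi_next",
        ],
    )
    if len(table):
        bw, sim = classify_pairs(
            table["psi_first"].to_numpy(), table["psi_next"].to_numpy(), heading
        )
        table["bw_class"] = bw
        table["sim_class"] = sim
        table["pair_class"] = np.where(
            table["ex"] > table["in"], "extrinsic", "intrinsic"
        )
    else:
        table["bw_class"] = table["sim_class"] = table["pair_class"] = []
    return table


def extrinsic_fraction(table: pd.DataFrame, column: str, label: str) -> float:
    """Fraction of extrinsically classified pairs within one class label."""
    sub = table[table[column] == label]
    if len(sub) == 0:
        return float("nan")
    return float((sub["pair_class"] == "extrinsic").mean())


# ---------------------------------------------------------------------------
# spike-time gradient maps
# ---------------------------------------------------------------------------

def gradient_map(
    record: SpikeRecord, window: tuple[float, float], layer: str = "CA3"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-field-centre travelling-direction arrows for one theta cycle.

    For each centre the arrow is the sum over its 8 lattice neighbours of
    the unit vector towards the neighbour weighted by the difference of
    mean spike times (neighbour minus own) within the cycle window, so
    arrows point towards later-spiking neighbours -- the direction the
    sequence travels.  Returns (arrows (n, 2), valid mask); silent cells
    and cells without spiking neighbours are invalid.
    """
    grid = record.grids[layer]
    t0, t1 = window
    ev = record.events
    sel = (ev["layer"] == layer) & (ev["t_ms"] >= t0) & (ev["t_ms"] < t1)
    sub = ev[sel]
    n_side = grid.n_side
    mean_t = np.full(grid.n, np.nan)
    if len(sub):
        g = sub.groupby("neuron_id")["t_ms"].mean()
        mean_t[g.index.to_numpy()] = g.to_numpy()
    mt = mean_t.reshape(n_side, n_side)  # row-major: [row, col]
    arrows = np.zeros((grid.n, 2))
    valid = np.zeros(grid.n, dtype=bool)
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r in range(n_side):
        for c in range(n_side):
            own = mt[r, c]
            if not np.isfinite(own):
                continue
            vec = np.zeros(2)
            found = False
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_side and 0 <= cc < n_side and np.isfinite(mt[rr, cc]):
                    u = np.array([dc, dr], float)  # col -> x, row -> y
                    u /= np.linalg.norm(u)
                    vec += u * (mt[rr, cc] - own)
                    found = True
            i = r * n_side + c
            arrows[i] = vec
            valid[i] = found
    return arrows, valid
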