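"""Synaptic weight matrices of the CA3-DG network.

All excitatory weight rules share the same structure: a Gaussian envelope
over the distance between place-field centres (width sigma = 2 cm) times a
von-Mises-like gain on the similarity of preferred heading directions.
The DG loop adds two asymmetries: outgoing CA3->DG connections are gated
onto a 40-cm path through the loop anchor, and DG->CA3 projections target
CA3 cells displaced by 4 cm along the loop direction theta_DG, which is
what turns the loop into a hard-wired sequence generator.

Matrices are dense float32 with entries below 1e-10 zeroed.  W[i, j] is the
strength of the synapse from presynaptic cell j to postsynaptic cell i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import PlaceCellGrid

_CUTOFF = 1e-10
_CHUNK = 1024

#: length (cm) of the DG->CA3 target displacement along the loop direction
LOOP_SHIFT = 4.0
#: the intrinsic path samples p_k = anchor + 2k*(cos, sin), k in [-10, 10]
LOOP_PATH_K = np.arange(-10, 11)


@dataclass
class WeightMatrix:
    """Dense weight block with layer tags; shape (n_target, n_source)."""

    W: np.ndarray
    source: str
    target: str

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float32)
        if np.any(self.W < 0) or not np.all(np.isfinite(self.W)):
            raise ValueError("weights must be finite and non-negative")

    @property
    def shape(self):
        return self.W.shape


def _require_dirs(grid: PlaceCellGrid):
    if grid.preferred_dirs is None:
        raise ValueError(
            f"{grid.layer} grid has no preferred directions assigned"
        )


def _gaussian_envelope(post_centers, pre_centers, sigma):
    """exp(-d^2 / 2 sigma^2) for all (post, pre) centre pairs."""
    d2 = (
        np.sum(post_centers**2, axis=1)[:, None]
        + np.sum(pre_centers**2, axis=1)[None, :]
        - 2.0 * post_centers @ pre_centers.T
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * sigma**2))


def _direction_gain(post_dirs, pre_dirs, K):
    """exp(K * (cos(psi_i - psi_j) - 1)) for all (post, pre) pairs."""
    return np.exp(K * (np.cos(post_dirs[:, None] - pre_dirs[None, :]) - 1.0))


def ca3_weights(
    grid: PlaceCellGrid,
    B_pos: float,
    B_dir: float,
    K_CA3: float,
    sigma: float,
    asymmetry_on: bool = False,
) -> WeightMatrix:
    """Recurrent CA3->CA3 weights.

    W_ij = J_ij * (B_pos + B_dir * exp[K_CA3 (cos(psi_i - psi_j) - 1)])
                * exp(-d(p_i, p_j)^2 / 2 sigma^2)

    With ``asymmetry_on`` the rigid rightward asymmetry J_ij = 1[x_j < x_i]
    restricts projections to rightward neighbours (strict inequality; ties
    give 0).  Self-connections follow the same formula.
    """
    _require_dirs(grid)
    n = grid.n
    out = np.empty((n, n), dtype=np.float32)
    c, psi = grid.centers, grid.preferred_dirs
    for lo in range(0, n, _CHUNK):
        hi = min(lo + _CHUNK, n)
        g = _gaussian_envelope(c[lo:hi], c, sigma)
        if B_dir != 0.0:
            amp = B_pos + B_dir * _direction_gain(psi[lo:hi], psi, K_CA3)
        else:
            amp = B_pos
        block = amp * g
        if asymmetry_on:
            block = block * (c[None, :, 0] < c[lo:hi, 0][:, None])
        out[lo:hi] = block
    out[out < _CUTOFF] = 0.0
    return WeightMatrix(out, source="CA3", target="CA3")


def loop_path_points(theta_DG: float, anchor=(0.0, 0.0)) -> np.ndarray:
    """The 21 sample points of the intrinsic path, spaced 2 cm apart."""
    anchor = np.asarray(anchor, float)
    direction = np.array([np.cos(theta_DG), np.sin(theta_DG)])
    return anchor[None, :] + 2.0 * LOOP_PATH_K[:, None] * direction[None, :]


def ca3_path_gain(
    ca3: PlaceCellGrid, sigma: float, theta_DG: float, anchor=(0.0, 0.0)
) -> np.ndarray:
    """Per-CA3-cell gain C_j: max Gaussian proximity to the intrinsic path."""
    pts = loop_path_points(theta_DG, anchor)
    d2 = np.sum((ca3.centers[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    return np.exp(-d2.min(axis=1) / (2.0 * sigma**2))


def ca3_to_dg_weights(
    ca3: PlaceCellGrid,
    dg: PlaceCellGrid,
    B_DG: float,
    K_DG: float,
    sigma: float,
    theta_DG: float,
    loop_anchor=(0.0, 0.0),
) -> WeightMatrix:
    """CA3->DG weights, gated by the path gain of the presynaptic CA3 cell.

    W_ij = C_j * B_DG * exp[K_DG (cos(psi_i^DG - psi_j^CA3) - 1)]
               * exp(-d(p_i^DG, p_j^CA3)^2 / 2 sigma^2)
    """
    _require_dirs(ca3)
    _require_dirs(dg)
    gain = ca3_path_gain(ca3, sigma, theta_DG, loop_anchor)
    W = (
        gain[None, :]
        * B_DG
        * _direction_gain(dg.preferred_dirs, ca3.preferred_dirs, K_DG)
        * _gaussian_envelope(dg.centers, ca3.centers, sigma)
    )
    W[W < _CUTOFF] = 0.0
    return WeightMatrix(W, source="CA3", target="DG")


def dg_to_ca3_weights(
    dg: PlaceCellGrid,
    ca3: PlaceCellGrid,
    B_DG: float,
    K_DG: float,
    sigma: float,
    theta_DG: float,
) -> WeightMatrix:
    """DG->CA3 weights targeting centres shifted 4 cm along the loop.

    W_ij = B_DG * exp[K_DG (cos(psi_i^CA3 - psi_j^DG) - 1)]
               * exp(-d(p_i^CA3 - r, p_j^DG)^2 / 2 sigma^2),
    r = 4 cm * (cos theta_DG, sin theta_DG).

    There are never DG->DG connections.
    """
    _require_dirs(ca3)
    _require_dirs(dg)
    r = LOOP_SHIFT * np.array([np.cos(theta_DG), np.sin(theta_DG)])
    W = (
        B_DG
        * _direction_gain(ca3.preferred_dirs, dg.preferred_dirs, K_DG)
        * _gaussian_envelope(ca3.centers - r[None, :], dg.centers, sigma)
    )
    W[W < _CUTOFF] = 0.0
    return WeightMatrix(W, source="DG", target="CA3")


def inhibitory_weights(
    n_post: int, n_pre: int, W0: float, seed: int, source: str, target: str
) -> WeightMatrix:
    """All-to-all block with uniformly randomised strengths W0 * U(0, 1).

    Used for both excitatory->interneuron feedback loops; there is no
    interneuron->interneuron block anywhere in the model.
    """
    if W0 < 0:
        raise ValueError("W0 must be non-negative")
    rng = np.random.default_rng(seed)
    W = W0 * rng.uniform(0.0, 1.0, size=(n_post, n_pre))
    return WeightMatrix(W.astype(np.float32), source=source, target=target)
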