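"""Arena geometry, place-cell grids and running trajectories.

Coordinates are continuous 2-d positions in centimetres with the arena
centred at the origin, so the default 80 x 80 cm arena spans [-40, 40] on
both axes.  Angles are radians everywhere inside the library and are wrapped
to [0, 2*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles (radians) to the interval [0, 2*pi).

    np.mod can round tiny negative inputs up to exactly 2*pi; those are
    mapped back to 0 so the half-open interval contract holds.
    """
    w = np.mod(theta, TWO_PI)
    w = np.where(w >= TWO_PI, 0.0, w)
    return float(w) if np.ndim(theta) == 0 else w


def circular_difference(a, b):
    """Absolute circular difference between two angles, in [0, pi]."""
    d = np.mod(np.asarray(a) - np.asarray(b), TWO_PI)
    return np.minimum(d, TWO_PI - d)


@dataclass(frozen=True)
class Arena:
    """Rectangular open-field arena centred at the origin."""

    width: float = 80.0
    height: float = 80.0

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena dimensions must be positive")

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of positions (..., 2) inside the arena."""
        p = np.asarray(positions, float)
        return (
            (np.abs(p[..., 0]) <= self.width / 2.0)
            & (np.abs(p[..., 1]) <= self.height / 2.0)
        )


@dataclass
class PlaceCellGrid:
    """A population of place cells whose field centres tile the arena.

    centers        -- (n, 2) field centres in cm
    preferred_dirs -- (n,) preferred heading angles in [0, 2*pi), or None
                      until :func:`assign_preferred_directions` is called
    n_side         -- cells per axis; n = n_side**2
    layer          -- population tag, "CA3" or "DG"
    """

    centers: np.ndarray
    n_side: int
    layer: str
    arena: Arena
    preferred_dirs: np.ndarray | None = field(default=None)

    @property
    def n(self) -> int:
        return self.centers.shape[0]

    @property
    def spacing(self) -> float:
        return self.arena.width / self.n_side


def build_grid(arena: Arena, n_side: int, layer: str = "CA3") -> PlaceCellGrid:
    """Regular n_side x n_side lattice of field centres spanning the arena.

    Centres sit at the midpoints of an n_side x n_side partition, keeping
    the lattice symmetric about the arena centre (first centre at
    -width/2 + spacing/2).  Preferred directions are left unset.
    """
    if n_side < 1:
        raise ValueError(f"n_side must be >= 1, got {n_side}")
    xs = -arena.width / 2.0 + (np.arange(n_side) + 0.5) * arena.width / n_side
    ys = -arena.height / 2.0 + (np.arange(n_side) + 0.5) * arena.height / n_side
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    centers = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    return PlaceCellGrid(centers=centers, n_side=n_side, layer=layer, arena=arena)


def assign_preferred_directions(grid: PlaceCellGrid, seed: int) -> PlaceCellGrid:
    """Semi-randomised preferred heading directions on 2 x 2 tiles.

    Within every 2 x 2 tile of neighbouring cells the four preferred angles
    are {0, 90, 180, 270} degrees plus a common random rotation drawn
    uniformly per tile, so the four angles always stay 90 degrees apart
    while the marginal distribution over many tiles is uniform.
    """
    if grid.n_side % 2 != 0:
        raise ValueError("n_side must be even to partition the grid into 2x2 tiles")
    rng = np.random.default_rng(seed)
    n = grid.n_side
    half = n // 2
    xi = rng.uniform(0.0, TWO_PI, size=(half, half))
    base = np.array([0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi])
    psi = np.empty((n, n))
    # row-major lattice; cell (row, col) belongs to tile (row//2, col//2) and
    # takes the quadrant angle indexed by its position within the tile
    rows, cols = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    quadrant = (rows % 2) * 2 + (cols % 2)
    psi = base[quadrant] + xi[rows // 2, cols // 2]
    return replace(grid, preferred_dirs=wrap_angle(psi.ravel()))


@dataclass
class Trajectory:
    """Time-stamped positions and headings of the simulated animal.

    times in ms on a uniform grid at dt, positions in cm, headings in
    radians.  All arrays share the same length.
    """

    times: np.ndarray
    positions: np.ndarray
    headings: np.ndarray
    dt: float

    def __post_init__(self):
        if not (len(self.times) == len(self.positions) == len(self.headings)):
            raise ValueError("times, positions and headings must be equally long")

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


def make_straight_trajectory(
    start,
    direction: float,
    speed: float,
    duration: float,
    dt: float = 0.1,
    arena: Arena | None = None,
) -> Trajectory:
    """Straight constant-speed run.

    start     -- (x, y) in cm
    direction -- heading angle phi in radians
    speed     -- cm/s
    duration  -- ms
    dt        -- ms

    p(t) = start + speed * t * (cos phi, sin phi) with constant heading phi.
    Raises if the path leaves the arena, naming the first offending time.
    """
    arena = arena or Arena()
    times = np.arange(0.0, duration + dt / 2.0, dt)
    start = np.asarray(start, float)
    vel = speed * 1e-3 * np.array([np.cos(direction), np.sin(direction)])  # cm/ms
    positions = start[None, :] + times[:, None] * vel[None, :]
    inside = arena.contains(positions)
    if not inside.all():
        t_bad = times[np.flatnonzero(~inside)[0]]
        raise ValueError(f"trajectory leaves the arena at t={t_bad:.1f} ms")
    headings = np.full_like(times, wrap_angle(direction))
    return Trajectory(times=times, positions=positions, headings=headings, dt=dt)
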