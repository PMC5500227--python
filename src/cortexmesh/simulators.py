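"""Reference random-walk simulators for membrane-protein dynamics.

Four trajectory classes used to benchmark subdiffusion analyses:

* free Brownian motion (i.i.d. Gaussian increments);
* fractional Brownian motion (fBM) with Hurst exponent ``H`` — subdiffusive,
  anticorrelated increments for ``H < 1/2``, anomalous MSD exponent
  ``alpha = 2H``;
* obstructed diffusion on a square lattice with immobile obstacles (site
  percolation), the blind-ant convention;
* hop diffusion among permeable fences on a square grid with a single
  compartment length scale.

All simulators are fully seeded: one root seed per call, split into one
independent stream per trajectory index, so results do not depend on how
trajectories are batched.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .errors import EmptyInputError, InvalidParameterError
from .trajectory import Trajectory, TrajectoryEnsemble

__all__ = [
    "FBMParams",
    "LatticeWorld",
    "FenceWorld",
    "PercolationEstimate",
    "fgn_autocovariance",
    "simulate_fbm",
    "simulate_brownian",
    "build_obstacle_lattice",
    "simulate_obstructed_walk",
    "estimate_percolation_threshold",
    "simulate_fenced_diffusion",
]


# ---------------------------------------------------------------------------
# fractional Brownian motion
# ---------------------------------------------------------------------------

@dataclass
class FBMParams:
    """Parameters for a 2D fBM ensemble.

    ``step_scale`` is the per-step displacement scale sigma in μm: each
    coordinate is an fBM path with Var[x(k dt)] = sigma^2 k^{2H}.
    """

    hurst: float
    n_steps: int
    dt: float = 0.02
    step_scale: float = 0.1
    n_traj: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise InvalidParameterError(f"hurst must be in (0, 1), got {self.hurst}")
        if self.n_steps < 1:
            raise InvalidParameterError("n_steps must be >= 1")
        if self.dt <= 0:
            raise InvalidParameterError("dt must be > 0")
        if self.n_traj < 1:
            raise InvalidParameterError("n_traj must be >= 1")


def fgn_autocovariance(lags, hurst: float, sigma: float = 1.0) -> np.ndarray:
    """Exact autocovariance of fractional Gaussian noise.

    gamma(k) = (sigma^2 / 2) (|k+1|^{2H} - 2|k|^{2H} + |k-1|^{2H})
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * sigma**2 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _davies_harte_eigenvalues(n: int, hurst: float) -> np.ndarray | None:
    """Eigenvalues of the circulant embedding of the fGn covariance.

    Returns None when the embedding is not nonnegative-definite (then the
    caller falls back to Hosking's recursion).
    """
    gamma = fgn_autocovariance(np.arange(n + 1), hurst)
    circ = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    lam = np.fft.fft(circ).real
    if lam.min() < -1e-9 * lam.max():
        return None
    return np.clip(lam, 0.0, None)


def _fgn_davies_harte(lam: np.ndarray, normals: np.ndarray) -> np.ndarray:
    """Map (batch, 2n) standard normals to (batch, n) exact fGn samples."""
    m = lam.shape[0]
    n = m // 2
    batch = normals.shape[0]
    w = np.zeros((batch, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0] / m) * normals[:, 0]
    w[:, n] = np.sqrt(lam[n] / m) * normals[:, 1]
    re = normals[:, 2::2]
    im = normals[:, 3::2]
    half = np.sqrt(lam[1:n] / (2 * m))
    w[:, 1:n] = half * (re + 1j * im)
    w[:, n + 1:] = np.conj(w[:, 1:n][:, ::-1])
    return np.fft.fft(w, axis=1).real[:, :n]


def _fgn_hosking(hurst: float, n: int, normals: np.ndarray) -> np.ndarray:
    """Hosking's exact recursive synthesis, O(n^2); fallback path."""
    gamma = fgn_autocovariance(np.arange(n), hurst)
    batch = normals.shape[0]
    out = np.empty((batch, n))
    phi = np.zeros(n)
    out[:, 0] = normals[:, 0] * np.sqrt(gamma[0])
    var = gamma[0]
    for i in range(1, n):
        phi_prev = phi[: i - 1].copy()
        kappa = (gamma[i] - phi_prev @ gamma[1:i][::-1]) / var if i > 1 else gamma[1] / var
        phi[i - 1] = kappa
        if i > 1:
            phi[: i - 1] = phi_prev - kappa * phi_prev[::-1]
        var *= 1.0 - kappa**2
        mean = out[:, :i] @ phi[:i][::-1]
        out[:, i] = mean + np.sqrt(var) * normals[:, i]
    return out


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_fbm(params: FBMParams) -> TrajectoryEnsemble:
    """Simulate an ensemble of 2D fBM trajectories.

    x and y are independent fBM paths with the exact fGn increment
    autocovariance; synthesis uses circulant embedding (Davies–Harte) with
    Hosking's recursion as fallback.  All paths start at the origin.
    """
    n = params.n_steps
    lam = _davies_harte_eigenvalues(n, params.hurst)
    rngs = _child_rngs(params.seed, params.n_traj)
    normals = np.stack([rng.standard_normal(2 * (2 * n)) for rng in rngs])
    normals = normals.reshape(params.n_traj * 2, 2 * n)
    if lam is not None:
        fgn = _fgn_davies_harte(lam, normals)
    else:
        fgn = _fgn_hosking(params.hurst, n, normals[:, :n])
    fgn = fgn.reshape(params.n_traj, 2, n) * params.step_scale
    times = np.arange(n + 1) * params.dt
    trajectories = []
    for i in range(params.n_traj):
        pos = np.zeros((n + 1, 2))
        pos[1:, 0] = np.cumsum(fgn[i, 0])
        pos[1:, 1] = np.cumsum(fgn[i, 1])
        trajectories.append(Trajectory(f"fbm-{i}", times, pos))
    return TrajectoryEnsemble(trajectories, frame_interval=params.dt)


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------

def simulate_brownian(
    diffusivity: float,
    dt: float,
    n_steps: int,
    n_traj: int,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Free 2D Brownian motion: per-axis i.i.d. Gaussian increments of
    variance 2 D dt, so the ensemble MSD is 4 D Δ."""
    if diffusivity < 0:
        raise InvalidParameterError("diffusivity must be >= 0")
    if dt <= 0 or n_steps < 1 or n_traj < 1:
        raise InvalidParameterError("dt, n_steps and n_traj must be positive")
    sd = np.sqrt(2.0 * diffusivity * dt)
    times = np.arange(n_steps + 1) * dt
    trajectories = []
    for i, rng in enumerate(_child_rngs(seed, n_traj)):
        steps = rng.normal(0.0, sd, size=(n_steps, 2)) if sd > 0 else np.zeros((n_steps, 2))
        pos = np.zeros((n_steps + 1, 2))
        pos[1:] = np.cumsum(steps, axis=0)
        trajectories.append(Trajectory(f"bm-{i}", times, pos))
    return TrajectoryEnsemble(trajectories, frame_interval=dt)


# ---------------------------------------------------------------------------
# obstructed (percolation) diffusion
# ---------------------------------------------------------------------------

@dataclass
class LatticeWorld:
    """A square lattice with immobile obstacles (True = obstacle)."""

    side: int
    obstacle_fraction: float
    occupancy: np.ndarray
    lattice_constant: float = 0.05
    periodic: bool = True
    seed: int = 0


def build_obstacle_lattice(
    side: int,
    obstacle_fraction: float,
    lattice_constant: float = 0.05,
    seed: int = 0,
) -> LatticeWorld:
    """Place exactly round(fraction * side^2) obstacles uniformly at random."""
    if not 0.0 <= obstacle_fraction < 1.0:
        raise InvalidParameterError("obstacle_fraction must be in [0, 1)")
    if side < 1:
        raise InvalidParameterError("side must be >= 1")
    n_sites = side * side
    n_obstacles = int(round(obstacle_fraction * n_sites))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    occupancy = np.zeros(n_sites, dtype=bool)
    occupancy[rng.choice(n_sites, size=n_obstacles, replace=False)] = True
    return LatticeWorld(
        side=side,
        obstacle_fraction=obstacle_fraction,
        occupancy=occupancy.reshape(side, side),
        lattice_constant=lattice_constant,
        seed=seed,
    )


_DIRECTIONS = np.array([[1, 0], [-1, 0], [0, 1], [0, -1]])


def simulate_obstructed_walk(
    world: LatticeWorld,
    n_steps: int,
    n_traj: int,
    seed: int = 0,
    dt: float = 0.02,
    restrict_to_spanning: bool = False,
    myopic: bool = False,
    sample_every: int = 1,
) -> TrajectoryEnsemble:
    """Blind-ant random walk on the obstructed lattice.

    At each step one of the 4 neighbours is proposed uniformly; the walker
    moves iff the site is vacant, otherwise it stays put while time advances
    (blind ant).  With ``myopic=True`` the proposal is drawn among vacant
    neighbours only.  The lattice is periodic; reported coordinates are
    unwrapped and scaled by the lattice constant.

    ``sample_every`` records only every k-th elementary step, emulating an
    acquisition frame that spans many elementary hops (``dt`` is then the
    frame interval, not the hop time); ``n_steps`` counts elementary steps.
    """
    if sample_every < 1 or n_steps % sample_every:
        raise InvalidParameterError("sample_every must divide n_steps")
    vacant = ~world.occupancy
    if not vacant.any():
        raise EmptyInputError("lattice has no vacant site")
    if restrict_to_spanning:
        labels, _ = ndimage.label(vacant)
        span = _spanning_labels(labels)
        if not span:
            raise EmptyInputError("no spanning vacant cluster to start from")
        start_mask = np.isin(labels, list(span))
    else:
        start_mask = vacant
    start_sites = np.argwhere(start_mask)

    rngs = _child_rngs(seed, n_traj)
    starts = np.stack([start_sites[r.integers(len(start_sites))] for r in rngs])
    if myopic:
        # per-step uniform draws, mapped to the vacant-neighbour subset
        uniforms = np.stack([r.random(n_steps) for r in rngs])
    else:
        dirs = np.stack([r.integers(0, 4, size=n_steps) for r in rngs])

    side = world.side
    pos = starts.astype(np.int64)  # unwrapped
    path = np.empty((n_steps + 1, n_traj, 2), dtype=np.int64)
    path[0] = pos
    occ = world.occupancy
    for k in range(n_steps):
        if myopic:
            wrapped = np.mod(pos, side)
            neigh = wrapped[:, None, :] + _DIRECTIONS[None, :, :]
            neigh = np.mod(neigh, side)
            open_mask = ~occ[neigh[..., 0], neigh[..., 1]]
            n_open = open_mask.sum(axis=1)
            choice = np.minimum((uniforms[:, k] * n_open).astype(int), np.maximum(n_open - 1, 0))
            order = np.argsort(~open_mask, axis=1, kind="stable")
            picked = order[np.arange(n_traj), choice]
            move = _DIRECTIONS[picked]
            move[n_open == 0] = 0
            pos = pos + move
        else:
            move = _DIRECTIONS[dirs[:, k]]
            target = np.mod(pos + move, side)
            blocked = occ[target[:, 0], target[:, 1]]
            pos = pos + np.where(blocked[:, None], 0, move)
        path[k + 1] = pos

    path = path[::sample_every]
    n_frames = path.shape[0] - 1
    times = np.arange(n_frames + 1) * dt
    a = world.lattice_constant
    trajectories = [
        Trajectory(f"perc-{i}", times, path[:, i, :].astype(float) * a)
        for i in range(n_traj)
    ]
    return TrajectoryEnsemble(trajectories, frame_interval=dt)


def _spanning_labels(labels: np.ndarray) -> set:
    """Labels whose clusters span the grid from the first to the last row
    (the standard single-direction spanning rule)."""
    top = set(labels[0, :][labels[0, :] > 0])
    bottom = set(labels[-1, :][labels[-1, :] > 0])
    return top & bottom


def _vacant_spans(occupancy: np.ndarray) -> bool:
    labels, n = ndimage.label(~occupancy)
    if n == 0:
        return False
    return bool(_spanning_labels(labels))


class PercolationEstimate(NamedTuple):
    """Monte-Carlo estimate of the obstacle fraction at which vacant sites
    stop forming a spanning cluster."""

    threshold: float
    stderr: float
    per_realization: np.ndarray


def estimate_percolation_threshold(
    side: int,
    n_realizations: int,
    seed: int = 0,
) -> PercolationEstimate:
    """Estimate the obstacle concentration at which the vacant phase loses
    its side-spanning 4-connected cluster.

    Per realization, obstacle sites are added in a random order and the
    critical count is located by bisection on the (monotone) spanning
    property; the threshold is the mean critical fraction over realizations,
    with its standard error.
    """
    if side < 8:
        raise InvalidParameterError("side must be >= 8")
    if n_realizations < 1:
        raise InvalidParameterError("n_realizations must be >= 1")
    n_sites = side * side
    thresholds = np.empty(n_realizations)
    for i, rng in enumerate(_child_rngs(seed, n_realizations)):
        order = rng.permutation(n_sites)
        occ = np.zeros(n_sites, dtype=bool)
        # bisection: smallest obstacle count k at which spanning is lost
        lo, hi = 0, n_sites  # spans at lo, does not span at hi
        while hi - lo > 1:
            mid = (lo + hi) // 2
            occ[:] = False
            occ[order[:mid]] = True
            if _vacant_spans(occ.reshape(side, side)):
                lo = mid
            else:
                hi = mid
        thresholds[i] = hi / n_sites
    stderr = thresholds.std(ddof=1) / np.sqrt(n_realizations) if n_realizations > 1 else np.nan
    return PercolationEstimate(float(thresholds.mean()), float(stderr), thresholds)


# ---------------------------------------------------------------------------
# fenced hop diffusion
# ---------------------------------------------------------------------------

@dataclass
class FenceWorld:
    """Square grid of permeable fences with pitch ``compartment_side`` (μm).

    A Gaussian step that crosses a fence line is accepted with
    ``hop_probability``, otherwise the offending coordinate is reflected
    about the fence.
    """

    compartment_side: float
    hop_probability: float
    diffusivity: float
    dt: float = 0.02

    def __post_init__(self) -> None:
        if self.compartment_side <= 0:
            raise InvalidParameterError("compartment_side must be > 0")
        if not 0.0 <= self.hop_probability <= 1.0:
            raise InvalidParameterError("hop_probability must be in [0, 1]")
        if self.diffusivity < 0 or self.dt <= 0:
            raise InvalidParameterError("diffusivity must be >= 0 and dt > 0")


def _advance_coordinate(pos: float, target: float, pitch: float, hop_p: float, rng) -> float:
    """Advance one coordinate across the periodic fence grid.

    Each fence line strictly between the current position and the target is
    tested in crossing order; rejection reflects the remaining path about
    that fence.  Exact for grid fences because x and y crossings decouple.
    """
    for _ in range(10000):
        if target > pos:
            fence = (np.floor(pos / pitch) + 1.0) * pitch
            if fence >= target:
                return target
        elif target < pos:
            fence = np.ceil(pos / pitch - 1.0) * pitch
            if fence <= target:
                return target
        else:
            return target
        if hop_p >= 1.0 or (hop_p > 0.0 and rng.random() < hop_p):
            pos = fence + (1e-12 if target > pos else -1e-12) * pitch
        else:
            pos = fence
            target = 2.0 * fence - target
    raise RuntimeError("fence reflection did not terminate")


def simulate_fenced_diffusion(
    world: FenceWorld,
    n_steps: int,
    n_traj: int,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Hop diffusion among permeable fences.

    Brownian steps (variance 2 D dt per axis); each fence-line crossing is
    accepted with the hop probability, otherwise reflected.  Start positions
    are uniform within the compartment containing the origin.
    """
    if n_steps < 1 or n_traj < 1:
        raise InvalidParameterError("n_steps and n_traj must be >= 1")
    L = world.compartment_side
    sd = np.sqrt(2.0 * world.diffusivity * world.dt)
    times = np.arange(n_steps + 1) * world.dt
    trajectories = []
    for i, rng in enumerate(_child_rngs(seed, n_traj)):
        start = rng.uniform(0.0, L, size=2)
        steps = rng.normal(0.0, sd, size=(n_steps, 2))
        pos = np.empty((n_steps + 1, 2))
        pos[0] = start
        x, y = start
        for k in range(n_steps):
            x = _advance_coordinate(x, x + steps[k, 0], L, world.hop_probability, rng)
            y = _advance_coordinate(y, y + steps[k, 1], L, world.hop_probability, rng)
            pos[k + 1] = (x, y)
        trajectories.append(Trajectory(f"fence-{i}", times, pos))
    return TrajectoryEnsemble(trajectories, frame_interval=world.dt)
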