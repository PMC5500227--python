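"""Single-particle-tracking statistics.

Time-averaged mean square displacements (TA-MSD), power-law (anomalous
exponent) and linear (diffusivity) fits, and lag-resolved turning-angle
distributions.  The turning-angle distribution is the model-discrimination
tool: it is uniform for Brownian motion, peaked at 180° for anticorrelated
walks, lag-invariant for percolation-like obstruction and lag-dependent for
hop diffusion among fences with a single length scale.
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EmptyInputError, InvalidDataError, InvalidParameterError
from .trajectory import Trajectory, TrajectoryEnsemble

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "DiffusionFit",
    "AngleDistribution",
    "ta_msd",
    "ensemble_ta_msd",
    "fit_anomalous_exponent",
    "fit_diffusivity",
    "turning_angles",
    "angle_distribution",
    "angle_mode",
    "lag_invariance_statistic",
]


@dataclass
class MSDCurve:
    """TA-MSD values (μm²) vs lag times (s), with across-trajectory spread."""

    lags: np.ndarray
    values: np.ndarray
    spread: np.ndarray
    n_contributing: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise InvalidDataError("lags must be strictly increasing")


@dataclass
class PowerLawFit:
    """MSD ~ prefactor * lag^exponent, fitted in log-log coordinates."""

    exponent: float
    prefactor: float
    fit_range: tuple
    r_squared: float

    def summary(self) -> str:
        return (
            f"power-law MSD fit: alpha = {self.exponent:.4f}, "
            f"prefactor = {self.prefactor:.4g} um^2/s^alpha, "
            f"range = [{self.fit_range[0]:g}, {self.fit_range[1]:g}] s, "
            f"R^2 = {self.r_squared:.4f}"
        )


@dataclass
class DiffusionFit:
    """MSD = 4 D lag + intercept (2D convention)."""

    diffusivity: float
    intercept: float
    fit_range: tuple


@dataclass
class AngleDistribution:
    """Per-degree probability density of turning angles on [0°, 180°]."""

    lag: float
    bin_edges: np.ndarray
    density: np.ndarray
    n_angles: int
    n_skipped: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        widths = np.diff(self.bin_edges)
        total = float(np.sum(self.density * widths))
        if self.n_angles > 0 and abs(total - 1.0) > 1e-9:
            raise InvalidDataError(f"density must integrate to 1, got {total}")

    def cdf(self) -> np.ndarray:
        """Cumulative distribution at the right bin edges."""
        return np.cumsum(self.density * np.diff(self.bin_edges))


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def _lag_indices(traj: Trajectory, max_lag: float) -> np.ndarray:
    dt = traj.dt
    k_max = int(np.floor(max_lag / dt + 1e-9))
    k_max = min(k_max, len(traj) - 1)
    return np.arange(1, k_max + 1)


def ta_msd(traj: Trajectory, max_lag: float) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    For lag index k the estimator averages |r(i+k) - r(i)|² over all
    overlapping windows i = 0..N-1-k, the discrete form of the running
    time average over the full experimental time T.
    """
    if len(traj) < 2:
        raise InvalidDataError("trajectory too short for an MSD (need >= 2 points)")
    if max_lag >= traj.duration + traj.dt * 0.5 and max_lag > traj.duration:
        raise InvalidParameterError(f"max_lag {max_lag} >= total time {traj.duration}")
    ks = _lag_indices(traj, max_lag)
    if ks.size == 0:
        raise InvalidParameterError("max_lag below one frame interval")
    pos = traj.positions
    values = np.empty(ks.size)
    for j, k in enumerate(ks):
        d = pos[k:] - pos[:-k]
        values[j] = np.mean(np.einsum("ij,ij->i", d, d))
    return MSDCurve(ks * traj.dt, values, np.zeros_like(values), np.ones(ks.size, dtype=int))


def ensemble_ta_msd(ensemble: TrajectoryEnsemble, max_lag: float) -> MSDCurve:
    """Ensemble average of per-trajectory TA-MSDs, each trajectory weighted
    equally; spread is the per-lag standard deviation across trajectories."""
    if len(ensemble) == 0:
        raise EmptyInputError("empty trajectory ensemble")
    curves = [ta_msd(t, min(max_lag, t.duration - t.dt * 0.5)) for t in ensemble
              if len(t) >= 2]
    if not curves:
        raise EmptyInputError("no trajectory long enough for an MSD")
    dt = ensemble.frame_interval
    k_max = max(c.lags.size for c in curves)
    sums = np.zeros(k_max)
    sq_sums = np.zeros(k_max)
    counts = np.zeros(k_max, dtype=int)
    for c in curves:
        m = c.lags.size
        sums[:m] += c.values
        sq_sums[:m] += c.values**2
        counts[:m] += 1
    keep = counts > 0
    mean = sums[keep] / counts[keep]
    var = np.maximum(sq_sums[keep] / counts[keep] - mean**2, 0.0)
    lags = (np.arange(1, k_max + 1) * dt)[keep]
    return MSDCurve(lags, mean, np.sqrt(var), counts[keep])


def _fit_window(msd: MSDCurve, fit_range) -> np.ndarray:
    lo, hi = fit_range
    mask = (msd.lags >= lo - 1e-12) & (msd.lags <= hi + 1e-12)
    return np.flatnonzero(mask)


def fit_anomalous_exponent(msd: MSDCurve, fit_range) -> PowerLawFit:
    """Unweighted least-squares line of log(MSD) on log(lag); the slope is
    the anomalous exponent alpha."""
    idx = _fit_window(msd, fit_range)
    if idx.size < 3:
        raise InvalidDataError(f"need >= 3 lags inside fit range, got {idx.size}")
    vals = msd.values[idx]
    if np.any(vals <= 0):
        raise InvalidDataError("nonpositive MSD value inside fit range")
    x = np.log(msd.lags[idx])
    y = np.log(vals)
    res = stats.linregress(x, y)
    return PowerLawFit(
        exponent=float(res.slope),
        prefactor=float(np.exp(res.intercept)),
        fit_range=tuple(fit_range),
        r_squared=float(res.rvalue**2),
    )


def fit_diffusivity(msd: MSDCurve, fit_range) -> DiffusionFit:
    """Ordinary least squares of MSD on lag; D = slope / 4 (2D)."""
    idx = _fit_window(msd, fit_range)
    if idx.size < 3:
        raise InvalidDataError(f"need >= 3 lags inside fit range, got {idx.size}")
    res = stats.linregress(msd.lags[idx], msd.values[idx])
    return DiffusionFit(
        diffusivity=float(res.slope / 4.0),
        intercept=float(res.intercept),
        fit_range=tuple(fit_range),
    )


def default_fit_range(msd: MSDCurve, dt: float) -> tuple:
    """Default MSD fit window: 2 dt up to min(1 s, T/4)."""
    t_max = msd.lags[-1] + dt
    return (2 * dt, min(1.0, t_max / 4.0))


# ---------------------------------------------------------------------------
# turning angles
# ---------------------------------------------------------------------------

def _lag_to_steps(lag: float, dt: float) -> int:
    k = lag / dt
    k_int = int(round(k))
    if k_int < 1 or abs(k - k_int) > 1e-6 * max(1.0, abs(k)):
        raise InvalidParameterError(f"lag {lag} is not a positive multiple of dt {dt}")
    return k_int


def turning_angles(traj: Trajectory, lag: float, return_skips: bool = False):
    """Unsigned turning angles (degrees) of one trajectory at one lag.

    For each start index t, the angle between v1 = r(t+Δ) - r(t) and
    v2 = r(t+2Δ) - r(t+Δ), computed via atan2(|cross|, dot) ∈ [0°, 180°].
    Overlapping triplets are used.  Pairs in which either displacement is
    exactly zero (undefined direction) are skipped and counted.
    """
    k = _lag_to_steps(lag, traj.dt)
    if len(traj) < 2 * k + 1:
        if return_skips:
            return np.empty(0), 0
        return np.empty(0)
    pos = traj.positions
    v1 = pos[k:-k] - pos[:-2 * k]
    v2 = pos[2 * k:] - pos[k:-k]
    valid = (np.einsum("ij,ij->i", v1, v1) > 0) & (np.einsum("ij,ij->i", v2, v2) > 0)
    cross = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
    dot = np.einsum("ij,ij->i", v1, v2)
    angles = np.degrees(np.arctan2(np.abs(cross[valid]), dot[valid]))
    if return_skips:
        return angles, int((~valid).sum())
    return angles


def angle_distribution(
    ensemble: TrajectoryEnsemble,
    lags,
    bin_width: float = 5.0,
) -> list[AngleDistribution]:
    """Pooled turning-angle densities per lag over an ensemble.

    Angles are pooled across all trajectories, histogrammed on [0°, 180°]
    with the given bin width and normalized to unit integral (per-degree
    density).
    """
    if len(ensemble) == 0:
        raise EmptyInputError("empty trajectory ensemble")
    edges = np.arange(0.0, 180.0 + bin_width * 0.5, bin_width)
    if not np.isclose(edges[-1], 180.0):
        edges = np.append(edges, 180.0)
    out = []
    for lag in np.atleast_1d(lags):
        pooled = []
        skipped = 0
        for traj in ensemble:
            a, s = turning_angles(traj, float(lag), return_skips=True)
            pooled.append(a)
            skipped += s
        angles = np.concatenate(pooled) if pooled else np.empty(0)
        if angles.size == 0:
            raise EmptyInputError(f"no valid turning-angle pairs at lag {lag}")
        counts, _ = np.histogram(np.clip(angles, 0.0, 180.0), bins=edges)
        density = counts / (angles.size * np.diff(edges))
        out.append(AngleDistribution(float(lag), edges, density, int(angles.size), skipped))
    return out


def angle_mode(dist: AngleDistribution, return_tie: bool = False):
    """Location (degrees) of the maximal-density bin.

    Ties are broken toward 180°; the 180° edge bin is reported as 180°
    (its closed upper edge), interior bins by their centre.  With
    ``return_tie`` also returns whether the maximum was tied.
    """
    if dist.n_angles == 0:
        raise EmptyInputError("empty angle distribution")
    dens = dist.density
    maximal = np.flatnonzero(np.isclose(dens, dens.max(), rtol=1e-12, atol=0.0))
    best = maximal[-1]
    if best == len(dens) - 1:
        mode = 180.0
    else:
        mode = float(0.5 * (dist.bin_edges[best] + dist.bin_edges[best + 1]))
    if return_tie:
        return mode, len(maximal) > 1
    return mode


def is_edge_mode(dist: AngleDistribution) -> bool:
    """True when the maximal bin is the 180° edge bin."""
    dens = dist.density
    return bool(np.isclose(dens[-1], dens.max(), rtol=1e-12, atol=0.0))


def lag_invariance_statistic(dists: list[AngleDistribution]) -> float:
    """Maximum pairwise two-sample KS statistic (sup-norm of binned CDF
    differences) over a family of turning-angle distributions.

    Small values mean the distribution is (nearly) independent of lag —
    the signature of scale-free obstructed diffusion; hop diffusion with a
    single compartment scale produces a larger statistic.
    """
    if len(dists) < 2:
        raise InvalidParameterError("need >= 2 distributions")
    edges = dists[0].bin_edges
    for d in dists[1:]:
        if d.bin_edges.shape != edges.shape or not np.allclose(d.bin_edges, edges):
            raise InvalidParameterError("distributions must share identical bins")
    cdfs = np.stack([d.cdf() for d in dists])
    stat = 0.0
    for i in range(len(dists)):
        for j in range(i + 1, len(dists)):
            stat = max(stat, float(np.max(np.abs(cdfs[i] - cdfs[j]))))
    return stat
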