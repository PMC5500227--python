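"""Synthetic cortical-actin meshworks and localization microscopy data.

The generator realizes Kolmogorov's repeated-fragmentation picture of the
actin-delimited compartments: starting from the whole field of view,
compartments are recursively split by growing "filaments" (axis-aligned
chords) at positions drawn from a size-independent fraction law, which
drives the compartment-area distribution toward log-normal.  Fence segments
are decorated with localizations of finite precision (the experimental
localization accuracy is 20 ± 8 nm), localizations are rendered into
superresolution-style pixel images, and trajectories can be confined by the
fences with a permeable-hop rule.  Reference fractal rasters with known
box-counting dimension provide oracles for the image pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError
from .trajectory import Trajectory, TrajectoryEnsemble

__all__ = [
    "Compartment",
    "MeshworkModel",
    "LocalizationTable",
    "MeshImage",
    "generate_fragmentation_meshwork",
    "meshwork_to_localizations",
    "render_localizations",
    "simulate_meshwork_confined_tracks",
    "make_reference_fractals",
    "read_localizations",
    "write_localizations",
]

#: Acquisition rate used to map frames to seconds (50 frames/s).
FRAMES_PER_SECOND = 50.0


@dataclass
class Compartment:
    """An axis-aligned rectangular compartment (μm units)."""

    x0: float
    y0: float
    x1: float
    y1: float
    depth: int = 0

    @property
    def area(self) -> float:
        return (self.x1 - self.x0) * (self.y1 - self.y0)

    @property
    def perimeter(self) -> float:
        return 2.0 * ((self.x1 - self.x0) + (self.y1 - self.y0))

    def contains(self, x: float, y: float, tol: float = 0.0) -> bool:
        return (self.x0 - tol <= x <= self.x1 + tol) and (self.y0 - tol <= y <= self.y1 + tol)

    @property
    def polygon(self) -> np.ndarray:
        return np.array(
            [[self.x0, self.y0], [self.x1, self.y0], [self.x1, self.y1], [self.x0, self.y1]]
        )


@dataclass
class MeshworkModel:
    """A fence meshwork: region, fence segments, and true compartments.

    ``fences`` are (x0, y0, x1, y1) segments in μm, including the region
    boundary; ``generation_log`` records one entry per split.
    """

    region: tuple  # (width, height) μm, origin at (0, 0)
    fences: list
    compartments: list
    generation_log: list = field(default_factory=list)

    @property
    def internal_fences(self) -> list:
        return self.fences[4:]

    def true_areas(self) -> np.ndarray:
        return np.array([c.area for c in self.compartments])

    def true_perimeters(self) -> np.ndarray:
        return np.array([c.perimeter for c in self.compartments])

    def total_fence_length(self) -> float:
        f = np.asarray(self.fences)
        return float(np.hypot(f[:, 2] - f[:, 0], f[:, 3] - f[:, 1]).sum())

    def to_json(self, path) -> None:
        payload = {
            "region_um": list(self.region),
            "fences_um": [list(map(float, f)) for f in self.fences],
            "compartments": [
                {"x0": c.x0, "y0": c.y0, "x1": c.x1, "y1": c.y1, "depth": c.depth}
                for c in self.compartments
            ],
            "generation_log": self.generation_log,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "MeshworkModel":
        with open(path) as fh:
            payload = json.load(fh)
        comps = [Compartment(**c) for c in payload["compartments"]]
        return cls(
            region=tuple(payload["region_um"]),
            fences=[tuple(f) for f in payload["fences_um"]],
            compartments=comps,
            generation_log=payload.get("generation_log", []),
        )


@dataclass
class LocalizationTable:
    """Point localizations: frame index, x/y in nm, per-point precision nm."""

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    precision: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        if np.any(self.precision <= 0):
            raise InvalidParameterError("localization precision must be > 0")

    def __len__(self) -> int:
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": self.frame, "x_nm": self.x, "y_nm": self.y, "precision_nm": self.precision}
        )


def write_localizations(locs: LocalizationTable, path) -> None:
    locs.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def read_localizations(path) -> LocalizationTable:
    table = pd.read_csv(path)
    from .errors import SchemaError

    missing = [c for c in ("frame", "x_nm", "y_nm", "precision_nm") if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    return LocalizationTable(
        table["frame"].to_numpy(),
        table["x_nm"].to_numpy(),
        table["y_nm"].to_numpy(),
        table["precision_nm"].to_numpy(),
    )


@dataclass
class MeshImage:
    """A rendered pixel image with physical pixel size in nm.

    Pixel (row, col) maps to physical (y, x); the centre of pixel (0, 0)
    sits at ``origin + 0.5 * pixel_size``.  ``frame_window`` and
    ``t_interval`` tag the reconstruction window of sliding PALM images.
    """

    pixels: np.ndarray
    pixel_size: float
    origin: tuple = (0.0, 0.0)
    frame_window: tuple | None = None
    t_interval: tuple | None = None
    empty: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if np.any(self.pixels < 0):
            raise InvalidParameterError("pixel values must be nonnegative")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    def save_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.pixels.astype(np.float32))
        sidecar = {
            "pixel_size_nm": self.pixel_size,
            "origin_nm": list(self.origin),
            "frame_window": list(self.frame_window) if self.frame_window else None,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh)

    @classmethod
    def load_tiff(cls, path) -> "MeshImage":
        import tifffile

        pixels = tifffile.imread(path)
        with open(str(path) + ".json") as fh:
            sidecar = json.load(fh)
        fw = sidecar.get("frame_window")
        return cls(
            pixels,
            sidecar["pixel_size_nm"],
            tuple(sidecar.get("origin_nm", (0.0, 0.0))),
            frame_window=tuple(fw) if fw else None,
        )


# ---------------------------------------------------------------------------
# fragmentation meshwork
# ---------------------------------------------------------------------------

def _fraction_sampler(split_fraction_law, rng):
    """Accept ('uniform', lo, hi), a scipy frozen distribution, or a callable
    rng -> fraction; fractions must land in (0, 1)."""
    if split_fraction_law is None:
        split_fraction_law = ("uniform", 0.25, 0.75)
    if isinstance(split_fraction_law, tuple):
        if len(split_fraction_law) != 3 or split_fraction_law[0] != "uniform":
            raise InvalidParameterError(f"unknown split law spec {split_fraction_law!r}")
        lo, hi = split_fraction_law[1], split_fraction_law[2]
        if not (0.0 < lo < hi < 1.0):
            raise InvalidParameterError("uniform split bounds must satisfy 0 < lo < hi < 1")
        return lambda: rng.uniform(lo, hi)
    if hasattr(split_fraction_law, "rvs"):
        return lambda: float(split_fraction_law.rvs(random_state=rng))
    if callable(split_fraction_law):
        return lambda: float(split_fraction_law(rng))
    raise InvalidParameterError(f"invalid split_fraction_law {split_fraction_law!r}")


def generate_fragmentation_meshwork(
    region: tuple = (12.0, 12.0),
    n_generations: int = 400,
    split_fraction_law=None,
    min_area: float = 0.05,
    seed: int = 0,
    orientation: str = "alternating",
) -> MeshworkModel:
    """Kolmogorov-style repeated fragmentation of a rectangular region.

    Each generation picks one splittable compartment uniformly at random and
    divides it by an axis-aligned chord at a fraction of its extent drawn
    from ``split_fraction_law`` (size-independent — the Kolmogorov
    condition, which drives log-area statistics toward normality).
    Orientation alternates with split depth by default (``orientation``:
    'alternating' or 'random').  Compartments below ``min_area`` (μm²) are
    never split further.
    """
    if n_generations < 0:
        raise InvalidParameterError("n_generations must be >= 0")
    if min_area <= 0:
        raise InvalidParameterError("min_area must be > 0")
    if orientation not in ("alternating", "random"):
        raise InvalidParameterError("orientation must be 'alternating' or 'random'")
    w, h = region
    if w <= 0 or h <= 0:
        raise InvalidParameterError("region sides must be > 0")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    draw_fraction = _fraction_sampler(split_fraction_law, rng)

    compartments = [Compartment(0.0, 0.0, w, h, depth=0)]
    fences = [(0.0, 0.0, w, 0.0), (w, 0.0, w, h), (w, h, 0.0, h), (0.0, h, 0.0, 0.0)]
    log = []
    for gen in range(n_generations):
        splittable = [i for i, c in enumerate(compartments) if c.area > min_area]
        if not splittable:
            break
        idx = splittable[rng.integers(len(splittable))]
        c = compartments[idx]
        if orientation == "alternating":
            vertical = c.depth % 2 == 0  # vertical chord splits the x extent first
        else:
            vertical = bool(rng.integers(2))
        frac = draw_fraction()
        if vertical:
            x_cut = c.x0 + frac * (c.x1 - c.x0)
            left = Compartment(c.x0, c.y0, x_cut, c.y1, depth=c.depth + 1)
            right = Compartment(x_cut, c.y0, c.x1, c.y1, depth=c.depth + 1)
            fences.append((x_cut, c.y0, x_cut, c.y1))
            children = (left, right)
        else:
            y_cut = c.y0 + frac * (c.y1 - c.y0)
            bottom = Compartment(c.x0, c.y0, c.x1, y_cut, depth=c.depth + 1)
            top = Compartment(c.x0, y_cut, c.x1, c.y1, depth=c.depth + 1)
            fences.append((c.x0, y_cut, c.x1, y_cut))
            children = (bottom, top)
        compartments[idx] = children[0]
        compartments.append(children[1])
        log.append(
            {
                "generation": gen,
                "fraction": float(frac),
                "vertical": bool(vertical),
                "parent_area": float(c.area),
            }
        )
    return MeshworkModel(region=(w, h), fences=fences, compartments=compartments, generation_log=log)


# ---------------------------------------------------------------------------
# localizations & rendering
# ---------------------------------------------------------------------------

def meshwork_to_localizations(
    mesh: MeshworkModel,
    linear_density: float = 300.0,
    precision_mean: float = 20.0,
    precision_sd: float = 8.0,
    n_frames: int = 100,
    seed: int = 0,
    include_boundary: bool = True,
) -> LocalizationTable:
    """Sample fence-bound localizations with finite precision.

    Points are placed along each fence segment as a Poisson process with
    the given linear density (points per μm of fence), jittered
    isotropically by a per-point precision drawn as |Normal(mean, sd)| nm,
    and assigned to frames uniformly.
    """
    if linear_density <= 0:
        raise InvalidParameterError("linear_density must be > 0")
    fences = mesh.fences if include_boundary else mesh.internal_fences
    if not fences:
        raise EmptyInputError("meshwork has no fences")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
    xs, ys = [], []
    for (x0, y0, x1, y1) in fences:
        length = float(np.hypot(x1 - x0, y1 - y0))
        n_pts = rng.poisson(linear_density * length)
        if n_pts == 0:
            continue
        t = rng.random(n_pts)
        xs.append(x0 + t * (x1 - x0))
        ys.append(y0 + t * (y1 - y0))
    if not xs:
        raise EmptyInputError("no localizations sampled; increase linear_density")
    x_um = np.concatenate(xs)
    y_um = np.concatenate(ys)
    n = x_um.size
    precision = np.abs(rng.normal(precision_mean, precision_sd, size=n))
    precision = np.maximum(precision, 1e-3)
    x_nm = x_um * 1000.0 + rng.normal(0.0, precision)
    y_nm = y_um * 1000.0 + rng.normal(0.0, precision)
    frames = rng.integers(0, n_frames, size=n)
    return LocalizationTable(frames, x_nm, y_nm, precision)


def render_localizations(
    locs: LocalizationTable,
    pixel_size: float = 20.0,
    blur_sd: float = 0.0,
    frame_window: tuple | None = None,
    shape: tuple | None = None,
    origin: tuple | None = None,
    region: tuple | None = None,
) -> MeshImage:
    """Render localizations into a 2D histogram image.

    ``shape`` (rows, cols) and ``origin`` (nm) default to the tight,
    pixel-aligned bounding box of the points, so every in-window
    localization lands inside the image.  ``region`` (width, height in μm)
    instead clips the field of view to [0, width] x [0, height] — points
    jittered outside the region are dropped.  Optional Gaussian blur of
    ``blur_sd`` nm uses a renormalized kernel; total intensity equals the
    in-window localization count inside the field of view.
    """
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be > 0")
    if region is not None:
        origin = (0.0, 0.0)
        shape = (
            int(np.ceil(region[1] * 1000.0 / pixel_size)),
            int(np.ceil(region[0] * 1000.0 / pixel_size)),
        )
    if frame_window is not None:
        first, last = frame_window
        sel = (locs.frame >= first) & (locs.frame <= last)
    else:
        sel = np.ones(len(locs), dtype=bool)
    if origin is None:
        if shape is None and sel.any():
            origin = (
                np.floor(locs.x[sel].min() / pixel_size) * pixel_size,
                np.floor(locs.y[sel].min() / pixel_size) * pixel_size,
            )
        else:
            origin = (0.0, 0.0)
    x = locs.x[sel] - origin[0]
    y = locs.y[sel] - origin[1]
    if shape is None:
        if x.size == 0:
            return MeshImage(np.zeros((1, 1)), pixel_size, origin, frame_window, empty=True)
        n_rows = int(np.ceil((y.max() + 1e-9) / pixel_size))
        n_cols = int(np.ceil((x.max() + 1e-9) / pixel_size))
        shape = (max(n_rows, 1), max(n_cols, 1))
    rows = np.floor(y / pixel_size).astype(int)
    cols = np.floor(x / pixel_size).astype(int)
    inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    img = np.zeros(shape)
    np.add.at(img, (rows[inside], cols[inside]), 1.0)
    if blur_sd > 0:
        from scipy import ndimage

        total = img.sum()
        img = ndimage.gaussian_filter(img, sigma=blur_sd / pixel_size, mode="constant")
        if img.sum() > 0:
            img *= total / img.sum()
    return MeshImage(
        img, pixel_size, origin, frame_window=frame_window, empty=bool(x.size == 0)
    )


# ---------------------------------------------------------------------------
# meshwork-confined trajectories
# ---------------------------------------------------------------------------

def _segment_crossings(p0, p1, v_fences, h_fences):
    """Parametric positions of fence-segment crossings along step p0 -> p1.

    ``v_fences``/``h_fences`` are (coord, lo, hi) arrays for vertical and
    horizontal segments.  Returns a list of (t, axis, coord) sorted by t.
    """
    hits = []
    dx = p1[0] - p0[0]
    dy = p1[1] - p0[1]
    if dx != 0.0 and v_fences.size:
        t = (v_fences[:, 0] - p0[0]) / dx
        mask = (t > 1e-12) & (t < 1.0 - 1e-12)
        if mask.any():
            y_at = p0[1] + t[mask] * dy
            f = v_fences[mask]
            ok = (y_at >= f[:, 1]) & (y_at <= f[:, 2])
            for tt, cc in zip(t[mask][ok], f[ok][:, 0]):
                hits.append((float(tt), 0, float(cc)))
    if dy != 0.0 and h_fences.size:
        t = (h_fences[:, 0] - p0[1]) / dy
        mask = (t > 1e-12) & (t < 1.0 - 1e-12)
        if mask.any():
            x_at = p0[0] + t[mask] * dx
            f = h_fences[mask]
            ok = (x_at >= f[:, 1]) & (x_at <= f[:, 2])
            for tt, cc in zip(t[mask][ok], f[ok][:, 0]):
                hits.append((float(tt), 1, float(cc)))
    hits.sort()
    return hits


def _mesh_fence_arrays(mesh: MeshworkModel):
    v, h = [], []
    for (x0, y0, x1, y1) in mesh.fences:
        if abs(x1 - x0) < 1e-12:
            v.append((x0, min(y0, y1), max(y0, y1)))
        else:
            h.append((y0, min(x0, x1), max(x0, x1)))
    return np.array(v, dtype=float).reshape(-1, 3), np.array(h, dtype=float).reshape(-1, 3)


def simulate_meshwork_confined_tracks(
    mesh: MeshworkModel,
    diffusivity: float = 0.19,
    hop_probability: float = 0.05,
    dt: float = 0.02,
    n_steps: int = 200,
    n_traj: int = 100,
    seed: int = 0,
) -> TrajectoryEnsemble:
    """Brownian steps confined by the meshwork fences.

    A step is a straight segment; each fence segment it crosses is tested
    independently in crossing order and accepted with ``hop_probability``,
    otherwise the offending coordinate is reflected about the fence line
    and remaining crossings are re-scanned.  Start positions are uniform
    over the region.
    """
    if not 0.0 <= hop_probability <= 1.0:
        raise InvalidParameterError("hop_probability must be in [0, 1]")
    if diffusivity < 0 or dt <= 0:
        raise InvalidParameterError("diffusivity must be >= 0 and dt > 0")
    if not mesh.compartments:
        raise EmptyInputError("meshwork has no compartments")
    v_fences, h_fences = _mesh_fence_arrays(mesh)
    w, h_region = mesh.region
    sd = np.sqrt(2.0 * diffusivity * dt)
    times = np.arange(n_steps + 1) * dt
    seeds = np.random.SeedSequence(seed).spawn(n_traj)
    trajectories = []
    for i in range(n_traj):
        rng = np.random.Generator(np.random.PCG64(seeds[i]))
        p = np.array([rng.uniform(0.0, w), rng.uniform(0.0, h_region)])
        steps = rng.normal(0.0, sd, size=(n_steps, 2))
        pos = np.empty((n_steps + 1, 2))
        pos[0] = p
        for k in range(n_steps):
            target = p + steps[k]
            for _ in range(200):
                hits = _segment_crossings(p, target, v_fences, h_fences)
                if not hits:
                    break
                t_hit, axis, coord = hits[0]
                if hop_probability >= 1.0 or (
                    hop_probability > 0.0 and rng.random() < hop_probability
                ):
                    # accepted: move just past the fence and keep going
                    cross = p + t_hit * (target - p)
                    nudge = np.sign(target[axis] - p[axis]) * 1e-9
                    cross[axis] += nudge
                    p = cross
                else:
                    cross = p + t_hit * (target - p)
                    nudge = np.sign(p[axis] - target[axis]) * 1e-9
                    target[axis] = 2.0 * coord - target[axis]
                    cross[axis] += nudge
                    p = cross
            p = target.copy()
            pos[k + 1] = p
        trajectories.append(Trajectory(f"mesh-{i}", times, pos))
    return TrajectoryEnsemble(trajectories, frame_interval=dt)


# ---------------------------------------------------------------------------
# reference fractals
# ---------------------------------------------------------------------------

def make_reference_fractals(kind: str, size: int, seed: int = 0, pixel_size: float = 20.0) -> MeshImage:
    """Exact binary rasters with known box-counting dimension.

    kinds: 'filled_square' (d=2), 'line' (d=1), 'sierpinski_carpet'
    (d = log 8 / log 3, size must be a power of 3), 'percolation_cluster'
    (largest open cluster at the site-percolation critical density,
    d_f ≈ 91/48).
    """
    if size < 1:
        raise InvalidParameterError("size must be >= 1")
    if kind == "filled_square":
        pixels = np.ones((size, size), dtype=bool)
    elif kind == "line":
        pixels = np.zeros((size, size), dtype=bool)
        pixels[size // 2, :] = True
    elif kind == "sierpinski_carpet":
        k = int(round(np.log(size) / np.log(3)))
        if 3**k != size:
            raise InvalidParameterError("sierpinski_carpet size must be a power of 3")
        pixels = np.ones((1, 1), dtype=bool)
        for _ in range(k):
            n = pixels.shape[0]
            tiled = np.tile(pixels, (3, 3))
            tiled[n:2 * n, n:2 * n] = False
            pixels = tiled
    elif kind == "percolation_cluster":
        from scipy import ndimage

        rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed)))
        open_sites = rng.random((size, size)) < 0.592746
        labels, n = ndimage.label(open_sites)
        if n == 0:
            raise InvalidParameterError("no open sites in percolation field")
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        pixels = labels == int(np.argmax(counts))
    else:
        raise InvalidParameterError(f"unknown fractal kind {kind!r}")
    return MeshImage(pixels.astype(np.uint8), pixel_size)
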