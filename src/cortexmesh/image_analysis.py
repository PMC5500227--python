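"""Superresolution-image morphometry and trajectory–image conditioning.

Sliding-window PALM reconstruction, Euclidean distance maps to actin
features, MSD conditioned on distance to actin, filament cross-section
profiles, watershed compartment segmentation with area/perimeter
statistics, log-normal area fits, perimeter–area scaling and box-counting
fractal dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, stats
from skimage import measure, segmentation
from skimage.filters import threshold_otsu

from .errors import EmptyInputError, InvalidDataError, InvalidParameterError
from .meshwork_synthesis import LocalizationTable, MeshImage, render_localizations
from .trajectory import TrajectoryEnsemble

__all__ = [
    "DistanceMap",
    "SegmentationResult",
    "BoxCountResult",
    "DistanceBinnedMSD",
    "CrossSectionProfile",
    "sliding_reconstruction",
    "euclidean_distance_map",
    "msd_vs_actin_distance",
    "cross_section_profile",
    "watershed_compartments",
    "fit_lognormal_areas",
    "perimeter_area_scaling",
    "box_count_dimension",
    "branching_ratio",
]


# ---------------------------------------------------------------------------
# reconstruction & distance maps
# ---------------------------------------------------------------------------

def sliding_reconstruction(
    locs: LocalizationTable,
    window_frames: int = 100,
    stride_frames: int = 10,
    pixel_size: float = 20.0,
    blur_sd: float = 0.0,
    shape: tuple | None = None,
) -> list[MeshImage]:
    """Sliding-window reconstruction: one image per window
    ``[k*stride, k*stride + window)`` for all full windows.

    Each image is tagged with its frame window and time interval (50
    frames/s).  The default window/stride (100 frames / 10 frames) realize
    a 2-s reconstruction sliding by 0.2 s.
    """
    if window_frames < 1 or stride_frames < 1:
        raise InvalidParameterError("window_frames and stride_frames must be >= 1")
    n_frames = int(locs.frame.max()) + 1 if len(locs) else 0
    if window_frames > n_frames:
        raise InvalidDataError(
            f"window of {window_frames} frames exceeds recording of {n_frames} frames"
        )
    full = render_localizations(locs, pixel_size=pixel_size)
    origin = full.origin
    if shape is None:
        shape = full.shape
    from .meshwork_synthesis import FRAMES_PER_SECOND

    n_windows = (n_frames - window_frames) // stride_frames + 1
    images = []
    for k in range(n_windows):
        first = k * stride_frames
        last = first + window_frames - 1
        img = render_localizations(
            locs, pixel_size=pixel_size, blur_sd=blur_sd,
            frame_window=(first, last), shape=shape, origin=origin,
        )
        img.t_interval = (first / FRAMES_PER_SECOND, (last + 1) / FRAMES_PER_SECOND)
        images.append(img)
    return images


@dataclass
class DistanceMap:
    """Per-pixel Euclidean distance (nm) to the nearest feature pixel."""

    values: np.ndarray
    pixel_size: float
    source_threshold: float
    origin: tuple = (0.0, 0.0)

    def distance_at(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        """Distance-map value at physical coordinates (nearest pixel)."""
        rows = np.clip(
            np.floor((np.asarray(y_nm) - self.origin[1]) / self.pixel_size).astype(int),
            0, self.values.shape[0] - 1,
        )
        cols = np.clip(
            np.floor((np.asarray(x_nm) - self.origin[0]) / self.pixel_size).astype(int),
            0, self.values.shape[1] - 1,
        )
        return self.values[rows, cols]


def euclidean_distance_map(image: MeshImage, threshold: float) -> DistanceMap:
    """Exact Euclidean distance map to pixels at/above ``threshold``,
    in nm (pixel-centre to pixel-centre)."""
    feature = image.pixels >= threshold
    if not feature.any():
        raise EmptyInputError("no feature pixels at/above threshold")
    dist_px = ndimage.distance_transform_edt(~feature)
    return DistanceMap(dist_px * image.pixel_size, image.pixel_size, threshold, tuple(image.origin))


# ---------------------------------------------------------------------------
# MSD vs distance to actin
# ---------------------------------------------------------------------------

@dataclass
class DistanceBinnedMSD:
    """Mean squared displacement over one segment duration, binned by the
    segment's maximum distance to the nearest actin feature."""

    distance_bin_edges: np.ndarray
    msd: np.ndarray
    sem: np.ndarray
    n_segments: np.ndarray
    segment_distances: np.ndarray = field(default=None, repr=False)
    segment_sq_displacements: np.ndarray = field(default=None, repr=False)
    n_skipped: int = 0

    def spearman(self):
        """Spearman correlation of segment-level (distance, r²) pairs."""
        return stats.spearmanr(self.segment_distances, self.segment_sq_displacements)


def msd_vs_actin_distance(
    ensemble: TrajectoryEnsemble,
    images: list[MeshImage],
    threshold: float | None = None,
    segment_duration: float = 0.2,
    distance_bins: np.ndarray | None = None,
) -> DistanceBinnedMSD:
    """MSD over ``segment_duration`` conditioned on distance to actin.

    Each trajectory is cut into consecutive non-overlapping segments of the
    given duration; each segment is paired with the reconstruction window
    covering its midpoint (nearest window centre among those covering it);
    the segment's distance d is the maximum distance-map value over its
    samples and its squared displacement |r(end) - r(start)|² is
    accumulated into the bin containing d.
    """
    if distance_bins is None:
        distance_bins = np.arange(0.0, 550.0, 50.0)
    distance_bins = np.asarray(distance_bins, dtype=float)
    if len(images) == 0:
        raise EmptyInputError("no reconstruction images")
    dmaps = []
    centers = []
    for img in images:
        thr = threshold if threshold is not None else threshold_otsu(img.pixels)
        dmaps.append(euclidean_distance_map(img, thr))
        if img.t_interval is not None:
            centers.append(0.5 * (img.t_interval[0] + img.t_interval[1]))
        else:
            centers.append(None)

    def window_for(t_mid: float):
        best, best_d = None, np.inf
        for i, img in enumerate(images):
            if img.t_interval is None:
                return i if len(images) == 1 else None
            lo, hi = img.t_interval
            if lo <= t_mid <= hi and abs(centers[i] - t_mid) < best_d:
                best, best_d = i, abs(centers[i] - t_mid)
        return best

    seg_d, seg_r2 = [], []
    skipped = 0
    for traj in ensemble:
        if len(traj) < 2:
            continue
        n_per_seg = int(round(segment_duration / traj.dt))
        if n_per_seg < 1:
            raise InvalidParameterError("segment_duration below one frame interval")
        n_segments = (len(traj) - 1) // n_per_seg
        for s in range(n_segments):
            i0, i1 = s * n_per_seg, (s + 1) * n_per_seg
            t_mid = 0.5 * (traj.times[i0] + traj.times[i1])
            w = window_for(t_mid)
            if w is None:
                skipped += 1
                continue
            seg_pos = traj.positions[i0:i1 + 1] * 1000.0  # μm -> nm
            d = float(dmaps[w].distance_at(seg_pos[:, 0], seg_pos[:, 1]).max())
            disp = traj.positions[i1] - traj.positions[i0]
            seg_d.append(d)
            seg_r2.append(float(disp @ disp))
    if not seg_d:
        raise EmptyInputError("all segments skipped: no overlapping windows")
    seg_d = np.asarray(seg_d)
    seg_r2 = np.asarray(seg_r2)
    which = np.digitize(seg_d, distance_bins) - 1
    n_bins = len(distance_bins) - 1
    msd = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        counts[b] = sel.sum()
        if counts[b]:
            msd[b] = seg_r2[sel].mean()
            sem[b] = (
                seg_r2[sel].std(ddof=1) / np.sqrt(counts[b]) if counts[b] > 1 else np.nan
            )
    return DistanceBinnedMSD(distance_bins, msd, sem, counts, seg_d, seg_r2, skipped)


# ---------------------------------------------------------------------------
# cross-section profiles
# ---------------------------------------------------------------------------

@dataclass
class CrossSectionProfile:
    """Average perpendicular intensity profile across filament cut lines,
    aligned by centroid, with a Gaussian fit of its width."""

    distance: np.ndarray  # nm, signed offset from the aligned centre
    intensity: np.ndarray
    gaussian_sd: float  # nm
    gaussian_params: tuple  # (amplitude, centre, sd, offset)


def cross_section_profile(
    image: MeshImage,
    cut_lines: list,
    half_width: float = 150.0,
    sample_step: float | None = None,
) -> CrossSectionProfile:
    """Average cross-section of linear features.

    For each cut line ((x0, y0), (x1, y1)) in nm the intensity is sampled
    along the perpendicular through the line's midpoint out to
    ``±half_width`` nm; profiles are aligned by their intensity centroid
    and averaged; a least-squares Gaussian fit returns the width (nm).
    """
    if not cut_lines:
        raise InvalidParameterError("need at least one cut line")
    px = image.pixel_size
    step = sample_step if sample_step is not None else px / 2.0
    offsets = np.arange(-half_width, half_width + step * 0.5, step)
    profiles = []
    rows_max, cols_max = image.shape
    for (p0, p1) in cut_lines:
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        mid = 0.5 * (p0 + p1)
        direction = p1 - p0
        norm = np.hypot(*direction)
        if norm == 0:
            raise InvalidParameterError("degenerate cut line")
        normal = np.array([-direction[1], direction[0]]) / norm
        pts = mid[None, :] + offsets[:, None] * normal[None, :]
        rows = pts[:, 1] / px - 0.5
        cols = pts[:, 0] / px - 0.5
        if rows.min() < -1 or cols.min() < -1 or rows.max() > rows_max or cols.max() > cols_max:
            raise InvalidParameterError("cut line (or its sampling band) outside image")
        vals = ndimage.map_coordinates(
            image.pixels.astype(float), np.vstack([rows, cols]), order=1, mode="nearest"
        )
        total = vals.sum()
        if total <= 0:
            continue
        centroid = float((offsets * vals).sum() / total)
        # re-centre by shifting the sampling grid
        shifted = np.interp(offsets, offsets - centroid, vals)
        profiles.append(shifted)
    if not profiles:
        raise InvalidDataError("no cut line crossed a feature")
    mean_profile = np.mean(profiles, axis=0)

    def gauss(x, amp, mu, sd, off):
        return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2) + off

    amp0 = float(mean_profile.max() - mean_profile.min())
    p0 = (amp0, 0.0, half_width / 4.0, float(mean_profile.min()))
    params, _ = optimize.curve_fit(gauss, offsets, mean_profile, p0=p0, maxfev=20000)
    return CrossSectionProfile(
        offsets, mean_profile, float(abs(params[2])), tuple(float(v) for v in params)
    )


# ---------------------------------------------------------------------------
# watershed morphometry
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    """Watershed compartments: label image (0 = actin/fence ridge), per-
    compartment area (μm²) and perimeter (μm), and actin coverage."""

    labels: np.ndarray
    areas: np.ndarray
    perimeters: np.ndarray
    label_ids: np.ndarray
    actin_coverage: float
    ridge_coverage: float
    pixel_size: float


def watershed_compartments(
    image: MeshImage,
    smoothing_sd: float | None = None,
    actin_threshold=None,
    min_area: float | None = None,
    marker_depth_frac: float = 0.1,
    exclude_border: bool = True,
) -> SegmentationResult:
    """Watershed segmentation of actin-delimited compartments.

    The intensity landscape is smoothed (Gaussian, default SD one pixel)
    and flooded from its regional minima; basins are compartments, the
    watershed ridges trace the actin.  Shallow minima (depth below
    ``marker_depth_frac`` of the smoothed maximum — sampling noise inside
    the fence band) are suppressed before seeding.  Compartments below
    ``min_area`` (μm², default 3 px²) are merged into the neighbour sharing
    the longest boundary; compartments touching the image border (clipped
    by the field of view) are dropped by default.  ``actin_coverage`` is
    the fraction of pixels at/above the actin threshold (default Otsu);
    ``ridge_coverage`` the fraction assigned to watershed ridges.
    """
    pixels = np.asarray(image.pixels, dtype=float)
    if pixels.size == 0 or np.ptp(pixels) == 0:
        raise InvalidDataError("uniform or empty image: no compartments")
    px_um = image.pixel_size / 1000.0
    sd_px = 1.0 if smoothing_sd is None else smoothing_sd / image.pixel_size
    smoothed = ndimage.gaussian_filter(pixels, sigma=sd_px) if sd_px > 0 else pixels
    if actin_threshold is None:
        thr = float(threshold_otsu(pixels))
    else:
        thr = float(actin_threshold)

    from skimage.morphology import h_minima, local_minima

    if marker_depth_frac > 0:
        minima = h_minima(smoothed, marker_depth_frac * float(smoothed.max()))
    else:
        minima = local_minima(smoothed, connectivity=1)
    if not minima.any():
        minima = local_minima(smoothed, connectivity=1)
    markers, n_markers = ndimage.label(minima)
    if n_markers < 1:
        raise InvalidDataError("no regional minima: no compartments")
    full = segmentation.watershed(smoothed, markers=markers)  # full partition
    lines = segmentation.watershed(smoothed, markers=markers, watershed_line=True)

    min_area_um2 = (3 * px_um**2) if min_area is None else min_area
    mapping = _merge_basins(full, pixels >= thr, min_area_um2, px_um)
    resolved = mapping[full]
    # reinstate ridge lines only where they still separate distinct labels
    labels = _overlay_ridges(resolved, lines == 0)
    labels = _drop_disconnected_fragments(labels)
    ridge_coverage = float((labels == 0).mean())
    if exclude_border:
        border = np.unique(
            np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
        )
        labels[np.isin(labels, border[border > 0])] = 0

    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        raise InvalidDataError("no interior compartments found")
    areas = counts * px_um**2
    perims = np.array(
        [
            measure.perimeter_crofton(labels == i, directions=4) * px_um
            for i in ids
        ]
    )
    actin_coverage = float((pixels >= thr).mean())
    return SegmentationResult(labels, areas, perims, ids, actin_coverage, ridge_coverage, image.pixel_size)


def _boundary_lengths(labels: np.ndarray) -> dict:
    """Shared-boundary pixel counts between adjacent labels of a full
    partition."""
    h_a, h_b = labels[:, :-1].ravel(), labels[:, 1:].ravel()
    v_a, v_b = labels[:-1, :].ravel(), labels[1:, :].ravel()
    a = np.concatenate([h_a, v_a])
    b = np.concatenate([h_b, v_b])
    diff = a != b
    lo = np.minimum(a[diff], b[diff]).astype(np.int64)
    hi = np.maximum(a[diff], b[diff]).astype(np.int64)
    keys, counts = np.unique(lo * (labels.max() + 1) + hi, return_counts=True)
    base = labels.max() + 1
    return {(int(k // base), int(k % base)): int(c) for k, c in zip(keys, counts)}


def _merge_basins(
    full: np.ndarray,
    actin_mask: np.ndarray,
    min_area_um2: float,
    px_um: float,
) -> np.ndarray:
    """Union-find merge of watershed basins on the full partition.

    Basins that are mere pockets inside the actin band (no interior pixel
    at least 2 px away from thresholded actin) and basins below the area
    floor are folded into the adjacent basin sharing the longest boundary.
    Returns the label mapping array.
    """
    ids = np.arange(full.max() + 1)
    parent = ids.copy()

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    min_px = min_area_um2 / px_um**2
    # pocket test: a true compartment has an interior at least 2 px away
    # from the actin band; shallower basins are gaps inside the band
    edt_px = ndimage.distance_transform_edt(~actin_mask) if actin_mask.any() else np.full(
        full.shape, np.inf
    )

    for _ in range(64):
        resolved = parent[ids]
        changed = True
        while changed:
            new = parent[resolved]
            changed = bool(np.any(new != resolved))
            resolved = new
        lab = resolved[full]
        pairs = _boundary_lengths(lab)
        uniq, counts = np.unique(lab, return_counts=True)
        if uniq.size < 2:
            break
        area_of = dict(zip(uniq.tolist(), counts.tolist()))
        depth = dict(
            zip(uniq.tolist(), np.atleast_1d(ndimage.maximum(edt_px, labels=lab, index=uniq)))
        )
        to_merge = [
            u for u in uniq
            if u > 0 and (area_of[u] < min_px or depth[u] < 2.0)
        ]
        if not to_merge:
            break
        merged_any = False
        for sid in to_merge:
            best, best_len = None, -1
            for (a, b), length in pairs.items():
                if a == sid and b != sid:
                    other = b
                elif b == sid and a != sid:
                    other = a
                else:
                    continue
                if other > 0 and length > best_len:
                    best, best_len = other, length
            if best is not None and find(best) != find(sid):
                parent[find(sid)] = find(best)
                merged_any = True
        if not merged_any:
            break
    resolved = parent[ids]
    changed = True
    while changed:
        new = parent[resolved]
        changed = bool(np.any(new != resolved))
        resolved = new
    return resolved


def _overlay_ridges(resolved: np.ndarray, ridge: np.ndarray) -> np.ndarray:
    """Set ridge pixels to 0 where their 4-neighbourhood still spans more
    than one final label; absorbed ridges keep the merged label."""
    labels = resolved.copy()
    padded = np.pad(resolved, 1, mode="edge")
    up = padded[:-2, 1:-1]
    down = padded[2:, 1:-1]
    left = padded[1:-1, :-2]
    right = padded[1:-1, 2:]
    lo = np.minimum(np.minimum(up, down), np.minimum(left, right))
    hi = np.maximum(np.maximum(up, down), np.maximum(left, right))
    separating = ridge & (lo != hi)
    labels[separating] = 0
    return labels


def _drop_disconnected_fragments(labels: np.ndarray) -> np.ndarray:
    """Keep each label's largest 4-connected component; stray ridge-zone
    fragments (typically single pixels) become ridge."""
    out = labels.copy()
    for i in np.unique(labels[labels > 0]):
        comp, n = ndimage.label(labels == i)
        if n > 1:
            sizes = np.bincount(comp.ravel())
            sizes[0] = 0
            keep = int(np.argmax(sizes))
            out[(comp > 0) & (comp != keep)] = 0
    return out


def fit_lognormal_areas(areas) -> tuple:
    """Maximum-likelihood log-normal fit of compartment areas.

    Returns (mu_log, sigma_log, gof_p): normal MLE on log-areas and the
    KS goodness-of-fit p-value against the fitted normal.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size < 3:
        raise InvalidDataError("need at least 3 areas")
    if np.any(areas <= 0):
        raise InvalidDataError("areas must all be > 0")
    logs = np.log(areas)
    mu = float(logs.mean())
    sigma = float(logs.std(ddof=0))
    if sigma == 0:
        return mu, 0.0, 1.0
    gof = stats.kstest(logs, "norm", args=(mu, sigma))
    return mu, sigma, float(gof.pvalue)


def perimeter_area_scaling(result) -> tuple:
    """Perimeter–area power law L = a A^b fitted in log-log coordinates.

    Accepts a SegmentationResult or an (areas, perimeters) pair; returns
    (prefactor a, exponent b, Pearson correlation of the log pairs).
    """
    if isinstance(result, SegmentationResult):
        areas, perims = result.areas, result.perimeters
    else:
        areas, perims = result
    areas = np.asarray(areas, dtype=float)
    perims = np.asarray(perims, dtype=float)
    if areas.size < 3:
        raise InvalidDataError("need at least 3 compartments")
    if np.any(areas <= 0) or np.any(perims <= 0):
        raise InvalidDataError("degenerate (zero) area or perimeter")
    la, lp = np.log(areas), np.log(perims)
    res = stats.linregress(la, lp)
    return float(np.exp(res.intercept)), float(res.slope), float(res.rvalue)


# ---------------------------------------------------------------------------
# box counting
# ---------------------------------------------------------------------------

@dataclass
class BoxCountResult:
    """Occupied-box counts N(ε) and the fitted fractal dimension
    d_f = -dlogN/dlogε."""

    box_sizes: np.ndarray
    counts: np.ndarray
    fractal_dimension: float
    fit_range: tuple

    def summary(self) -> str:
        return (
            f"box counting: d_f = {self.fractal_dimension:.3f} over box sizes "
            f"[{self.fit_range[0]}, {self.fit_range[1]}] px"
        )


def _count_boxes(mask: np.ndarray, eps: int, offset: tuple = (0, 0)) -> int:
    r0, c0 = offset
    padded = np.zeros(
        (
            int(np.ceil((mask.shape[0] + r0) / eps)) * eps,
            int(np.ceil((mask.shape[1] + c0) / eps)) * eps,
        ),
        dtype=bool,
    )
    padded[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]] = mask
    h, w = padded.shape
    blocks = padded.reshape(h // eps, eps, w // eps, eps)
    return int(blocks.any(axis=(1, 3)).sum())


def default_box_sizes(side: int) -> np.ndarray:
    """Powers of two from 2 px up to a quarter of the image side."""
    sizes = []
    e = 2
    while e <= side // 4:
        sizes.append(e)
        e *= 2
    return np.array(sizes, dtype=int)


def box_count_dimension(
    image: MeshImage,
    box_sizes=None,
    fit_range: tuple | None = None,
    offset_average: bool = False,
) -> BoxCountResult:
    """Box-counting (capacity) dimension of a binary image.

    For each box size ε a grid anchored at the image origin covers the
    image and the boxes containing at least one occupied pixel are counted;
    d_f is minus the slope of log N vs log ε over ``fit_range``.  With
    ``offset_average`` the count is averaged over 4 sub-box grid offsets,
    reducing grid-anchoring bias.
    """
    mask = np.asarray(image.pixels) > 0
    if not mask.any():
        raise EmptyInputError("empty image: nothing to count")
    side = min(mask.shape)
    if box_sizes is None:
        box_sizes = default_box_sizes(side)
    box_sizes = np.asarray(sorted(set(int(b) for b in box_sizes)))
    if np.any(box_sizes < 1):
        raise InvalidParameterError("box sizes must be >= 1 px")
    counts = np.empty(box_sizes.size, dtype=float)
    for i, eps in enumerate(box_sizes):
        if offset_average and eps > 1:
            offs = [(0, 0), (eps // 2, 0), (0, eps // 2), (eps // 2, eps // 2)]
            counts[i] = np.mean([_count_boxes(mask, int(eps), o) for o in offs])
        else:
            counts[i] = _count_boxes(mask, int(eps))
    if fit_range is None:
        fit_range = (int(box_sizes.min()), int(box_sizes.max()))
    sel = (box_sizes >= fit_range[0]) & (box_sizes <= fit_range[1])
    if sel.sum() < 3:
        raise InvalidParameterError("need >= 3 box sizes inside fit range")
    res = stats.linregress(np.log(box_sizes[sel]), np.log(counts[sel]))
    return BoxCountResult(box_sizes, counts, float(-res.slope), tuple(fit_range))


def branching_ratio(fractal_dimension: float, bifurcation_ratio: float) -> float:
    """Length-order ratio R_r of a hierarchically branched structure with
    fractal dimension d_f and bifurcation ratio R_b: R_r = R_b^(1/d_f)."""
    if fractal_dimension <= 0:
        raise InvalidParameterError("fractal_dimension must be > 0")
    if bifurcation_ratio <= 1:
        raise InvalidParameterError("bifurcation_ratio must be > 1")
    return float(bifurcation_ratio ** (1.0 / fractal_dimension))
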