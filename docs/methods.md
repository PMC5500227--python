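# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `cortexmesh`, in the order a study flows through the
package: trajectory simulators → SPT statistics → synthetic meshworks →
image morphometry.

## Trajectory simulators

All simulators share one random-number contract: a single root seed per
call is split (via `numpy.random.SeedSequence`) into one independent
stream per trajectory index, so results are bit-identical regardless of
how trajectories are batched or parallelized. The default frame interval
is dt = 0.02 s (50 frames/s acquisition).

**Brownian motion.** Per-axis i.i.d. Gaussian increments of variance
2 D dt; the 2D ensemble MSD is 4 D Δ. The default diffusivity, 0.19 μm²/s,
is the free-diffusion scale of an untethered membrane channel.

**Fractional Brownian motion.** Each coordinate is an exact fBM path with
increment (fGn) autocovariance
γ(k) = (σ²/2)(|k+1|^{2H} − 2|k|^{2H} + |k−1|^{2H}).
Synthesis is by circulant embedding (Davies–Harte): the embedding
eigenvalues are checked for nonnegativity and the O(n²) Hosking recursion
is the fallback when the embedding fails (it does not for fGn at the
parameters used here, but the guard keeps the method exact by
construction). Exactness matters because the test suite checks the
empirical autocovariance against γ(k) within sampling error, and because
the α = 2H relation is used for parameter recovery at the 0.05 level.

**Obstructed (percolation) diffusion.** Site percolation on a periodic
square lattice: exactly round(fraction · side²) obstacle sites placed
uniformly without replacement. The walker is a *blind ant*: one of the
four neighbours is proposed uniformly; the move is taken only if the site
is vacant, and time advances either way. A myopic-ant option (propose
among vacant neighbours only) is available. Coordinates are reported
unwrapped, in μm via the lattice constant, so periodic wrapping introduces
no artificial MSD saturation. Start sites are uniform over vacant sites by
default (proteins land anywhere), with an option to restrict to the
spanning cluster.

`sample_every` records every k-th elementary step. This emulates the fact
that one 20-ms camera frame spans very many elementary hops of a molecule
on a nanometre-scale obstacle lattice. It matters for turning angles: at
the elementary-step level the angles of a square-lattice walk are
restricted to {0°, 90°, 180°}, a lattice artifact; at 100 steps per frame
(the discrimination-study setting) the displacement vectors are sums over
many hops and the distributions become smooth and lag-invariant, which is
the regime the acquisition actually probes. Elementary-step resolution
remains the default (`sample_every=1`).

**Percolation threshold.** Estimated per realization by adding obstacles
in a random order and bisecting on the obstacle count for the loss of a
first-to-last-row 4-connected vacant cluster (the standard one-direction
spanning rule); the estimate is the mean critical fraction with its
standard error. On 256² lattices with 200 realizations this gives
0.410 ± 0.001 — consistent with 1 − 0.5927, the vacancy complement of the
square-lattice site-percolation density, so an obstacle concentration of
41% sits just above threshold.

**Fenced hop diffusion.** Gaussian steps on a periodic square grid of
fences with pitch L. Each fence line crossed by a step is tested
independently in crossing order: the crossing is accepted with the hop
probability, otherwise the remaining path is reflected about that fence.
Reflection (rather than rejection of the whole step) preserves step-length
statistics. Because the fences form an axis-aligned grid, x- and
y-crossings decouple exactly and each axis is advanced independently.
Start positions are uniform within one compartment. With hop probability 0
the long-time TA-MSD plateau is L²/3, the mean squared distance of two
independent uniform points in a square — the analytic limit used as an
oracle (recovered within 0.2% at the test's sample size).

## SPT statistics

**TA-MSD.** The discrete estimator of the running time average uses all
overlapping windows: MSD(k dt) = mean over i of |r(i+k) − r(i)|². The
vectorized implementation is tested against a naive double loop at 1e-12
relative. Ensemble averaging weights each trajectory equally and reports
the across-trajectory standard deviation as the spread.

**Fits.** The anomalous exponent is the slope of an unweighted
least-squares line of log MSD on log lag, restricted to a fit window
(default 2 dt to min(1 s, T/4): the first lag is dominated by localization
noise in real data, and lags beyond T/4 by estimator variance). The
diffusivity is slope/4 from an ordinary linear fit (2D convention).

**Turning angles.** For lag Δ = k dt, the unsigned angle between
v₁ = r(t+Δ) − r(t) and v₂ = r(t+2Δ) − r(t+Δ), computed as
atan2(|v₁×v₂|, v₁·v₂) ∈ [0°, 180°]; overlapping triplets are used. Pairs
with a zero-length displacement (common in lattice walks at elementary
resolution) have no defined direction; they are skipped and counted.
Distributions are pooled over the ensemble, histogrammed in 5° bins
(default; wide enough not to starve bins at realistic sample sizes, narrow
enough to resolve the 180° edge) and normalized to unit integral. The
mode is the centre of the maximal-density bin, ties broken toward 180°,
with the edge bin reported as 180°.

One subtlety: for fBM with H = 0.3 at one-frame lag, the exact Gaussian
angle density is monotone but nearly flat at the top — the last two
5° bins differ by only ~0.4% in mass. Resolving the modal bin therefore
needs ~2×10⁷ pooled angles; below that the observed modal bin wobbles
between the last few bins. The fBM mode checks and the reproduction
script use 20 000 trajectories of 1024 steps for this reason.

**Lag invariance.** The maximum over distribution pairs of the sup-norm
difference of binned CDFs (a two-sample KS statistic). Small values
(≲ 0.03 at 10⁵ angles per lag) indicate a scale-free walk; fenced hop
diffusion at matched sampling exceeds this by several-fold.

## Synthetic meshworks and localization data

**Fragmentation meshwork.** Kolmogorov's breakage picture: starting from
the full rectangular region, a uniformly chosen compartment is split by an
axis-aligned chord at a fraction of its extent drawn from a
size-independent law (default uniform on [0.25, 0.75]; bounded away from
0 and 1 to avoid sliver cells). Orientation alternates with split depth
(a random-orientation option exists). Compartments below `min_area` are
never split further. Size-independence of the split fractions drives the
log-areas toward normality; the suite checks that the |skewness| of
log-areas shrinks with generations and that a KS test against the fitted
normal is not rejected at 1% after a few hundred splits. Defaults —
12×12 μm region, 400 splits, min_area 0.05 μm² — give ~400 compartments
whose smallest members (~0.012 μm², 110 nm across) remain above the
rendering resolution so that segmentation ground truth is meaningful.

**Localizations.** Points are laid down along each fence segment as a
Poisson process (default 300 points per μm of fence — sparse for a long
STORM acquisition, dense enough to render continuous fences), jittered
isotropically by a per-point precision drawn as |N(20 nm, 8 nm)| (the
experimental localization accuracy), and assigned uniformly to frames.
Photophysics (blinking, binding/unbinding kinetics) is deliberately not
modelled; frame assignment is the only temporal structure.

**Rendering.** A 2D histogram at 20 nm/px by default; the field of view
defaults to the pixel-aligned bounding box of the points and can be
clipped to the generator's region (`region=...`), which the studies use so
that border artifacts and region-border compartments are handled
symmetrically between truth and segmentation. An optional Gaussian blur
uses a renormalized kernel; intensity equals the in-field localization
count either way.

**Confined tracks.** Brownian steps with the same accept-or-reflect rule
as the fence simulator, applied to the meshwork's finite fence segments:
crossings are processed in parametric order along the step, and a
rejection reflects the offending coordinate and re-scans. With hop
probability 0 a trajectory provably never leaves its starting compartment
(tested geometrically).

**Reference fractals.** Exact rasters of a filled square (d = 2), a line
(d = 1), the Sierpinski carpet (d = log 8 / log 3 ≈ 1.893, size a power of
three) and the largest cluster of critical site percolation — oracles for
the box-counting estimator.

## Image morphometry

**Sliding reconstruction.** One image per window [k·stride,
k·stride+window) for all full windows, each tagged with its frame range
and time interval; defaults 100 frames / 10 frames realize a 2-s window
sliding by 0.2 s.

**Distance maps.** Exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt`) of the thresholded feature mask,
in nm. Feature binarization defaults to Otsu's threshold, overridable by a
fixed value.

**MSD vs distance to actin.** Trajectories are cut into consecutive
200-ms segments; each segment is paired with the reconstruction window
covering its midpoint (nearest window centre among those covering it);
its distance d is the *maximum* distance-map value over its samples; its
squared displacement over the segment is accumulated into 50-nm bins of d
(0–500 nm default), reporting per-bin mean, standard error and count, and
keeping the segment-level (d, r²) pairs so a Spearman test can use full
resolution. A known property of the max-distance classifier: for *free*
walkers on a meshwork whose fence spacing is comparable to or larger than
the 200-ms excursion (~0.4 μm at D = 0.19 μm²/s), small max-d can only be
achieved by low-mobility segments, which biases the lowest distance bins
downward even without any true interaction. On a dense meshwork (fence
spacing well below the excursion, as for cortical actin) the bias is
negligible at realistic sampling; the conditioning study therefore uses a
2000-split mesh (mean compartment 0.05 μm²). At several times that
sampling depth a small residual suppression of the lowest bin becomes
statistically visible; flatness of the free control is, like in the
experiment, a statement at the study's statistical power.

**Cross-sections.** Intensity is sampled along perpendiculars through
each cut line's midpoint (bilinear interpolation, half-width 150 nm
default), profiles aligned by intensity centroid, averaged, and fitted
with a four-parameter Gaussian; the width is the |SD|. A zero-width
synthetic filament rendered with 20-nm precision returns SD = 20 nm within
10% (pixelization adds px²/12 ≈ (5.8 nm)² in quadrature at 20 nm/px).

**Watershed compartments.** The rendered image is smoothed (Gaussian,
SD 1 px default) and flooded from markers obtained by suppressing minima
shallower than 10% of the smoothed maximum (h-minima) — compartment
interiors are deep, near-zero basins; shallow dimples inside the fence
band are noise. Merging decisions are made on the full basin partition
with a union–find: basins below the area floor (default 3 px²) and basins
that are mere pockets inside the actin band (no pixel ≥ 2 px from
thresholded actin) are folded into the neighbour sharing the longest
boundary, which provably keeps regions connected. Watershed ridge lines
are then reinstated only where they still separate distinct final labels
(label 0 = ridge/actin); rare 1-px orphan fragments are returned to the
ridge. Compartments touching the image border are dropped by default —
they are clipped by the field of view; with region-clipped rendering this
removes region-border compartments from both the segmentation and the
ground-truth comparison symmetrically. Areas are pixel counts ×
pixel_size²; perimeters use the Crofton 4-direction estimator, which is
far less biased than pixel-edge counting for the perimeter–area exponent.
Both the thresholded-actin coverage and the watershed-ridge coverage are
reported, since "covered by actin" is ambiguous between the two.

**Log-normal fit and perimeter–area scaling.** Normal MLE on log-areas
with a KS goodness-of-fit p-value; least-squares line of log L on log A
returning L = a·A^b and the Pearson correlation of the log pairs. Ideal
squares give b = 0.5, a = 4 exactly; the synthetic end-to-end study
recovers the generator's (μ, σ) within a few percent (10% is the
acceptance bound).

**Box counting.** Grids anchored at the image origin; N(ε) = number of
ε×ε boxes containing an occupied pixel, optionally averaged over four
sub-box grid offsets (reduces anchoring bias; the estimate is then stable
within ±0.02 under sub-box translations). d_f is minus the slope of log N
on log ε over the fit range (default 2 px to a quarter of the image side;
powers of three are the natural box sizes for the carpet oracle). The fast
reshape-based count is tested against a per-box brute-force scan.

**Branching.** R_r = R_b^{1/d_f}; with d_f = 1.75 and R_b = 2 this gives
R_r ≈ 1.49.

## Problem sizes

The test suite and the reproduction script size their simulations to run
comfortably on one CPU: fBM recovery at 1000 trajectories × 1024 steps per
Hurst value; the discrimination study at ~10⁵ angles per lag (300
trajectories, 450 frames, 100 elementary steps per frame for the lattice
walk); the morphometry study at ~400 compartments on a 600×600-px image;
the fBM modal-bin determination at 2×10⁷ angles. The whole suite runs in
well under a minute of simulation time plus fitting.

## Known limitations

- Meshworks are axis-aligned rectangle tilings; real cortical actin has
  curved, branched filaments. The morphometry estimators do not assume
  rectangularity, but the generator's perimeter–area exponent (b ≈ 0.5,
  compact cells) is at the shape-homogeneous end of what real meshworks
  show.
- Localization photophysics (blinking, repeated localizations of one
  fluorophore) is not modelled; localization counts are Poisson in space
  and uniform in time.
- The max-distance segment classifier has the intrinsic selection bias
  described above; distance-conditioned MSD comparisons should always be
  run with a free-diffusion control at matched sampling, as the pipeline
  does.
- 2D only; no moving obstacles or fence turnover within a study.
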