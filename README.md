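# cortexmesh

Tools for studying how the cortical actin meshwork compartmentalizes the
plasma membrane: simulators for the candidate subdiffusive random walks of
membrane proteins, the trajectory statistics that discriminate between
those models, a synthetic generator for actin-like meshworks and
localization-microscopy data, and the image-side morphometry pipeline
(watershed compartments, log-normal area statistics, perimeter–area
scaling, box-counting fractal dimension).

## Who this is for

Biophysicists analysing single-particle tracking (SPT) of membrane
proteins together with superresolution (PALM/STORM) images of cortical
actin, and anyone who needs well-tested reference implementations of the
underlying estimators on synthetic data with known ground truth.

## The statistics at the core

**Time-averaged MSD and the anomalous exponent.** For a trajectory r(t)
observed over total time T, the time-averaged mean square displacement at
lag Δ is

    δ²(Δ) = 1/(T−Δ) ∫₀^{T−Δ} |r(t+Δ) − r(t)|² dt,

estimated discretely with overlapping windows and averaged over the
ensemble, ⟨δ²(Δ)⟩ ~ Δ^α. α = 1 is free diffusion (slope 4D in 2D);
α < 1 is subdiffusion. For fractional Brownian motion (fBM) with Hurst
exponent H, α = 2H.

**Turning angles.** The unsigned angle θ ∈ [0°, 180°] between successive
displacement vectors at a fixed lag. Brownian motion gives a uniform
distribution; anticorrelated walks (fBM with H < 1/2, obstructed diffusion
near the percolation threshold) peak at 180°. The *lag dependence*
separates mechanisms that the MSD alone cannot: obstructed (percolation)
diffusion is scale-free, so its turning-angle distribution is invariant in
lag, while hop diffusion between permeable fences with a single
compartment size has a characteristic time — its 180° peak grows with lag
and then decays. The package quantifies this with the maximum pairwise
Kolmogorov–Smirnov statistic across lags.

**Meshwork morphometry.** Watershed segmentation of the rendered actin
image yields compartments with areas A and perimeters L. Repeated,
size-independent fragmentation (Kolmogorov's breakage model) predicts
log-normal areas; shape homogeneity across scales appears as a single
power law L ~ A^b with high log-log correlation; and the box-counting
(capacity) dimension d_f, from N(ε) ~ ε^(−d_f) occupied boxes at box size
ε, measures the meshwork's self-similarity. For a hierarchically branched
network, the bifurcation ratio R_b and length-order ratio R_r satisfy
R_b = R_r^{d_f}.

## Worked example

Simulate subdiffusive fBM, fit the anomalous exponent, and run the
model-discrimination statistics on an obstructed lattice walk:

```python
from cortexmesh.simulators import (FBMParams, simulate_fbm,
                                   build_obstacle_lattice, simulate_obstructed_walk)
from cortexmesh.spt_stats import (ensemble_ta_msd, fit_anomalous_exponent,
                                  angle_distribution, angle_mode,
                                  lag_invariance_statistic)

ens = simulate_fbm(FBMParams(hurst=0.3, n_steps=1024, n_traj=1000, seed=1))
msd = ensemble_ta_msd(ens, max_lag=2.0)
print(fit_anomalous_exponent(msd, (0.04, 2.0)).summary())

world = build_obstacle_lattice(side=256, obstacle_fraction=0.41, seed=2)
walk = simulate_obstructed_walk(world, n_steps=45_000, n_traj=200, seed=3,
                                sample_every=100)   # 100 hops per 20-ms frame
dists = angle_distribution(walk, [k * 0.02 for k in (1, 2, 5, 10, 25, 50)])
print("angle modes (deg):", [angle_mode(d) for d in dists])
print("lag-invariance KS:", round(lag_invariance_statistic(dists), 4))
```

Output:

```
power-law MSD fit: alpha = 0.6005, prefactor = 0.2105 um^2/s^alpha, range = [0.04, 2] s, R^2 = 1.0000
angle modes (deg): [180.0, 180.0, 180.0, 180.0, 180.0, 180.0]
lag-invariance KS: 0.0232
```

The fitted α = 0.60 recovers 2H for H = 0.3. The obstructed walk at 41%
obstacles — just above the percolation threshold — peaks at 180° at every
lag, and the small KS statistic (0.023) shows the distribution is
lag-invariant, the fingerprint that separates percolation-like obstruction
from fenced hop diffusion.

A command-line interface mirrors the library:

```bash
cortexmesh simulate fbm --hurst 0.3 --n-traj 500 --seed 1 --out tracks.csv
cortexmesh analyze msd --in tracks.csv --max-lag 2.0 --out msd.csv
cortexmesh study meshwork --config study.yaml
```

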