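"""Reproducible end-to-end studies: simulate → analyze → report.

A study is specified by a small key-value configuration (YAML on disk),
validated fail-fast (unknown keys are errors), and produces a
:class:`StudyReport` whose metrics are all traceable to files written in
the output directory.  Every output carries a JSON provenance sidecar
(config hash, seed, package version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from . import simulators, spt_stats
from .meshwork_synthesis import (
    generate_fragmentation_meshwork,
    make_reference_fractals,
    meshwork_to_localizations,
    render_localizations,
    simulate_meshwork_confined_tracks,
)
from .image_analysis import (
    box_count_dimension,
    fit_lognormal_areas,
    msd_vs_actin_distance,
    perimeter_area_scaling,
    watershed_compartments,
)
from .trajectory import write_trajectories

__all__ = ["StudyConfig", "StudyReport", "run_dynamics_study", "run_meshwork_study", "write_report"]


_DYNAMICS_BLOCKS = {"fbm", "brownian", "percolation", "fences"}
_DYNAMICS_KEYS = {"seed", "out_dir", "lags_frames", "bin_width_deg", "fit_range_s"} | _DYNAMICS_BLOCKS
_MESH_KEYS = {"seed", "out_dir", "meshwork", "localizations", "render", "tracks", "fractal"}


@dataclass
class StudyConfig:
    """Validated study configuration."""

    seed: int
    out_dir: Path
    blocks: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path, kind: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw, kind)

    @classmethod
    def from_dict(cls, raw: dict, kind: str) -> "StudyConfig":
        allowed = _DYNAMICS_KEYS if kind == "dynamics" else _MESH_KEYS
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {', '.join(sorted(unknown))}")
        if "seed" not in raw:
            raise ConfigError("missing required key: seed")
        blocks = {k: v for k, v in raw.items() if k not in ("seed", "out_dir", "lags_frames", "bin_width_deg", "fit_range_s")}
        analysis = {
            "lags_frames": raw.get("lags_frames", [1, 2, 5, 10, 25, 50]),
            "bin_width_deg": raw.get("bin_width_deg", 5.0),
            "fit_range_s": raw.get("fit_range_s"),
        }
        return cls(
            seed=int(raw["seed"]),
            out_dir=Path(raw.get("out_dir", "study_out")),
            blocks=blocks,
            analysis=analysis,
        )

    def digest(self) -> str:
        payload = json.dumps(
            {"seed": self.seed, "blocks": self.blocks, "analysis": self.analysis},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyReport:
    """Per-stage output files plus summary metrics and provenance."""

    files: dict
    metrics: dict
    provenance: dict


def _provenance(config: StudyConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed, "version": __version__}


def _sidecar(path: Path, config: StudyConfig) -> None:
    with open(str(path) + ".prov.json", "w") as fh:
        json.dump(_provenance(config), fh)


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise ConfigError(f"{field_name}: {message}")


def _simulate_block(name: str, params: dict, seed: int):
    params = dict(params or {})
    n_steps = int(params.pop("n_steps", 512))
    n_traj = int(params.pop("n_traj", 200))
    dt = float(params.pop("dt", 0.02))
    if name == "fbm":
        _require("hurst" in params, "fbm.hurst", "required")
        return simulators.simulate_fbm(
            simulators.FBMParams(
                hurst=float(params.pop("hurst")),
                n_steps=n_steps, dt=dt,
                step_scale=float(params.pop("step_scale", 0.1)),
                n_traj=n_traj, seed=seed,
            )
        )
    if name == "brownian":
        return simulators.simulate_brownian(
            float(params.pop("diffusivity", 0.19)), dt, n_steps, n_traj, seed
        )
    if name == "percolation":
        world = simulators.build_obstacle_lattice(
            int(params.pop("side", 256)),
            float(params.pop("obstacle_fraction", 0.41)),
            float(params.pop("lattice_constant", 0.05)),
            seed,
        )
        sample_every = int(params.pop("sample_every", 100))
        return simulators.simulate_obstructed_walk(
            world, n_steps * sample_every, n_traj, seed + 1, dt=dt, sample_every=sample_every
        )
    if name == "fences":
        world = simulators.FenceWorld(
            compartment_side=float(params.pop("compartment_side", 0.2)),
            hop_probability=float(params.pop("hop_probability", 0.05)),
            diffusivity=float(params.pop("diffusivity", 0.19)),
            dt=dt,
        )
        return simulators.simulate_fenced_diffusion(world, n_steps, n_traj, seed)
    raise ConfigError(f"unknown simulator block {name!r}")


def run_dynamics_study(config: StudyConfig) -> StudyReport:
    """Chain simulators → MSD/exponent fits → turning-angle distributions.

    One sub-study per simulator block; writes trajectory CSVs, MSD curves,
    angle distributions per lag and a lag-invariance statistic per block.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    unknown = set(config.blocks) - _DYNAMICS_BLOCKS
    if unknown:
        raise ConfigError(f"unknown simulator block(s): {', '.join(sorted(unknown))}")
    if not config.blocks:
        raise ConfigError("dynamics study requires at least one simulator block")
    files: dict = {}
    metrics: dict = {}
    lags_frames = config.analysis["lags_frames"]
    bin_width = float(config.analysis["bin_width_deg"])
    seeds = {name: config.seed + 1000 * i for i, name in enumerate(sorted(config.blocks))}
    for name, params in sorted(config.blocks.items()):
        ens = _simulate_block(name, params, seeds[name])
        dt = ens.frame_interval
        tracks_path = out / f"{name}_tracks.csv"
        write_trajectories(ens, tracks_path)
        _sidecar(tracks_path, config)
        n_frames = min(len(t) for t in ens.trajectories) - 1
        msd = spt_stats.ensemble_ta_msd(ens, max_lag=min(100, max(n_frames // 2, 3)) * dt)
        msd_path = out / f"{name}_msd.csv"
        pd.DataFrame(
            {"lag_s": msd.lags, "msd_um2": msd.values, "sd_um2": msd.spread, "n": msd.n_contributing}
        ).to_csv(msd_path, index=False)
        _sidecar(msd_path, config)
        fit_range = config.analysis["fit_range_s"] or spt_stats.default_fit_range(msd, dt)
        fit = spt_stats.fit_anomalous_exponent(msd, fit_range)
        lags_s = [k * dt for k in lags_frames if 2 * k + 1 <= n_frames]
        dists = spt_stats.angle_distribution(ens, lags_s, bin_width)
        ang_path = out / f"{name}_angles.csv"
        rows = []
        for d in dists:
            for j in range(len(d.density)):
                rows.append(
                    {
                        "lag_s": d.lag,
                        "bin_left_deg": d.bin_edges[j],
                        "bin_right_deg": d.bin_edges[j + 1],
                        "density_per_deg": d.density[j],
                    }
                )
        pd.DataFrame(rows).to_csv(ang_path, index=False)
        _sidecar(ang_path, config)
        fit_path = out / f"{name}_fits.json"
        block_metrics = {
            "alpha": fit.exponent,
            "prefactor": fit.prefactor,
            "r_squared": fit.r_squared,
            "angle_modes_deg": [spt_stats.angle_mode(d) for d in dists],
            "lag_invariance_ks": (
                spt_stats.lag_invariance_statistic(dists) if len(dists) >= 2 else None
            ),
        }
        with open(fit_path, "w") as fh:
            json.dump(block_metrics, fh, indent=1)
        _sidecar(fit_path, config)
        files[name] = {
            "tracks": str(tracks_path),
            "msd": str(msd_path),
            "angles": str(ang_path),
            "fits": str(fit_path),
        }
        metrics[name] = block_metrics
    return StudyReport(files, metrics, _provenance(config))


def run_meshwork_study(config: StudyConfig) -> StudyReport:
    """Chain meshwork synthesis → rendering → watershed morphometry →
    fractal dimension → MSD-vs-distance, on fully synthetic data."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "meshwork" not in config.blocks or config.blocks.get("meshwork") is None:
        raise ConfigError("meshwork: block is required and may not be empty")
    files: dict = {}
    metrics: dict = {}
    mw = dict(config.blocks["meshwork"])
    mesh = generate_fragmentation_meshwork(
        region=tuple(mw.pop("region", (12.0, 12.0))),
        n_generations=int(mw.pop("n_generations", 400)),
        min_area=float(mw.pop("min_area", 0.05)),
        seed=config.seed,
    )
    if mw:
        raise ConfigError(f"meshwork: unknown key(s) {', '.join(sorted(mw))}")
    mesh_path = out / "meshwork.json"
    mesh.to_json(mesh_path)
    _sidecar(mesh_path, config)
    files["meshwork"] = str(mesh_path)

    loc_cfg = dict(config.blocks.get("localizations") or {})
    locs = meshwork_to_localizations(
        mesh,
        linear_density=float(loc_cfg.pop("linear_density", 300.0)),
        precision_mean=float(loc_cfg.pop("precision_mean", 20.0)),
        precision_sd=float(loc_cfg.pop("precision_sd", 8.0)),
        n_frames=int(loc_cfg.pop("n_frames", 100)),
        seed=config.seed + 1,
    )
    if loc_cfg:
        raise ConfigError(f"localizations: unknown key(s) {', '.join(sorted(loc_cfg))}")
    render_cfg = dict(config.blocks.get("render") or {})
    pixel_size = float(render_cfg.pop("pixel_size", 20.0))
    image = render_localizations(locs, pixel_size=pixel_size, region=mesh.region)
    if render_cfg:
        raise ConfigError(f"render: unknown key(s) {', '.join(sorted(render_cfg))}")
    img_path = out / "meshwork.tiff"
    image.save_tiff(img_path)
    _sidecar(img_path, config)
    files["image"] = str(img_path)

    seg = watershed_compartments(image)
    seg_path = out / "compartments.csv"
    pd.DataFrame(
        {"label": seg.label_ids, "area_um2": seg.areas, "perimeter_um": seg.perimeters}
    ).to_csv(seg_path, index=False)
    _sidecar(seg_path, config)
    files["compartments"] = str(seg_path)
    mu_r, sg_r, gof = fit_lognormal_areas(seg.areas)
    mu_t, sg_t, _ = fit_lognormal_areas(mesh.true_areas())
    a_pref, b_exp, rho = perimeter_area_scaling(seg)
    metrics["segmentation"] = {
        "n_compartments": int(len(seg.areas)),
        "mu_log_recovered": mu_r,
        "sigma_log_recovered": sg_r,
        "lognormal_gof_p": gof,
        "mu_log_true": mu_t,
        "sigma_log_true": sg_t,
        "perimeter_area_prefactor": a_pref,
        "perimeter_area_exponent": b_exp,
        "perimeter_area_pearson_log": rho,
        "actin_coverage": seg.actin_coverage,
        "ridge_coverage": seg.ridge_coverage,
    }

    box = box_count_dimension(image)
    metrics["fractal_dimension_meshwork"] = box.fractal_dimension
    fr_cfg = config.blocks.get("fractal")
    if fr_cfg is not None:
        fr_cfg = dict(fr_cfg)
        oracle = make_reference_fractals(
            fr_cfg.pop("kind", "sierpinski_carpet"), int(fr_cfg.pop("size", 729)), seed=config.seed
        )
        sizes = [3**i for i in range(1, int(np.log(min(oracle.shape)) / np.log(3)))]
        metrics["fractal_dimension_oracle"] = box_count_dimension(
            oracle, box_sizes=sizes
        ).fractal_dimension
        if fr_cfg:
            raise ConfigError(f"fractal: unknown key(s) {', '.join(sorted(fr_cfg))}")

    tr_cfg = config.blocks.get("tracks")
    if tr_cfg is not None:
        tr_cfg = dict(tr_cfg)
        ens = simulate_meshwork_confined_tracks(
            mesh,
            diffusivity=float(tr_cfg.pop("diffusivity", 0.19)),
            hop_probability=float(tr_cfg.pop("hop_probability", 0.05)),
            dt=float(tr_cfg.pop("dt", 0.02)),
            n_steps=int(tr_cfg.pop("n_steps", 200)),
            n_traj=int(tr_cfg.pop("n_traj", 100)),
            seed=config.seed + 2,
        )
        if tr_cfg:
            raise ConfigError(f"tracks: unknown key(s) {', '.join(sorted(tr_cfg))}")
        tracks_path = out / "confined_tracks.csv"
        write_trajectories(ens, tracks_path)
        _sidecar(tracks_path, config)
        files["tracks"] = str(tracks_path)
        image.t_interval = None  # static meshwork: one window covers all times
        binned = msd_vs_actin_distance(ens, [image])
        msd_path = out / "msd_vs_distance.csv"
        pd.DataFrame(
            {
                "d_min_nm": binned.distance_bin_edges[:-1],
                "d_max_nm": binned.distance_bin_edges[1:],
                "msd_um2": binned.msd,
                "sem_um2": binned.sem,
                "n_segments": binned.n_segments,
            }
        ).to_csv(msd_path, index=False)
        _sidecar(msd_path, config)
        files["msd_vs_distance"] = str(msd_path)
        rho_s, p_s = binned.spearman()
        metrics["msd_vs_distance_spearman"] = {"rho": float(rho_s), "p": float(p_s)}

    report_path = out / "report.json"
    report = StudyReport(files, metrics, _provenance(config))
    write_report(report, report_path)
    return report


def write_report(report: StudyReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"files": report.files, "metrics": report.metrics, "provenance": report.provenance},
            fh, indent=1, default=float,
        )
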