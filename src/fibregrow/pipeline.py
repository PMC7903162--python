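"""End-to-end orchestration: grow -> optimise -> mesh -> measure -> report.

Also hosts the two study harnesses:

* an input-vs-output morphology sweep over Watson concentrations, which
  grows one phantom per kappa and compares achieved density and
  orientation dispersion against the sampled targets;
* a mechanism-ablation experiment growing matched phantoms with each
  growth mechanism toggled individually, reporting mean achieved density
  with its standard error over seeds.

Full-scale presets match a 20 x 20 x 20 um region with 2.5e6 growth nodes
(hours per phantom); the reduced presets (10 um region, 2e5 nodes) are the
desk-scale configuration used throughout the test-suite examples.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict

import numpy as np
import pandas as pd

from .config import GrowthConfig, MechanismFlags, load_config, save_config
from .directions import sample_watson
from .growth import Phantom, grow_all
from .initialise import seeds_to_dataframe
from .meshing import mesh_phantom, write_ply
from .morphometry import measure_density, orientation_stats, skeleton_centreline

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "run_table_experiment",
    "run_ablation_experiment",
    "phantom_summary",
    "REDUCED_PRESET",
    "FULL_PRESET",
    "ABLATION_SCENARIOS",
]

#: desk-scale preset: small region, node cloud scaled to keep the same
#: growth behaviour per unit volume
REDUCED_PRESET = {"region_size": (10.0, 10.0, 10.0), "n_nodes": 200_000}
#: the full-fidelity preset for production sweeps
FULL_PRESET = {"region_size": (20.0, 20.0, 20.0), "n_nodes": 2_500_000}

#: the four configurations of the ablation study: single parallel bundle,
#: single dispersed bundle, and two/three mutually perpendicular bundles
ABLATION_SCENARIOS = {
    "parallel": {
        "target_density": 0.75,
        "dispersion_model": "parallel",
        "bundles": [{"bundle_index": 0, "mean_direction": (0, 0, 1)}],
    },
    "watson_k8": {
        "target_density": 0.75,
        "dispersion_model": "watson",
        "watson_kappa": 8.0,
        "bundles": [{"bundle_index": 0, "mean_direction": (0, 0, 1)}],
    },
    "two_crossing": {
        "target_density": 0.40,
        "dispersion_model": "parallel",
        "bundles": [
            {"bundle_index": 0, "mean_direction": (0, 0, 1)},
            {"bundle_index": 1, "mean_direction": (1, 0, 0)},
        ],
    },
    "three_crossing": {
        "target_density": 0.30,
        "dispersion_model": "parallel",
        "bundles": [
            {"bundle_index": 0, "mean_direction": (0, 0, 1)},
            {"bundle_index": 1, "mean_direction": (1, 0, 0)},
            {"bundle_index": 2, "mean_direction": (0, 1, 0)},
        ],
    },
}


def phantom_summary(phantom: Phantom, voxel: float = 0.2) -> dict:
    """Achieved morphology: density, orientation stats, fibre accounting."""
    config = phantom.config
    region = np.asarray(config.region_size, dtype=float)
    completed = phantom.completed
    out = {
        "n_seeded": len(phantom.fibres),
        "n_completed": len(completed),
        "n_removed": len(phantom.removed),
    }
    if completed:
        out["density"] = measure_density(completed, (np.zeros(3), region), voxel=voxel)
        # orientation measured on diameter-scale-smoothed centre lines,
        # matching the mesh-slicing measurement procedure
        directions = []
        for f in completed:
            cl = skeleton_centreline(f.skeleton, f.radii, n_points=100)
            d = np.diff(cl, axis=0)
            directions.append(d[np.linalg.norm(d, axis=1) > 0])
        directions = np.vstack(directions)
        axis = np.asarray(config.bundles[0].mean_direction)
        stats = orientation_stats(directions, axis)
        out["mu_theta"] = stats.mu_theta
        out["sigma_theta"] = stats.sigma_theta
    else:
        out["density"] = 0.0
        out["mu_theta"] = float("nan")
        out["sigma_theta"] = float("nan")
    return out


def run_pipeline(
    config,
    output_dir=None,
    mechanisms: MechanismFlags | None = None,
    mesh: bool = True,
    grid_resolution: float | None = None,
    density_voxel: float = 0.2,
):
    """Run the full generation pipeline; returns (phantom, meshes, manifest).

    When ``output_dir`` is given, writes skeleton CSVs, PLY meshes, the
    growth log, a morphometry summary and a rerunnable manifest.
    """
    import os

    if not isinstance(config, GrowthConfig):
        config = load_config(config)
    if mechanisms is None:
        mechanisms = MechanismFlags.all()

    timings = {}
    t0 = time.perf_counter()
    phantom = grow_all(config, mechanisms)
    timings["grow_s"] = time.perf_counter() - t0

    meshes, mesh_failures = [], []
    if mesh and phantom.completed:
        t0 = time.perf_counter()
        meshes, mesh_failures = mesh_phantom(phantom, grid_resolution=grid_resolution)
        timings["mesh_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    summary = phantom_summary(phantom, voxel=density_voxel)
    timings["measure_s"] = time.perf_counter() - t0

    manifest = {
        "config": config.to_dict(),
        "mechanisms": asdict(mechanisms),
        "master_seed": config.master_seed,
        "fibres": {
            "seeded": summary["n_seeded"],
            "completed": summary["n_completed"],
            "removed": summary["n_removed"],
        },
        "morphology": {
            "density": summary["density"],
            "mu_theta_deg": summary["mu_theta"],
            "sigma_theta_deg": summary["sigma_theta"],
        },
        "mesh_failures": mesh_failures,
        "timings": timings,
    }

    if output_dir is not None:
        os.makedirs(output_dir, exist_ok=True)
        save_config(config, os.path.join(output_dir, "config.yaml"))
        seeds_df = pd.concat(
            [f.to_dataframe().assign(fibre=i) for i, f in enumerate(phantom.fibres) if len(f.radii)],
            ignore_index=True,
        ) if phantom.fibres else pd.DataFrame()
        seeds_df.to_csv(os.path.join(output_dir, "skeletons.csv"), index=False)
        pd.DataFrame(phantom.log).to_csv(os.path.join(output_dir, "growth_log.csv"), index=False)
        if meshes:
            write_ply(meshes, os.path.join(output_dir, "meshes"))
        with open(os.path.join(output_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return phantom, meshes, manifest


def run_table_experiment(
    kappas=(8, 10, 15, 20, 30, 50, 100),
    preset: dict | None = None,
    target_density: float = 0.75,
    master_seed: int = 0,
    n_target_samples: int = 10_000,
    mechanisms: MechanismFlags | None = None,
    density_voxel: float = 0.2,
) -> pd.DataFrame:
    """Input-vs-output morphology sweep over Watson concentrations.

    For each kappa the target mu/sigma of the polar angle come from 10^4
    Watson samples; a phantom is grown with all mechanisms and its output
    density, mu_theta, sigma_theta and fibre count are measured.
    """
    preset = dict(REDUCED_PRESET if preset is None else preset)
    rows = []
    for kappa in kappas:
        samples = sample_watson(kappa, (0, 0, 1), n_target_samples, seed=master_seed + 17)
        target = orientation_stats(samples)
        config = GrowthConfig(
            dispersion_model="watson",
            watson_kappa=float(kappa),
            target_density=target_density,
            master_seed=master_seed,
            **preset,
        )
        phantom = grow_all(config, mechanisms or MechanismFlags.all())
        summary = phantom_summary(phantom, voxel=density_voxel)
        rows.append(
            {
                "kappa": kappa,
                "input_density": target_density,
                "output_density": summary["density"],
                "target_mu_theta": target.mu_theta,
                "output_mu_theta": summary["mu_theta"],
                "target_sigma_theta": target.sigma_theta,
                "output_sigma_theta": summary["sigma_theta"],
                "n_fibres": summary["n_completed"],
            }
        )
        logger.info("kappa=%s done: %s", kappa, rows[-1])
    return pd.DataFrame(rows)


def run_ablation_experiment(
    scenarios=("parallel",),
    mechanism_sets: dict | None = None,
    seeds=(0, 1, 2),
    preset: dict | None = None,
    overrides: dict | None = None,
    density_voxel: float = 0.2,
) -> pd.DataFrame:
    """Achieved density by growth mechanism, mean +/- standard error over seeds."""
    preset = dict(REDUCED_PRESET if preset is None else preset)
    if mechanism_sets is None:
        mechanism_sets = {
            "minimal": MechanismFlags.minimal(),
            "collapse": MechanismFlags.only("collapse"),
            "dynamic_network": MechanismFlags.only("dynamic_network"),
            "fasciculation": MechanismFlags.only("fasciculation"),
            "global_optimisation": MechanismFlags.only("global_optimisation"),
            "all": MechanismFlags.all(),
        }
    rows = []
    for scen in scenarios:
        base = dict(ABLATION_SCENARIOS[scen])
        base.update(preset)
        if overrides:
            base.update(overrides)
        for name, flags in mechanism_sets.items():
            densities = []
            for seed in seeds:
                config = GrowthConfig(master_seed=int(seed), **base)
                phantom = grow_all(config, flags)
                densities.append(phantom_summary(phantom, voxel=density_voxel)["density"])
            densities = np.asarray(densities)
            rows.append(
                {
                    "scenario": scen,
                    "mechanisms": name,
                    "mean_density": float(densities.mean()),
                    "se_density": float(densities.std(ddof=1) / np.sqrt(len(densities)))
                    if len(densities) > 1
                    else 0.0,
                    "n_seeds": len(densities),
                }
            )
            logger.info("ablation %s/%s: %s", scen, name, rows[-1])
    return pd.DataFrame(rows)
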