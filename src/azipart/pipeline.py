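"""End-to-end pipeline: simulate → converge → PMF → partition → reweight.

Produces, in an output directory: the hill history (hills.dat), the sampled
trajectory with orientation (colvar.dat), raw and symmetrized PMFs,
a convergence report (JSON), the partition result (JSON), reweighted z and
PE densities, and a manifest recording the config, its hash and the seeds —
so a rerun with the same config is reproducible artifact-for-artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from pathlib import Path

import numpy as np

from . import __version__
from .convergence import extend_until_converged
from .dynamics import SoluteGeometry, attach_orientation
from .io import RunConfig, write_colvar, write_density, write_hills, write_pmf
from .metadynamics import MetadSettings, MetadynamicsRun, pmf_from_bias, symmetrize
from .partitioning import RegionSpec, partition_free_energy
from .potentials import make_model_potential
from .reweighting import orientation_summary, unbias_weights, weighted_density

__all__ = ["run_pipeline"]

log = logging.getLogger("azipart")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run every stage and write artifacts; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        potential = make_model_potential(
            config.potential_kind, config.potential_params,
            z_range=(config.z_min, config.z_max),
        )
        settings = MetadSettings(
            temperature=config.temperature,
            bias_factor=config.bias_factor,
            sigma=config.sigma,
            initial_height=config.initial_height,
            pace_steps=config.pace,
            dt=config.dt,
            friction=config.friction,
            z_min=config.z_min,
            z_max=config.z_max,
            grid_spacing=config.grid_spacing,
            sample_stride=config.sample_stride,
            z0=config.z0,
        )

        stage = "simulate"
        t0 = _time.perf_counter()
        run = MetadynamicsRun(potential, settings, config.seed)
        bias, report, n_ext = extend_until_converged(
            run,
            base_depositions=config.base_depositions,
            increment_depositions=config.increment_depositions,
            max_extensions=config.max_extensions,
            lookback_depositions=config.lookback_depositions,
        )
        timings[stage] = _time.perf_counter() - t0
        log.info("simulate: %d hills, %d extensions, converged=%s",
                 bias.n_depositions, n_ext, report.converged)

        traj = run.trajectory()
        geometry = SoluteGeometry(
            head_offset=config.head_offset,
            tail_offset=config.tail_offset,
            max_length=config.max_length,
        )
        traj = attach_orientation(
            traj, geometry,
            {"strength": config.orientation_strength,
             "edge": config.region_boundary,
             "corr_steps": config.orientation_corr_steps},
            seed=config.seed + 1,
        )
        write_hills(bias, outdir / "hills.dat")
        artifacts["hills"] = "hills.dat"
        write_colvar(traj, outdir / "colvar.dat")
        artifacts["colvar"] = "colvar.dat"
        with (outdir / "convergence.json").open("w") as fh:
            json.dump({**report.to_dict(), "n_extensions": n_ext}, fh, indent=2)
        artifacts["convergence"] = "convergence.json"

        stage = "pmf"
        t0 = _time.perf_counter()
        pmf_raw = pmf_from_bias(bias, water_cut=config.region_boundary)
        pmf_sym = symmetrize(pmf_raw)
        meta = {"temperature_K": config.temperature,
                "bias_factor": config.bias_factor}
        write_pmf(pmf_raw, outdir / "pmf_raw.dat", meta)
        write_pmf(pmf_sym, outdir / "pmf.dat", meta)
        artifacts["pmf_raw"] = "pmf_raw.dat"
        artifacts["pmf"] = "pmf.dat"
        timings[stage] = _time.perf_counter() - t0

        stage = "partition"
        t0 = _time.perf_counter()
        regions = RegionSpec(config.region_boundary, config.z_min, config.z_max)
        part = partition_free_energy(pmf_sym, regions, config.temperature)
        ground_truth = potential.ground_truth_delta_g(
            config.temperature, config.region_boundary
        )
        with (outdir / "partition.json").open("w") as fh:
            json.dump(
                {**part.to_dict(),
                 "ground_truth_delta_g_kJ_per_mol": ground_truth,
                 "converged": report.converged},
                fh, indent=2,
            )
        artifacts["partition"] = "partition.json"
        timings[stage] = _time.perf_counter() - t0

        stage = "reweight"
        t0 = _time.perf_counter()
        ws = unbias_weights(
            traj, bias,
            temperature=config.temperature,
            equilibration_fraction=config.equilibration_fraction,
        )
        z_edges = np.linspace(config.z_min, config.z_max, 121)
        write_density(weighted_density(ws, z_edges), outdir / "density_z.dat", "z")
        artifacts["density_z"] = "density_z.dat"
        pe_density, z_densities = orientation_summary(
            traj, bias, geometry,
            temperature=config.temperature,
            equilibration_fraction=config.equilibration_fraction,
        )
        write_density(pe_density, outdir / "density_pe.dat", "pe")
        artifacts["density_pe"] = "density_pe.dat"
        for name, dens in z_densities.items():
            fname = f"density_{name}.dat"
            write_density(dens, outdir / fname, name)
            artifacts[f"density_{name}"] = fname
        timings[stage] = _time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed in stage {stage!r} "
            f"(artifacts so far: {sorted(artifacts.values())}): {exc}"
        ) from exc

    manifest = {
        "package": "azipart",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seeds": {"dynamics": config.seed, "orientation": config.seed + 1},
        "converged": report.converged,
        "n_extensions": n_ext,
        "n_depositions": bias.n_depositions,
        "artifacts": artifacts,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with (outdir / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
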