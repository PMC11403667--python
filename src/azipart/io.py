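"""Text file formats and run configuration.

Trajectories and hill histories use the whitespace-delimited dialect common
to metadynamics post-processing tools: a ``#! FIELDS name name ...`` header
line followed by one row per record.  Parsing is header-driven, so column
order is free and unknown columns are preserved.  PMFs and densities are
plain multi-column text with ``#`` comment headers.  All writers/readers
are round-trip identities on their own output.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .dynamics import CVTrajectory
from .errors import FormatError, ParameterError
from .metadynamics import BiasState, PMFProfile, make_bias_state, replay_bias
from .reweighting import Density1D

__all__ = [
    "RunConfig",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "read_pmf",
    "write_pmf",
    "write_density",
    "read_density",
]

_FMT = "%.17g"  # repr-precision: round trips exactly through text


def _read_fields_table(path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    fields: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith("#!"):
                tokens = s[2:].split()
                if tokens and tokens[0] == "FIELDS":
                    fields = tokens[1:]
                continue
            if s.startswith("#"):
                continue
            if fields is None:
                raise FormatError(f"{path}:{lineno}: data before '#! FIELDS' header")
            parts = s.split()
            if len(parts) != len(fields):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(fields)} columns, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    if fields is None:
        raise FormatError(f"{path}: missing '#! FIELDS' header")
    data = np.array(rows, dtype=float) if rows else np.empty((0, len(fields)))
    return fields, data


def write_colvar(traj: CVTrajectory, path) -> None:
    """Write a trajectory: ``#! FIELDS time z [head_z tail_z] [bias] ...``."""
    cols: dict[str, np.ndarray] = {"time": traj.times, "z": traj.z}
    if traj.head_z is not None:
        cols["head_z"] = traj.head_z
    if traj.tail_z is not None:
        cols["tail_z"] = traj.tail_z
    if traj.bias is not None:
        cols["bias"] = traj.bias
    for name, values in traj.extras.items():
        arr = np.asarray(values)
        if arr.shape == traj.z.shape:
            cols[name] = arr
    with Path(path).open("w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        np.savetxt(fh, np.column_stack(list(cols.values())), fmt=_FMT)


def read_colvar(path, z_range: tuple[float, float] = (-6.0, 6.0)) -> CVTrajectory:
    """Parse a trajectory file; requires time and z columns."""
    fields, data = _read_fields_table(path)
    for required in ("time", "z"):
        if required not in fields:
            raise FormatError(f"{path}: mandatory column {required!r} missing")
    col = {name: data[:, i] for i, name in enumerate(fields)}
    known = {"time", "z", "head_z", "tail_z", "bias"}
    extras = {k: v for k, v in col.items() if k not in known}
    return CVTrajectory(
        times=col["time"],
        z=col["z"],
        head_z=col.get("head_z"),
        tail_z=col.get("tail_z"),
        bias=col.get("bias"),
        z_range=z_range,
        extras=extras,
    )


def write_hills(bias: BiasState, path) -> None:
    """Write the deposition history: one hill per row."""
    with Path(path).open("w") as fh:
        fh.write("#! FIELDS time center sigma height biasf\n")
        for time, center, height in bias.history:
            fh.write(
                " ".join(
                    _FMT % v
                    for v in (time, center, bias.sigma, height, bias.bias_factor)
                )
                + "\n"
            )


def read_hills(
    path,
    z_min: float = -6.0,
    z_max: float = 6.0,
    grid_spacing: float = 0.02,
    temperature: float = 300.0,
    initial_height: float = 25.0,
) -> BiasState:
    """Reconstruct a bias surface by replaying a recorded hill history.

    The grid parameters are not stored in the file and must be supplied.
    Non-monotonic deposition times are rejected; a height that *grows* on
    revisiting the same centre contradicts the well-tempered damping law
    and triggers a warning (the file is still replayed as recorded).
    """
    fields, data = _read_fields_table(path)
    for required in ("time", "center", "height"):
        if required not in fields:
            raise FormatError(f"{path}: mandatory column {required!r} missing")
    col = {name: data[:, i] for i, name in enumerate(fields)}
    times, centers, heights = col["time"], col["center"], col["height"]
    if times.size > 1 and np.any(np.diff(times) <= 0):
        bad = int(np.argmax(np.diff(times) <= 0)) + 2
        raise FormatError(f"{path}: deposition times not increasing at row {bad}")
    sigma = float(col["sigma"][0]) if "sigma" in col and times.size else 0.3
    bias_factor = float(col["biasf"][0]) if "biasf" in col and times.size else 20.0
    state = make_bias_state(
        z_min=z_min,
        z_max=z_max,
        grid_spacing=grid_spacing,
        temperature=temperature,
        bias_factor=bias_factor,
        sigma=sigma,
        initial_height=initial_height,
    )
    state.history = list(zip(times.tolist(), centers.tolist(), heights.tolist()))
    state.V = replay_bias(state.history, state.grid_z, state.sigma)
    # well-tempering sanity: revisits of (nearly) the same centre must not
    # deposit taller hills than before
    order = np.argsort(centers, kind="stable")
    sc, st, sh = centers[order], times[order], heights[order]
    close = np.abs(np.diff(sc)) < sigma / 2
    for i in np.flatnonzero(close):
        first, second = (i, i + 1) if st[i] <= st[i + 1] else (i + 1, i)
        if sh[second] > sh[first] * (1 + 1e-9):
            warnings.warn(
                f"{path}: hill height increases over time near z = {sc[i]:.3g} "
                "(inconsistent with well-tempered damping)",
                stacklevel=2,
            )
            break
    return state


def write_pmf(pmf: PMFProfile, path, meta: Mapping[str, object] | None = None) -> None:
    """Write a PMF as 3 columns (z, f, ci95) with a comment header."""
    with Path(path).open("w") as fh:
        fh.write(f"# offset_convention: {pmf.offset_convention}\n")
        fh.write(f"# symmetrized: {pmf.symmetrized}\n")
        fh.write(f"# water_cut: {_FMT % pmf.water_cut}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("# columns: z_nm f_kJ_per_mol ci95_kJ_per_mol\n")
        ci = pmf.ci95 if pmf.ci95 is not None else np.zeros_like(pmf.f)
        np.savetxt(fh, np.column_stack([pmf.grid_z, pmf.f, ci]), fmt=_FMT)


def read_pmf(path) -> PMFProfile:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    rows = []
    for line in lines:
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if ":" in s:
                key, _, value = s.lstrip("#").partition(":")
                meta[key.strip()] = value.strip()
            continue
        parts = s.split()
        if len(parts) != 3:
            raise FormatError(f"{path}: expected 3 columns, got {len(parts)}")
        rows.append([float(p) for p in parts])
    if not rows:
        raise FormatError(f"{path}: no data rows")
    data = np.array(rows)
    return PMFProfile(
        grid_z=data[:, 0],
        f=data[:, 1],
        ci95=data[:, 2],
        offset_convention=meta.get("offset_convention", "water_zero"),
        symmetrized=meta.get("symmetrized", "False") == "True",
        water_cut=float(meta.get("water_cut", 3.0)),
    )


def write_density(density: Density1D, path, label: str = "") -> None:
    """Two columns (bin_center, density) plus a normalization check line."""
    with Path(path).open("w") as fh:
        if label:
            fh.write(f"# observable: {label}\n")
        fh.write(f"# normalization: {_FMT % density.normalization}\n")
        fh.write(f"# bin_width: {_FMT % (density.bin_edges[1] - density.bin_edges[0])}\n")
        np.savetxt(fh, np.column_stack([density.bin_centers, density.density]), fmt=_FMT)


def read_density(path) -> Density1D:
    data = np.loadtxt(path)
    data = np.atleast_2d(data)
    centers, dens = data[:, 0], data[:, 1]
    width = centers[1] - centers[0] if centers.size > 1 else 1.0
    edges = np.concatenate([[centers[0] - width / 2], centers + width / 2])
    return Density1D(edges, dens)


@dataclass
class RunConfig:
    """End-to-end settings for the simulate→converge→partition→reweight run.

    Bias settings default to the well-tempered membrane-insertion values
    (sigma 0.3 nm, initial height 25 kJ/mol, bias factor 20, CV range ±6 nm,
    region boundary ±3 nm, 300 K); run lengths are desk-scale.
    """

    # physics / bias
    temperature: float = 300.0
    bias_factor: float = 20.0
    sigma: float = 0.3
    initial_height: float = 25.0
    pace: int = 50  # integrator steps between depositions
    z_min: float = -6.0
    z_max: float = 6.0
    region_boundary: float = 3.0
    grid_spacing: float = 0.02
    # dynamics
    dt: float = 0.001
    friction: float = 1.0
    sample_stride: int = 2
    z0: float = 0.0
    # protocol lengths (in depositions)
    base_depositions: int = 4000
    increment_depositions: int = 1000
    lookback_depositions: int = 100
    max_extensions: int = 8
    # reweighting / orientation
    equilibration_fraction: float = 0.25
    orientation_strength: float = 4.0
    orientation_corr_steps: float = 50.0
    head_offset: float = 0.9
    tail_offset: float = -0.9
    max_length: float = 2.0
    # model potential
    potential_kind: str = "amphiphile"
    potential_params: dict = field(
        default_factory=lambda: {
            "well_depth": 45.0,
            "well_position": 1.0,
            "barrier_height": 10.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_factor <= 1:
            raise ParameterError("bias_factor must exceed 1")
        if not (self.z_min < -self.region_boundary < 0 < self.region_boundary < self.z_max):
            raise ParameterError(
                "require z_min < -region_boundary < 0 < region_boundary < z_max"
            )
        for name in (
            "sigma", "initial_height", "dt", "friction", "grid_spacing",
            "base_depositions", "increment_depositions", "max_length",
        ):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
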