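"""Overdamped Langevin dynamics on 1D model potentials, plus a solute
orientation generator.

The walker plays the role of the solute's membrane-insertion coordinate
z(t).  Orientation is modelled as the cosine u of the angle between the
molecular (tail-to-head) axis and +z; u follows a temporally correlated
process whose stationary law is an exponential-tilt density ~ exp(kappa*u)
on [-1, 1], with the tilt strength kappa depending on z: strong alignment
with the outward membrane normal when embedded, isotropic in water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import lfilter
from scipy.special import ndtr

from ._kernels import step_chunk
from .constants import kt
from .errors import GeometryError, IntegrationError, ParameterError
from .potentials import ModelPotential

__all__ = ["CVTrajectory", "SoluteGeometry", "langevin_propagate", "attach_orientation"]


@dataclass(frozen=True)
class SoluteGeometry:
    """Rigid-rod reduction of the solute along its molecular axis.

    ``head_offset``/``tail_offset`` locate the head and tail groups relative
    to the centre of mass (nm, signed along the axis).  ``max_length`` is the
    normalisation length for the parallel-elongation statistic — slightly
    larger than the head-tail span, mimicking a maximum length observed over
    many configurations rather than the equilibrium span.
    """

    head_offset: float = 0.9
    tail_offset: float = -0.9
    max_length: float = 2.0

    def __post_init__(self) -> None:
        if self.max_length <= 0:
            raise ParameterError("max_length must be positive")
        if abs(self.head_offset - self.tail_offset) > self.max_length:
            raise GeometryError(
                "head-tail span exceeds max_length: "
                f"{abs(self.head_offset - self.tail_offset):g} > {self.max_length:g}"
            )

    @property
    def span(self) -> float:
        return abs(self.head_offset - self.tail_offset)


@dataclass
class CVTrajectory:
    """Time series of the collective variable and per-frame bookkeeping.

    ``bias`` holds V(z_i, t->infinity): the *final* bias surface evaluated at
    each frame's CV value, which is the weighting input for metadynamics
    reweighting.  ``head_z``/``tail_z`` are the z coordinates of the tracked
    head and tail groups when an orientation has been attached.
    """

    times: np.ndarray
    z: np.ndarray
    head_z: np.ndarray | None = None
    tail_z: np.ndarray | None = None
    bias: np.ndarray | None = None
    seed: int | None = None
    z_range: tuple[float, float] = (-6.0, 6.0)
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        for name in ("head_z", "tail_z", "bias"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                setattr(self, name, v)
                if v.shape != self.z.shape:
                    raise ParameterError(f"{name} length mismatch with z")
        if self.times.shape != self.z.shape:
            raise ParameterError("times and z must have equal lengths")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ParameterError("times must be strictly increasing")
        lo, hi = self.z_range
        if self.z.size and (self.z.min() < lo - 1e-9 or self.z.max() > hi + 1e-9):
            raise ParameterError("z values fall outside z_range")

    def __len__(self) -> int:
        return self.z.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, CVTrajectory):
            return NotImplemented

        def same(a, b):
            if a is None or b is None:
                return a is None and b is None
            return a.shape == b.shape and np.array_equal(a, b)

        return (
            same(self.times, other.times)
            and same(self.z, other.z)
            and same(self.head_z, other.head_z)
            and same(self.tail_z, other.tail_z)
            and same(self.bias, other.bias)
        )


def _potential_arrays(potential: ModelPotential):
    return (
        np.ascontiguousarray(potential.centers),
        np.ascontiguousarray(potential.amplitudes),
        np.ascontiguousarray(1.0 / potential.widths**2)
        if potential.widths.size
        else np.empty(0),
    )


def langevin_propagate(
    potential: ModelPotential,
    bias=None,
    dt: float = 0.001,
    friction: float = 1.0,
    temperature: float = 300.0,
    n_steps: int = 100_000,
    seed: int = 0,
    z0: float = 0.0,
    stride: int = 1,
) -> CVTrajectory:
    """Propagate the CV on U(z) = f0(z) + V(z) with overdamped dynamics.

    Euler-Maruyama: dz = (F/friction) dt + sqrt(2 kT dt / friction) * xi,
    with reflecting walls at the CV range edges.  Deterministic for a fixed
    seed.  ``bias``, if given, must expose ``grid_z`` and ``V`` arrays (a
    frozen bias surface; it is *not* updated here — see
    :func:`azipart.metadynamics.run_metadynamics` for on-the-fly biasing).

    Parameters are in the package's units: dt ps, friction kJ ps/mol/nm^2,
    temperature K.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if friction <= 0:
        raise ParameterError("friction must be positive")
    noise_scale = np.sqrt(2.0 * kt(temperature) * dt / friction)
    rng = np.random.default_rng(seed)
    z_min, z_max = potential.z_range
    if bias is not None:
        dz_grid = bias.grid_z[1] - bias.grid_z[0]
        fbias = -np.gradient(bias.V, dz_grid)
        inv_dz = 1.0 / dz_grid
        z_min, z_max = float(bias.grid_z[0]), float(bias.grid_z[-1])
    else:
        fbias, inv_dz = None, 0.0
    arrays = _potential_arrays(potential)
    noise = noise_scale * rng.standard_normal(n_steps)
    out = np.empty(n_steps)
    max_dz = step_chunk(
        float(z0), noise, dt / friction, arrays, z_min, z_max, fbias, inv_dz, out
    )
    if max_dz > 0.5 * (z_max - z_min):
        raise IntegrationError(
            f"single step moved {max_dz:.3g} nm, more than half the CV range; "
            "use a smaller dt (or larger friction)"
        )
    zs = out[stride - 1 :: stride].copy()
    times = dt * stride * np.arange(1, zs.size + 1)
    bias_at = None
    if bias is not None:
        bias_at = np.interp(zs, bias.grid_z, bias.V)
    return CVTrajectory(
        times, zs, bias=bias_at, seed=seed, z_range=(z_min, z_max)
    )


def _tilt_inverse_cdf(p: np.ndarray, kappa: np.ndarray) -> np.ndarray:
    """Quantile function of the density ~ exp(kappa*u) on [-1, 1].

    Stable for any sign and magnitude of kappa; kappa -> 0 reduces to the
    uniform law u = 2p - 1.
    """
    p = np.clip(p, 1e-15, 1.0 - 1e-15)
    kappa = np.asarray(kappa, dtype=float)
    small = np.abs(kappa) < 1e-8
    k = np.where(small, 1.0, kappa)
    # u = (1/k) * log((1-p) e^{-k} + p e^{k}), evaluated in log space
    u = np.logaddexp(np.log1p(-p) - k, np.log(p) + k) / k
    u = np.where(small, 2.0 * p - 1.0, u)
    return np.clip(u, -1.0, 1.0)


def attach_orientation(
    traj: CVTrajectory,
    geometry: SoluteGeometry = SoluteGeometry(),
    coupling_params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> CVTrajectory:
    """Populate head_z/tail_z with a z-coupled orientation process.

    The axis cosine u_t is generated from a latent stationary AR(1) Gaussian
    x_t mapped through its own CDF and then through the quantile function of
    the tilted density ~ exp(kappa(z) * sign(z) * u).  Consequences:

    * ``strength = 0`` — u is uniform on [-1, 1] (isotropic rod), so the
      parallel elongation |head_z - tail_z| / max_length is uniform on
      [0, span/max_length].
    * large ``strength`` inside the membrane — u -> sign(z): the head group
      points toward the membrane exterior, the tail toward the core.
    * |head_z - tail_z| <= geometry.span <= max_length for every frame, by
      construction.

    coupling_params keys: ``strength`` (peak tilt, dimensionless, default 4),
    ``edge`` (half-width of the aligned zone, nm, default 3), ``edge_width``
    (softness of the zone boundary, nm, default 0.3), ``corr_steps``
    (correlation time of the latent process in frames, default 50).
    """
    cp = dict(coupling_params or {})
    strength = float(cp.get("strength", 4.0))
    edge = float(cp.get("edge", 3.0))
    edge_width = float(cp.get("edge_width", 0.3))
    corr_steps = float(cp.get("corr_steps", 50.0))
    if strength < 0:
        raise ParameterError("strength must be non-negative")
    if edge_width <= 0 or corr_steps <= 0:
        raise ParameterError("edge_width and corr_steps must be positive")
    strength = min(strength, 500.0)  # exp-tilt saturates; avoids overflow

    n = len(traj)
    rng = np.random.default_rng(seed)
    rho = np.exp(-1.0 / corr_steps)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    if n:
        x[0] = eps[0]  # start in the stationary (unit-variance) law
    if n > 1:
        x[1:] = lfilter(
            [np.sqrt(1.0 - rho**2)], [1.0, -rho], eps[1:], zi=[rho * x[0]]
        )[0]
    p = ndtr(x)
    z = traj.z
    kappa = strength / (1.0 + np.exp((np.abs(z) - edge) / edge_width))
    u = _tilt_inverse_cdf(p, np.where(z >= 0, kappa, -kappa))
    head_z = z + geometry.head_offset * u
    tail_z = z + geometry.tail_offset * u
    return replace(
        traj,
        head_z=head_z,
        tail_z=tail_z,
        extras={**traj.extras, "orientation_seed": seed},
    )
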