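"""Membrane-like 1D model free-energy profiles with analytic ground truth.

The solute/bilayer system is reduced to a free-energy profile f0(z) along
the membrane-normal coordinate z (distance between the solute and the
bilayer midplane, nm).  Built-in profiles are sums of Gaussians, which keeps
them smooth, exactly even in z, and differentiable in closed form:

* ``amphiphile`` — two interfacial wells of depth D at z = ±z_well plus a
  central barrier of height B at z = 0 (head group hates the membrane core,
  tail hates water: the classic interfacial-binding shape).
* ``hydrophile`` — a single central barrier: the solute prefers water and
  pays a penalty for crossing the bilayer.
* ``flat`` — f0 = 0, no preference between the regions.
* ``custom`` — caller-supplied Gaussian components.

Every profile carries an analytic ground-truth partition free energy
obtained by dense Riemann quadrature, so downstream estimates can be
checked against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE
from .errors import ParameterError

__all__ = ["ModelPotential", "make_model_potential"]

_KNOWN_KINDS = ("amphiphile", "hydrophile", "flat", "custom")


@dataclass(frozen=True)
class ModelPotential:
    """Sum-of-Gaussians free-energy profile f0(z) on a closed z interval.

    ``f0(z) = sum_i amplitudes[i] * exp(-(z - centers[i])^2 / (2 widths[i]^2))``

    Negative amplitudes are wells, positive ones barriers.  All built-in
    kinds place components symmetrically about z = 0, so f0(z) = f0(-z)
    holds bit-exactly.
    """

    kind: str
    centers: np.ndarray
    amplitudes: np.ndarray
    widths: np.ndarray
    z_range: tuple[float, float] = (-6.0, 6.0)
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("centers", "amplitudes", "widths"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.centers.shape == self.amplitudes.shape == self.widths.shape):
            raise ParameterError("centers, amplitudes, widths must have equal shapes")
        if np.any(self.widths <= 0):
            raise ParameterError("Gaussian widths must be positive")

    def evaluate(self, z):
        """Free energy f0(z) in kJ/mol; accepts scalars or arrays."""
        z = np.asarray(z, dtype=float)
        if self.centers.size == 0:
            return np.zeros_like(z)
        dz = z[..., None] - self.centers
        return np.sum(self.amplitudes * np.exp(-0.5 * (dz / self.widths) ** 2), axis=-1)

    __call__ = evaluate

    def force(self, z):
        """-df0/dz in kJ/mol/nm."""
        z = np.asarray(z, dtype=float)
        if self.centers.size == 0:
            return np.zeros_like(z)
        dz = z[..., None] - self.centers
        g = self.amplitudes * np.exp(-0.5 * (dz / self.widths) ** 2)
        return np.sum(g * dz / self.widths**2, axis=-1)

    def ground_truth_delta_g(
        self,
        temperature: float = DEFAULT_TEMPERATURE,
        boundary: float = 3.0,
        n_points: int = 10_000,
    ) -> float:
        """Analytic water-to-bilayer partition free energy, kJ/mol.

        Midpoint Riemann quadrature of the Boltzmann-weighted integrals of
        f0 over the bilayer (|z| < boundary) and water (|z| >= boundary)
        regions at ``n_points`` nodes — an oracle independent of the
        trapezoidal route used by :mod:`azipart.partitioning`.
        """
        lo, hi = self.z_range
        edges = np.linspace(lo, hi, n_points + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        dz = edges[1] - edges[0]
        f = self.evaluate(mid)
        w = np.exp(-(f - f.min()) / (KB * temperature))
        in_bilayer = np.abs(mid) < boundary
        i_b = np.sum(w[in_bilayer]) * dz
        i_w = np.sum(w[~in_bilayer]) * dz
        v_b = 2.0 * boundary
        v_w = (hi - lo) - v_b
        return -KB * temperature * np.log((i_b / i_w) * (v_w / v_b))


def _amphiphile_components(params: Mapping[str, float]) -> tuple[np.ndarray, ...]:
    d = float(params["well_depth"])
    z_well = float(params["well_position"])
    b = float(params.get("barrier_height", 0.0))
    w_well = float(params.get("well_width", 0.5))
    w_barrier = float(params.get("barrier_width", 0.5))
    if w_well <= 0 or w_barrier <= 0:
        raise ParameterError("widths must be positive")
    if z_well <= 0:
        raise ParameterError("well_position must be positive")
    # Solve the 2x2 linear system so that, overlaps included, the profile is
    # exactly B at z = 0 and exactly -D at z = ±z_well.
    g_wb = np.exp(-0.5 * (z_well / w_well) ** 2)     # well gaussian at z=0
    g_ww = np.exp(-0.5 * (2 * z_well / w_well) ** 2)  # well gaussian at the mirror well
    g_bw = np.exp(-0.5 * (z_well / w_barrier) ** 2)   # barrier gaussian at z=±z_well
    mat = np.array([[2.0 * g_wb, 1.0], [1.0 + g_ww, g_bw]])
    a_well, a_barrier = np.linalg.solve(mat, np.array([b, -d]))
    centers = np.array([-z_well, z_well, 0.0])
    amplitudes = np.array([a_well, a_well, a_barrier])
    widths = np.array([w_well, w_well, w_barrier])
    return centers, amplitudes, widths


def make_model_potential(
    profile_kind: str,
    params: Mapping[str, float] | None = None,
    z_range: tuple[float, float] = (-6.0, 6.0),
) -> ModelPotential:
    """Build a membrane-like model potential.

    Parameters
    ----------
    profile_kind:
        One of ``amphiphile``, ``hydrophile``, ``flat``, ``custom``.
    params:
        ``amphiphile`` requires ``well_depth`` (D, kJ/mol), ``well_position``
        (z_well, nm) and accepts ``barrier_height`` (B at z=0), ``well_width``,
        ``barrier_width``.  ``hydrophile`` requires ``barrier_height`` and
        accepts ``barrier_width``.  ``custom`` requires ``centers``,
        ``amplitudes``, ``widths`` sequences.
    """
    params = dict(params or {})
    if profile_kind not in _KNOWN_KINDS:
        raise ParameterError(
            f"unknown profile kind {profile_kind!r}; expected one of {_KNOWN_KINDS}"
        )
    try:
        if profile_kind == "flat":
            c, a, w = np.empty(0), np.empty(0), np.empty(0)
        elif profile_kind == "amphiphile":
            c, a, w = _amphiphile_components(params)
        elif profile_kind == "hydrophile":
            b = float(params["barrier_height"])
            wb = float(params.get("barrier_width", 1.0))
            if wb <= 0:
                raise ParameterError("barrier_width must be positive")
            c, a, w = np.array([0.0]), np.array([b]), np.array([wb])
        else:  # custom
            c = np.asarray(params["centers"], dtype=float)
            a = np.asarray(params["amplitudes"], dtype=float)
            w = np.asarray(params["widths"], dtype=float)
    except KeyError as exc:
        raise ParameterError(
            f"missing parameter {exc.args[0]!r} for kind {profile_kind!r}"
        ) from None
    return ModelPotential(profile_kind, c, a, w, z_range=z_range, params=params)
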