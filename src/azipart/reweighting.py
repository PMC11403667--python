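"""Recover unbiased statistics from metadynamics-biased trajectories.

Once the bias has converged, a frame observed at CV value z carries the
weight e^{beta * V(z, t->infinity)}: the exponential of the converged bias
undoes the biased sampling, leaving the true free-energy surface as the
only influence on configurational probabilities.  Weighted histograms of
any per-frame observable (z of the head, tail or centre of mass; the
parallel-elongation statistic) then estimate its unbiased density,
normalized so the integrated total probability is 1.

Parallel elongation (PE) measures alignment with the membrane normal:

    PE = |head_z - tail_z| / L_max,

where L_max is the maximum molecular length ever observed.  PE = 1 is a
fully elongated molecule parallel to the z axis (perfect alignment with a
single leaflet); PE near 0 means no alignment — either perpendicular to
the normal or compact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import logsumexp

from .constants import kt
from .dynamics import CVTrajectory, SoluteGeometry
from .errors import EmptyDensityError, GeometryError, ParameterError
from .metadynamics import BiasState

__all__ = [
    "WeightedSamples",
    "Density1D",
    "unbias_weights",
    "weighted_density",
    "parallel_elongation",
    "orientation_summary",
]


@dataclass
class WeightedSamples:
    """Observable values with normalized unbiasing weights."""

    values: np.ndarray
    weights: np.ndarray
    beta: float
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape:
            raise ParameterError("values and weights must have equal lengths")
        if np.any(self.weights < 0):
            raise ParameterError("weights must be non-negative")
        total = self.weights.sum()
        if self.values.size and not np.isclose(total, 1.0, atol=1e-9):
            raise ParameterError(f"weights must sum to 1, got {total!r}")

    def with_values(self, values: np.ndarray, source: str = "") -> "WeightedSamples":
        """Same frames and weights, different per-frame observable."""
        return replace(self, values=np.asarray(values, dtype=float), source=source)

    def mean(self) -> float:
        return float(np.sum(self.weights * self.values))

    def var(self) -> float:
        m = self.mean()
        return float(np.sum(self.weights * (self.values - m) ** 2))


@dataclass
class Density1D:
    """Normalized 1D probability density on a bin grid."""

    bin_edges: np.ndarray
    density: np.ndarray

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.density.size != self.bin_edges.size - 1:
            raise ParameterError("density must have one value per bin")
        if np.any(self.density < 0):
            raise ParameterError("density must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def normalization(self) -> float:
        """Total integral; 1 up to floating-point rounding."""
        return float(np.sum(self.density * np.diff(self.bin_edges)))

    def mode(self) -> float:
        """Centre of the most probable bin."""
        return float(self.bin_centers[int(np.argmax(self.density))])


def unbias_weights(
    traj: CVTrajectory,
    bias_final: BiasState,
    temperature: float = 300.0,
    equilibration_fraction: float = 0.25,
    convergence_report=None,
) -> WeightedSamples:
    """Per-frame weights e^{beta V(z_i)} from the converged bias surface.

    The first ``equilibration_fraction`` of frames — the filling transient,
    during which the instantaneous bias differs most from its converged
    shape — is discarded.  ``values`` is initialized to the frames' CV
    values; use :meth:`WeightedSamples.with_values` to weight any other
    per-frame observable.  If a failed convergence report is supplied, a
    warning is emitted (reweighting with an unconverged bias is biased).
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    if not (0.0 <= equilibration_fraction < 1.0):
        raise ParameterError("equilibration_fraction must be in [0, 1)")
    if convergence_report is not None and not convergence_report.converged:
        warnings.warn(
            "reweighting a run whose convergence criteria failed; "
            "the recovered densities may be systematically biased",
            stacklevel=2,
        )
    start = int(equilibration_fraction * len(traj))
    z = traj.z[start:]
    if traj.bias is not None:
        v = traj.bias[start:]
    else:
        v = bias_final.evaluate(z)
    beta = 1.0 / kt(temperature)
    logw = beta * v
    logw -= logsumexp(logw)
    return WeightedSamples(
        values=z, weights=np.exp(logw), beta=beta, source="z"
    )


def weighted_density(samples: WeightedSamples, bin_edges: np.ndarray) -> Density1D:
    """Weighted histogram as a normalized probability density.

    Weight falling outside the bin range is discarded and the in-range
    density renormalized to unit integral.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if bin_edges.size < 2 or np.any(np.diff(bin_edges) <= 0):
        raise ParameterError("bin_edges must be increasing with at least two edges")
    counts, _ = np.histogram(samples.values, bins=bin_edges, weights=samples.weights)
    total = counts.sum()
    if total <= 0:
        raise EmptyDensityError("no weighted samples fall inside the bin range")
    return Density1D(bin_edges, counts / (total * np.diff(bin_edges)))


def parallel_elongation(head_z, tail_z, max_length: float):
    """PE = |head_z - tail_z| / max_length, in [0, 1]; vectorized."""
    if max_length <= 0:
        raise ParameterError("max_length must be positive")
    span = np.abs(np.asarray(head_z, dtype=float) - np.asarray(tail_z, dtype=float))
    if np.any(span > max_length * (1 + 1e-12)):
        raise GeometryError(
            "head-tail span exceeds max_length; the supplied max_length is "
            "inconsistent with the trajectory"
        )
    return span / max_length


def orientation_summary(
    traj: CVTrajectory,
    bias_final: BiasState,
    geometry: SoluteGeometry,
    temperature: float = 300.0,
    pe_bins: int = 40,
    z_bins: np.ndarray | int = 120,
    equilibration_fraction: float = 0.25,
    convergence_report=None,
) -> tuple[Density1D, dict[str, Density1D]]:
    """Unbiased PE density plus per-observable z densities.

    Returns the density of the parallel-elongation statistic and a dict of
    reweighted z densities for the tracked points: head group, tail group
    and centre of mass (the head/tail midpoint in the rod reduction).
    """
    if traj.head_z is None or traj.tail_z is None:
        raise ParameterError("trajectory carries no orientation (head_z/tail_z)")
    ws = unbias_weights(
        traj,
        bias_final,
        temperature=temperature,
        equilibration_fraction=equilibration_fraction,
        convergence_report=convergence_report,
    )
    start = len(traj) - ws.values.size
    head = traj.head_z[start:]
    tail = traj.tail_z[start:]
    pe = parallel_elongation(head, tail, geometry.max_length)
    pe_density = weighted_density(
        ws.with_values(pe, source="pe"), np.linspace(0.0, 1.0, pe_bins + 1)
    )
    if np.isscalar(z_bins):
        lo, hi = traj.z_range
        margin = geometry.max_length / 2
        z_bins = np.linspace(lo - margin, hi + margin, int(z_bins) + 1)
    z_densities = {
        "head": weighted_density(ws.with_values(head, source="head"), z_bins),
        "tail": weighted_density(ws.with_values(tail, source="tail"), z_bins),
        "com": weighted_density(
            ws.with_values(0.5 * (head + tail), source="com"), z_bins
        ),
    }
    return pe_density, z_densities
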