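"""Convergence control for the biased runs.

A run is accepted when three criteria hold simultaneously, exploiting the
mirror symmetry of the membrane system (the converged PMF must be even):

1. the pointwise asymmetry |f(z) - f(-z)| is at most 4 kJ/mol at every z;
2. the RMS over z of the half-difference (f(z) - f(-z))/2 — the standard
   error of the two-branch mean at each node — is below 2.5 kJ/mol;
3. the RMSD between the PMF at the end of the run and the PMF a fixed
   lookback earlier is below 2.5 kJ/mol (both water-zeroed first, so the
   drifting additive constant of the bias cannot fake stationarity).

Runs that fail are extended in fixed increments and re-tested, mirroring a
base-run + extensions protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError, ParameterError
from .metadynamics import BiasState, MetadynamicsRun, PMFProfile

__all__ = ["ConvergenceReport", "check_convergence", "extend_until_converged"]

DEFAULT_THRESHOLDS = (4.0, 2.5, 2.5)

#: Criterion 2 is evaluated as the RMS half-difference between branches;
#: criterion 1 as the pointwise (per-z) absolute branch difference.
ASYMMETRY_READING = "pointwise |f(z) - f(-z)|; RMS of half-difference"


@dataclass
class ConvergenceReport:
    """Outcome of the three-criterion convergence test (all kJ/mol)."""

    max_pointwise_asymmetry: float
    rms_asymmetry: float
    stationarity_rmsd: float
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS
    passed: dict = field(default_factory=dict)
    evaluation_time: float = 0.0
    extensions_exhausted: bool = False
    asymmetry_reading: str = ASYMMETRY_READING

    def __post_init__(self) -> None:
        if not self.passed:
            t1, t2, t3 = self.thresholds
            self.passed = {
                "pointwise_asymmetry": self.max_pointwise_asymmetry <= t1,
                "rms_asymmetry": self.rms_asymmetry <= t2,
                "stationarity": self.stationarity_rmsd <= t3,
            }
            self.passed["overall"] = all(
                self.passed[k]
                for k in ("pointwise_asymmetry", "rms_asymmetry", "stationarity")
            )

    @property
    def converged(self) -> bool:
        return bool(self.passed["overall"])

    def to_dict(self) -> dict:
        return {
            "statistics": {
                "max_pointwise_asymmetry": self.max_pointwise_asymmetry,
                "rms_asymmetry": self.rms_asymmetry,
                "stationarity_rmsd": self.stationarity_rmsd,
            },
            "thresholds": {
                "max_pointwise_asymmetry": self.thresholds[0],
                "rms_asymmetry": self.thresholds[1],
                "stationarity_rmsd": self.thresholds[2],
            },
            "passed": dict(self.passed),
            "evaluation_time": self.evaluation_time,
            "extensions_exhausted": self.extensions_exhausted,
            "asymmetry_reading": self.asymmetry_reading,
        }


def check_convergence(
    pmf_end: PMFProfile,
    pmf_earlier: PMFProfile,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
    evaluation_time: float = 0.0,
) -> ConvergenceReport:
    """Evaluate the three criteria on a pair of raw (unsymmetrized) PMFs."""
    if pmf_end.grid_z.shape != pmf_earlier.grid_z.shape or not np.allclose(
        pmf_end.grid_z, pmf_earlier.grid_z
    ):
        raise GridError("pmf_end and pmf_earlier must share a grid")
    if pmf_end.symmetrized or pmf_earlier.symmetrized:
        raise ParameterError(
            "convergence criteria compare raw branches; pass unsymmetrized PMFs"
        )
    if not pmf_end.has_symmetric_grid():
        raise GridError("asymmetry criteria require a grid symmetric about z = 0")
    f_end = pmf_end.water_zeroed().f
    f_prev = pmf_earlier.water_zeroed().f
    d = f_end - f_end[::-1]
    return ConvergenceReport(
        max_pointwise_asymmetry=float(np.max(np.abs(d))),
        rms_asymmetry=float(np.sqrt(np.mean((0.5 * d) ** 2))),
        stationarity_rmsd=float(np.sqrt(np.mean((f_end - f_prev) ** 2))),
        thresholds=thresholds,
        evaluation_time=evaluation_time,
    )


def extend_until_converged(
    run: MetadynamicsRun,
    base_depositions: int = 4000,
    increment_depositions: int = 1000,
    max_extensions: int = 8,
    lookback_depositions: int = 100,
    thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS,
) -> tuple[BiasState, ConvergenceReport, int]:
    """Run the base length, then extend in increments until converged.

    The lookback for the stationarity criterion is a fixed number of
    depositions (the scaled analogue of comparing against the PMF a fixed
    simulation time before the end).  When ``max_extensions`` is exhausted
    the last report is returned with ``extensions_exhausted`` set; no
    exception is raised.
    """
    if increment_depositions <= 0:
        raise ParameterError("increment_depositions must be positive")
    if not (0 < lookback_depositions < base_depositions):
        raise ParameterError("lookback must be positive and shorter than the base run")
    todo = base_depositions - run.n_depositions
    if todo > 0:
        run.advance(todo)
    n_extensions = 0
    while True:
        n = run.n_depositions
        report = check_convergence(
            run.pmf(with_ci=False),
            run.pmf_at(n - lookback_depositions, with_ci=False),
            thresholds=thresholds,
            evaluation_time=n * run.settings.pace_ps,
        )
        if report.converged or n_extensions >= max_extensions:
            report.extensions_exhausted = not report.converged
            return run.bias, report, n_extensions
        run.advance(increment_depositions)
        n_extensions += 1
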