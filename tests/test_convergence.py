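import numpy as np
import pytest

import azipart as az
from azipart.errors import GridError, ParameterError
from azipart.metadynamics import PMFProfile


def make_pmf(grid, f):
    return PMFProfile(np.asarray(grid, float), np.asarray(f, float))


class TestCriteria:
    def test_identical_even_profiles_pass_with_zero_statistics(self, grid_z):
        pmf = make_pmf(grid_z, grid_z**2)
        report = az.check_convergence(pmf, make_pmf(grid_z, grid_z**2))
        assert report.converged
        assert report.max_pointwise_asymmetry == pytest.approx(0.0, abs=1e-12)
        assert report.rms_asymmetry == pytest.approx(0.0, abs=1e-12)
        assert report.stationarity_rmsd == 0.0

    def test_single_node_asymmetry_of_five_fails_criterion_one(self, grid_z):
        """One 5 kJ/mol spike breaks the 4 kJ/mol pointwise cap while the
        RMS criterion stays comfortably below its threshold."""
        f = np.zeros_like(grid_z)
        f[np.argmin(np.abs(grid_z - 1.0))] = 5.0
        report = az.check_convergence(make_pmf(grid_z, f), make_pmf(grid_z, f))
        assert report.max_pointwise_asymmetry == pytest.approx(5.0)
        assert not report.passed["pointwise_asymmetry"]
        assert report.passed["rms_asymmetry"]
        assert not report.converged

    def test_constant_magnitude_drift_fails_stationarity_with_rmsd_three(self, grid_z):
        """Per-node differences all of magnitude 3 -> RMSD exactly 3 > 2.5.

        The difference field is odd (+3 right, -3 left) so the water-zero
        shift cannot absorb it.
        """
        drift = np.where(grid_z >= 0, 3.0, -3.0)
        report = az.check_convergence(
            make_pmf(grid_z, drift), make_pmf(grid_z, np.zeros_like(grid_z))
        )
        assert report.stationarity_rmsd == pytest.approx(3.0)
        assert not report.passed["stationarity"]

    def test_pure_offset_between_pmfs_is_ignored(self, grid_z):
        """A drifting additive constant must not register as non-stationarity."""
        report = az.check_convergence(
            make_pmf(grid_z, grid_z**2 + 40.0), make_pmf(grid_z, grid_z**2)
        )
        assert report.stationarity_rmsd == pytest.approx(0.0, abs=1e-9)
        assert report.converged

    def test_overall_is_the_conjunction_of_all_three(self, grid_z):
        # asymmetric end state compared against itself: criterion 3 trivially
        # passes while the asymmetry criteria fail -> overall must fail
        f = np.where(np.abs(grid_z - 1.0) < 0.5, 10.0, 0.0)
        report = az.check_convergence(make_pmf(grid_z, f), make_pmf(grid_z, f))
        assert report.passed["stationarity"]
        assert not report.passed["pointwise_asymmetry"]
        assert not report.converged

    def test_mirrored_input_yields_identical_report(self, grid_z):
        rng = np.random.default_rng(8)
        f_end = np.cumsum(rng.normal(size=grid_z.size)) * 0.1
        f_prev = f_end + rng.normal(size=grid_z.size) * 0.5
        a = az.check_convergence(make_pmf(grid_z, f_end), make_pmf(grid_z, f_prev))
        b = az.check_convergence(
            make_pmf(grid_z, f_end[::-1]), make_pmf(grid_z, f_prev[::-1])
        )
        assert a.max_pointwise_asymmetry == pytest.approx(b.max_pointwise_asymmetry, abs=1e-10)
        assert a.rms_asymmetry == pytest.approx(b.rms_asymmetry, abs=1e-10)
        assert a.stationarity_rmsd == pytest.approx(b.stationarity_rmsd, abs=1e-10)

    def test_grid_mismatch_rejected(self, grid_z):
        other = np.linspace(-6, 6, 301)
        with pytest.raises(GridError):
            az.check_convergence(
                make_pmf(grid_z, grid_z * 0), make_pmf(other, other * 0)
            )

    def test_symmetrized_input_rejected(self, grid_z):
        sym = az.symmetrize(make_pmf(grid_z, grid_z**2))
        with pytest.raises(ParameterError):
            az.check_convergence(sym, sym)


class TestExtensionProtocol:
    def test_generous_base_run_converges_without_extensions(self, amphiphile):
        run = az.MetadynamicsRun(amphiphile, az.MetadSettings(), seed=12)
        bias, report, n_ext = az.extend_until_converged(
            run, base_depositions=20_000, increment_depositions=2000,
            max_extensions=4, lookback_depositions=500,
        )
        assert report.converged
        assert n_ext == 0

    def test_zero_extension_budget_returns_flagged_report(self, amphiphile):
        run = az.MetadynamicsRun(amphiphile, az.MetadSettings(), seed=1)
        bias, report, n_ext = az.extend_until_converged(
            run, base_depositions=300, increment_depositions=100,
            max_extensions=0, lookback_depositions=50,
        )
        assert n_ext == 0
        assert not report.converged
        assert report.extensions_exhausted

    def test_invalid_lookback_rejected(self, amphiphile):
        run = az.MetadynamicsRun(amphiphile, az.MetadSettings(), seed=1)
        with pytest.raises(ParameterError):
            az.extend_until_converged(
                run, base_depositions=100, increment_depositions=50,
                lookback_depositions=100,
            )

    def test_asymmetry_shrinks_with_extension_in_expectation(self, amphiphile):
        """Across a small seed ensemble, the mean branch asymmetry after the
        longer run is no larger than after the short run (bounded noise)."""
        short, long_ = [], []
        for seed in (21, 22, 23):
            run = az.MetadynamicsRun(amphiphile, az.MetadSettings(), seed=seed)
            run.advance(2000)
            short.append(az.check_convergence(
                run.pmf(with_ci=False), run.pmf_at(1900, with_ci=False)
            ).rms_asymmetry)
            run.advance(10_000)
            long_.append(az.check_convergence(
                run.pmf(with_ci=False), run.pmf_at(11_900, with_ci=False)
            ).rms_asymmetry)
        assert np.mean(long_) <= np.mean(short) + 0.5
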