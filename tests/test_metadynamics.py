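import numpy as np
import pytest

import azipart as az
from azipart.constants import KB
from azipart.errors import RangeError, StateError
from azipart.metadynamics import PMFProfile, replay_bias

from _oracles import convergence_stats_bruteforce


def fresh_bias(**kw):
    return az.make_bias_state(**kw)


class TestDeposition:
    def test_first_hill_has_the_initial_height(self):
        bias = fresh_bias()
        az.deposit_gaussian(bias, 0.7, time=0.05)
        assert bias.history[0][2] == pytest.approx(25.0)
        assert bias.evaluate(0.7) == pytest.approx(25.0, abs=1e-6)

    def test_height_law_halves_at_kb_dT_ln2(self):
        """V(center) = kB*dT*ln2 damps the next hill to exactly w0/2."""
        bias = fresh_bias()
        bias.V += KB * bias.delta_T * np.log(2.0)
        az.deposit_gaussian(bias, 0.0, time=0.05)
        assert bias.history[0][2] == pytest.approx(12.5)

    def test_infinite_delta_T_reduces_to_untempered_hills(self):
        bias = fresh_bias(bias_factor=np.inf)
        for i in range(5):
            az.deposit_gaussian(bias, 0.0, time=0.05 * (i + 1))
        heights = [h for _, _, h in bias.history]
        assert heights == pytest.approx([25.0] * 5)

    def test_heights_strictly_decrease_on_revisits(self):
        bias = fresh_bias()
        for i in range(10):
            az.deposit_gaussian(bias, 1.3, time=0.05 * (i + 1))
        heights = [h for _, _, h in bias.history]
        assert all(b < a for a, b in zip(heights, heights[1:]))
        assert all(0 < h <= 25.0 for h in heights)

    def test_bias_is_monotone_in_time_at_every_node(self, amphiphile):
        bias, _ = az.run_metadynamics(amphiphile, seed=9, n_depositions=50)
        v_prev = np.zeros_like(bias.V)
        probe = fresh_bias()
        for time, center, height in bias.history:
            az.deposit_gaussian(probe, center, time, height=height)
            assert np.all(probe.V >= v_prev - 1e-12)
            v_prev = probe.V.copy()

    def test_out_of_range_centre_rejected(self):
        with pytest.raises(RangeError):
            az.deposit_gaussian(fresh_bias(), 6.5, time=0.05)

    def test_replay_reproduces_deposited_grid(self, amphiphile):
        bias, _ = az.run_metadynamics(amphiphile, seed=2, n_depositions=200)
        v = replay_bias(bias.history, bias.grid_z, bias.sigma)
        assert np.max(np.abs(v - bias.V)) < 1e-9

    def test_total_bias_mass_matches_history(self):
        """Deposited grid mass equals sum of hill heights x Gaussian mass."""
        bias = fresh_bias()
        rng = np.random.default_rng(0)
        for i, c in enumerate(rng.uniform(-3, 3, 50)):  # interior: no wall images
            az.deposit_gaussian(bias, c, time=0.05 * (i + 1))
        dz = bias.grid_z[1] - bias.grid_z[0]
        grid_mass = bias.V.sum() * dz
        hill_mass = sum(h for _, _, h in bias.history) * bias.sigma * np.sqrt(2 * np.pi)
        assert grid_mass == pytest.approx(hill_mass, rel=1e-6)


class TestPMFMap:
    def test_empty_bias_raises(self):
        with pytest.raises(StateError):
            az.pmf_from_bias(fresh_bias())

    def test_prefactor_is_gamma_over_gamma_minus_one(self):
        """f = -(gamma/(gamma-1)) V + const = -(20/19) V at the defaults."""
        bias = fresh_bias()
        az.deposit_gaussian(bias, 0.4, time=0.05)
        pmf = az.pmf_from_bias(bias, with_ci=False)
        recovered = -(20.0 / 19.0) * bias.V
        shift = pmf.f - recovered
        assert np.max(np.abs(shift - shift[0])) < 1e-9

    def test_water_region_mean_is_zero(self, amphiphile):
        bias, _ = az.run_metadynamics(amphiphile, seed=4, n_depositions=500)
        pmf = az.pmf_from_bias(bias, with_ci=False)
        mask = np.abs(pmf.grid_z) >= 3.0
        assert pmf.f[mask].mean() == pytest.approx(0.0, abs=1e-10)

    def test_run_is_deterministic(self, amphiphile):
        b1, t1 = az.run_metadynamics(amphiphile, seed=7, n_depositions=100)
        b2, t2 = az.run_metadynamics(amphiphile, seed=7, n_depositions=100)
        assert np.array_equal(b1.V, b2.V)
        assert b1.history == b2.history
        assert t1 == t2

    def test_advance_in_pieces_equals_one_shot(self, amphiphile):
        whole = az.MetadynamicsRun(amphiphile, az.MetadSettings(), seed=3).advance(120)
        parts = az.MetadynamicsRun(amphiphile, az.MetadSettings(), seed=3)
        parts.advance(50).advance(70)
        assert np.array_equal(whole.bias.V, parts.bias.V)
        assert whole.trajectory() == parts.trajectory()


class TestSymmetrize:
    def test_even_profile_is_a_fixed_point(self, grid_z):
        pmf = PMFProfile(grid_z, grid_z**2)
        out = az.symmetrize(pmf)
        assert out.f == pytest.approx(pmf.f, abs=1e-12)
        assert out.symmetrized
        assert np.max(out.ci95) < 1e-12  # branch term vanishes

    def test_odd_profile_cancels(self, grid_z):
        out = az.symmetrize(PMFProfile(grid_z, grid_z.copy()))
        assert np.max(np.abs(out.f)) < 1e-12

    def test_mixed_profile_keeps_even_part(self, grid_z):
        out = az.symmetrize(PMFProfile(grid_z, grid_z**2 + grid_z))
        assert out.f == pytest.approx(grid_z**2, abs=1e-9)

    def test_symmetrized_profile_is_exactly_even(self, converged_run):
        pmf = az.symmetrize(converged_run["run"].pmf(with_ci=False))
        assert np.array_equal(pmf.f, pmf.f[::-1])


class TestRecovery:
    def test_converged_run_recovers_the_model_pmf(self, amphiphile, converged_run):
        """Biased run through the convergence protocol reproduces f0 (water-
        zeroed, symmetrized) within the 2.5 kJ/mol stationarity tolerance."""
        assert converged_run["report"].converged
        pmf = az.symmetrize(converged_run["run"].pmf(with_ci=False))
        f0 = amphiphile.evaluate(pmf.grid_z)
        mask = np.abs(pmf.grid_z) >= 3.0
        f0 -= f0[mask].mean()
        rmsd = np.sqrt(np.mean((pmf.f - f0) ** 2))
        assert rmsd <= 2.5

    def test_convergence_stats_match_bruteforce(self, converged_run):
        run = converged_run["run"]
        end = run.pmf(with_ci=False)
        prev = run.pmf_at(run.n_depositions - 100, with_ci=False)
        report = az.check_convergence(end, prev)
        m, r, s = convergence_stats_bruteforce(end.f, prev.f, end.grid_z)
        assert report.max_pointwise_asymmetry == pytest.approx(m, abs=1e-10)
        assert report.rms_asymmetry == pytest.approx(r, abs=1e-10)
        assert report.stationarity_rmsd == pytest.approx(s, abs=1e-10)
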