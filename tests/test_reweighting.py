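import numpy as np
import pytest

import azipart as az
from azipart.constants import KB
from azipart.errors import EmptyDensityError, GeometryError, ParameterError

from _oracles import boltzmann_cdf_factory, boltzmann_moment, ks_uniform, weighted_ks


def make_traj(z, bias=None):
    z = np.asarray(z, float)
    return az.CVTrajectory(np.arange(1.0, z.size + 1), z, bias=bias)


class TestWeights:
    def test_constant_bias_gives_uniform_weights(self):
        traj = make_traj([0.1, 0.5, -0.3, 2.0], bias=[7.0, 7.0, 7.0, 7.0])
        bias = az.make_bias_state()
        ws = az.unbias_weights(traj, bias, 300.0, equilibration_fraction=0.0)
        assert ws.weights == pytest.approx(np.full(4, 0.25))

    def test_kbT_ln2_bias_difference_doubles_the_weight(self):
        dv = KB * 300 * np.log(2.0)
        traj = make_traj([0.0, 1.0], bias=[0.0, dv])
        ws = az.unbias_weights(traj, az.make_bias_state(), 300.0, equilibration_fraction=0.0)
        assert ws.weights[1] / ws.weights[0] == pytest.approx(2.0, rel=1e-12)

    def test_weights_normalized_and_nonnegative(self, converged_run):
        ws = az.unbias_weights(converged_run["run"].trajectory(), converged_run["bias"], 300.0)
        assert np.all(ws.weights >= 0)
        assert ws.weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equilibration_cut_drops_leading_frames(self):
        traj = make_traj(np.linspace(-1, 1, 100), bias=np.zeros(100))
        ws = az.unbias_weights(traj, az.make_bias_state(), 300.0, equilibration_fraction=0.25)
        assert ws.values.size == 75
        assert ws.values[0] == traj.z[25]

    def test_nonpositive_temperature_rejected(self):
        traj = make_traj([0.0], bias=[0.0])
        with pytest.raises((ParameterError, ValueError)):
            az.unbias_weights(traj, az.make_bias_state(), temperature=-1.0)

    def test_unconverged_report_warns(self, grid_z):
        from azipart.metadynamics import PMFProfile

        f = np.where(np.abs(grid_z - 1.0) < 0.5, 10.0, 0.0)
        bad = az.check_convergence(PMFProfile(grid_z, f), PMFProfile(grid_z, f))
        traj = make_traj([0.0, 0.5], bias=[0.0, 0.0])
        with pytest.warns(UserWarning, match="convergence"):
            az.unbias_weights(traj, az.make_bias_state(), 300.0,
                              equilibration_fraction=0.0, convergence_report=bad)

    def test_biased_harmonic_run_recovers_boltzmann_moments(self):
        """Reweighted mean/variance of z match the unbiased closed form.

        The walker runs in a deep (locally harmonic) well under a frozen
        linear-tilt bias; e^{beta V} weights must undo the tilt.
        """
        pot = az.make_model_potential(
            "custom", {"centers": [0.0], "amplitudes": [-300.0], "widths": [1.0]}
        )
        bias = az.make_bias_state()
        bias.V = 8.0 * bias.grid_z  # frozen tilt, kJ/mol per nm
        bias.history.append((0.0, 0.0, 0.0))  # mark as non-empty
        traj = az.langevin_propagate(pot, bias=bias, dt=0.0005, n_steps=400_000, seed=9)
        ws = az.unbias_weights(traj, bias, 300.0, equilibration_fraction=0.0)
        mean_exact = boltzmann_moment(pot, 1)
        var_exact = boltzmann_moment(pot, 2) - mean_exact**2
        assert ws.mean() == pytest.approx(mean_exact, abs=0.01)
        assert ws.var() == pytest.approx(var_exact, rel=0.10)


class TestDensity:
    def test_uniform_weights_reduce_to_plain_histogram(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=5000)
        n = x.size
        ws = az.WeightedSamples(x, np.full(n, 1.0 / n), beta=1.0)
        edges = np.linspace(-4, 4, 33)
        dens = az.weighted_density(ws, edges)
        ref, _ = np.histogram(x, bins=edges, density=True)
        assert dens.density == pytest.approx(ref, abs=1e-12)

    def test_single_occupied_bin_is_a_delta(self):
        ws = az.WeightedSamples([0.55, 0.56], [0.5, 0.5], beta=1.0)
        dens = az.weighted_density(ws, np.linspace(0, 1, 11))
        expected = np.zeros(10)
        expected[5] = 10.0  # 1 / bin_width
        assert dens.density == pytest.approx(expected)

    def test_integral_is_one(self, converged_run):
        ws = az.unbias_weights(converged_run["run"].trajectory(), converged_run["bias"], 300.0)
        dens = az.weighted_density(ws, np.linspace(-6, 6, 121))
        assert dens.normalization == pytest.approx(1.0, abs=1e-9)

    def test_all_samples_out_of_range_raises(self):
        ws = az.WeightedSamples([5.0, 6.0], [0.5, 0.5], beta=1.0)
        with pytest.raises(EmptyDensityError):
            az.weighted_density(ws, np.linspace(0, 1, 11))

    def test_reweighted_density_matches_boltzmann(self, amphiphile, converged_run):
        """Unbiasing a converged biased run recovers exp(-f0/kT)/Z."""
        ws = az.unbias_weights(converged_run["run"].trajectory(), converged_run["bias"], 300.0)
        cdf = boltzmann_cdf_factory(amphiphile)
        assert weighted_ks(ws.values, ws.weights, cdf) < 0.10


class TestParallelElongation:
    @pytest.mark.parametrize(
        "head,tail,expected",
        [(2.0, 0.0, 1.0), (1.3, 1.3, 0.0), (0.5, -0.5, 0.5), (-1.0, 1.0, 1.0)],
    )
    def test_linear_definition(self, head, tail, expected):
        assert az.parallel_elongation(head, tail, 2.0) == pytest.approx(expected)

    def test_inconsistent_max_length_raises(self):
        with pytest.raises(GeometryError):
            az.parallel_elongation(3.0, 0.0, 2.0)

    def test_pe_within_unit_interval_for_generated_frames(self, oriented_traj):
        pe = az.parallel_elongation(
            oriented_traj.head_z, oriented_traj.tail_z, az.SoluteGeometry().max_length
        )
        assert np.all((pe >= 0) & (pe <= 1))


class TestOrientationSummary:
    def test_aligned_fixture_concentrates_pe_near_one(self, amphiphile, converged_run):
        traj = az.attach_orientation(
            converged_run["run"].trajectory(), az.SoluteGeometry(),
            {"strength": 50.0}, seed=5,
        )
        pe_density, _ = az.orientation_summary(
            traj, converged_run["bias"], az.SoluteGeometry()
        )
        edges = pe_density.bin_edges
        widths = np.diff(edges)
        mass_high = np.sum((pe_density.density * widths)[edges[:-1] >= 0.7])
        assert mass_high > 0.6
        assert pe_density.mode() > 0.8

    def test_uncoupled_fixture_gives_flat_pe_density(self, converged_run):
        geom = az.SoluteGeometry()
        traj = az.attach_orientation(
            converged_run["run"].trajectory(), geom, {"strength": 0.0}, seed=6
        )
        ws = az.unbias_weights(traj, converged_run["bias"], 300.0)
        start = len(traj) - ws.values.size
        pe = az.parallel_elongation(traj.head_z[start:], traj.tail_z[start:], geom.max_length)
        assert ks_uniform(pe, ws.weights, 0.0, geom.span / geom.max_length) < 0.03

    def test_head_peak_lies_outside_tail_peak(self, converged_run, oriented_traj):
        """With the head pointing outward, the unbiased head density peaks
        farther from the membrane centre than the tail density."""
        _, z_dens = az.orientation_summary(
            oriented_traj, converged_run["bias"], az.SoluteGeometry()
        )
        assert abs(z_dens["head"].mode()) > abs(z_dens["tail"].mode())
        assert abs(z_dens["head"].mode()) > abs(z_dens["com"].mode())

    def test_missing_orientation_rejected(self, converged_run):
        with pytest.raises(ParameterError):
            az.orientation_summary(
                converged_run["run"].trajectory(), converged_run["bias"], az.SoluteGeometry()
            )
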