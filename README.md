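# azipart

Well-tempered metadynamics analysis of **membrane/water partitioning** on
one-dimensional model potentials: bias deposition and PMF reconstruction,
a symmetry-based convergence protocol, bilayer/water partition free
energies and partition coefficients, metadynamics reweighting of unbiased
observable densities, and a solute-orientation statistic.

The package is aimed at people developing or teaching enhanced-sampling
analyses of small-molecule membrane insertion — for instance amphiphiles
with a hydrophilic head group (such as a carboxy-2*H*-azirine) and a long
hydrophobic tail partitioning into a phospholipid bilayer. The expensive
all-atom part of such a study is replaced here by a synthetic stand-in
with *analytically known* answers: a membrane-like free-energy profile
f₀(z) along the insertion coordinate z (the distance from the bilayer
midplane, in nm), explored by an overdamped Langevin walker. Every
downstream stage — biasing, convergence control, partitioning,
reweighting — is exactly the analysis one would run on real
metadynamics output, and can be validated against the known ground truth.

## The method

**Well-tempered metadynamics.** Gaussian hills of width σ = 0.3 nm are
deposited along the collective variable z at a fixed pace. Each hill's
height is damped by the bias already present at its centre,

```
h = w₀ · exp(−V(z_c) / k_B ΔT),          w₀ = 25 kJ/mol,
```

so the CV is effectively sampled at T + ΔT (bias factor
γ = (T + ΔT)/T = 20; with T = 300 K, T + ΔT = 6000 K). At convergence
the PMF is recovered from the accumulated bias,

```
f(z) = −(γ/(γ−1)) · V(z, t→∞) + C,
```

with C fixed by the convention that the mean PMF over the water region
(|z| ≥ 3 nm) is zero, and f reported as the branch average
(f(z) + f(−z))/2, which the mirror symmetry of the membrane system makes
redundant copies of one another.

**Convergence.** A run stops only when (1) the pointwise asymmetry
|f(z) − f(−z)| is ≤ 4 kJ/mol everywhere, (2) the RMS of the
half-difference is < 2.5 kJ/mol, and (3) the RMSD between the PMF at the
end and a fixed lookback earlier is < 2.5 kJ/mol; otherwise the run is
extended in increments and re-tested.

**Partitioning.** With the bilayer region |z| < 3 nm and the water region
3 ≤ |z| ≤ 6 nm (equal volumes by construction),

```
ΔG_W→B = −RT ln[(∫_B e^(−f/RT) dz / ∫_W e^(−f/RT) dz) · (V_W/V_B)],
log₁₀ κ = −ΔG_W→B / (ln 10 · RT).
```

**Reweighting.** Frames of the biased trajectory are weighted by
e^(βV(z, t→∞)) to undo the bias; weighted histograms of any per-frame
observable give its unbiased density (normalised to unit integral). The
orientation statistic PE = |head_z − tail_z| / L_max is 1 for a fully
elongated molecule parallel to the membrane normal and near 0 for an
unaligned or compact one.

## Worked example

```python
import numpy as np
import azipart as az

pot = az.make_model_potential(
    "amphiphile", {"well_depth": 45.0, "well_position": 1.0, "barrier_height": 10.0}
)
run = az.MetadynamicsRun(pot, az.MetadSettings(), seed=1)
bias, report, n_ext = az.extend_until_converged(run)
pmf = az.symmetrize(run.pmf())
part = az.partition_free_energy(pmf)
print(report.converged, bias.n_depositions, n_ext)
print(round(part.delta_g, 2), part.log_kappa_rounded)
print(round(pot.ground_truth_delta_g(), 2))
```

prints

```
True 8000 4
-40.13 7
-39.33
```

— the run converged after 4 extensions (8000 hills); the estimated
partition free energy, −40.13 kJ/mol (log₁₀ κ ≈ +7), agrees with the
analytic ground truth of the model landscape, −39.33 kJ/mol, within the
protocol's 2.5 kJ/mol PMF tolerance. The scripts in `examples/` walk
through each capability (model potentials, PMF reconstruction, the
ΔG → log κ table, reweighting/orientation, the full pipeline) and print
the numbers they compute.

A thin CLI mirrors the stages:

```sh
azipart run-all --out out/            # full pipeline with the default config
azipart pmf --hills out/hills.dat --out pmf.dat
azipart partition --pmf pmf.dat --out partition.json
azipart reference-check                  # the five reference dG -> log kappa rows
```

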