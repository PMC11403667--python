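# Methods

## The model and what it stands in for

The object of study is the partitioning of a small solute between water
and a lipid bilayer, summarised by the potential of mean force f(z) along
the membrane-normal distance z between the solute and the bilayer
midplane. In a production study f(z) comes from all-atom metadynamics of
a solute in a solvated bilayer; here the landscape itself is an analytic
stand-in and the molecular dynamics is replaced by an overdamped Langevin
walker on that landscape. Everything downstream of the dynamics — bias
accumulation, the bias→PMF map, convergence control, partitioning,
reweighting — is the same analysis one would apply to real output, which
is the point: every stage can be checked against exact answers.

Units throughout: energies kJ/mol, lengths nm, times ps, temperatures K,
with k_B = R = 0.0083144626 kJ/mol/K.

### Model potentials

Built-in profiles are sums of Gaussians on z ∈ [−6, 6] nm, which makes
them smooth, exactly even in z, and differentiable in closed form:

* **amphiphile** — wells of depth D at z = ±z_well (head group at the
  interface, tail buried) plus a central barrier B (the head group's
  penalty for the membrane core). The two well amplitudes and the barrier
  amplitude are solved linearly so that, Gaussian overlaps included,
  f₀(±z_well) = −D and f₀(0) = B exactly. Default widths 0.5 nm put the
  profile within ~0.02 kJ/mol of zero for |z| > 3.
* **hydrophile** — a single central barrier: a solute that prefers water.
  With B = 10 kJ/mol and width 1 nm the ground-truth ΔG_W→B is
  +2.4 kJ/mol (log₁₀ κ ≈ −0.4, rounding to 0), i.e. near-indifference
  with a slight preference for water — the behaviour of a bare
  hydrophilic head group.
* **flat** and **custom** complete the set.

The standard test profile is the amphiphile with D = 45, z_well = 1,
B = 10 (ground truth ΔG_W→B = −39.33 kJ/mol at 300 K, by 10⁴-node
midpoint quadrature stored with the profile).

### Dynamics

Overdamped Euler–Maruyama: dz = (F/γ_f) dt + √(2 k_B T dt/γ_f) ξ, with
reflecting walls at ±6 nm. Defaults dt = 0.001 ps and friction
γ_f = 1 kJ·ps/mol/nm² give a free diffusion constant k_BT/γ_f ≈
2.5 nm²/ps, so a 10⁵-step run crosses the full CV range many times. The
walls realise the bounded CV range; reflection (rather than restraining
walls) is a deliberate choice because it preserves the equal-volume
bookkeeping of the two regions exactly. A step larger than half the CV
range aborts with advice to reduce dt. The discretisation inflates
stationary variances by ~k·dt/(2γ_f) in a well of curvature k, which is
why validation tests use a reduced dt.

### Orientation generator

Orientation is reduced to the cosine u of the angle between the
molecular (tail→head) axis and +z, for a rigid rod with head/tail
offsets ±0.9 nm from the centre of mass and a normalisation length
L_max = 2 nm. L_max deliberately exceeds the 1.8 nm span, mimicking a
"maximum length ever observed" that overestimates the equilibrium span —
so the parallel elongation PE = |head_z − tail_z|/L_max tops out at 0.9,
and density very close to PE = 1 is depleted.

u follows a latent stationary AR(1) Gaussian mapped through its CDF onto
the quantile function of the tilt density ∝ exp(κ(z)·sign(z)·u) on
[−1, 1]. κ(z) = strength / (1 + exp((|z| − edge)/w)) is large inside the
membrane (|z| < 3 nm) and ~0 outside. Consequences, each of which is a
tested contract: zero strength gives u uniform on [−1, 1], hence PE
uniform on [0, 0.9] (an isotropic tumbler — every PE value equally
probable); large strength pins u → sign(z), so the head points toward
the membrane exterior and PE → 0.9 for embedded frames; the length
bound |head_z − tail_z| ≤ L_max holds for every frame by construction.
What this generator does *not* emulate: flexible conformations (radius
of gyration changes), head-group chemistry, or any coupling from
orientation back onto the z dynamics.

## Well-tempered bias

Hills are Gaussians of width σ = 0.3 nm, initial height w₀ = 25 kJ/mol,
bias factor γ = 20 at T = 300 K (so k_BΔT = 47.4 kJ/mol and the CV is
effectively sampled at 6000 K), deposited every 50 integrator steps. The
deposition pace is a desk-scale knob, not a physical time: what matters
for the analysis is the number of hills, and the scaled protocol
(below) is expressed in depositions.

The bias lives on a uniform grid (spacing 0.02 nm, 601 nodes), hills
truncated at 6σ (relative error < 10⁻⁸). Hills whose tails cross the
reflecting walls are mirrored back inside the range; without this the
bias underfills within ~σ of the walls, producing a spurious ~50 kJ/mol
edge barrier that also poisons the water-zero offset. The deposition
history (time, centre, damped height) is retained, so any intermediate
bias state can be reconstructed by replay — this is how the lookback PMF
for the stationarity criterion and the block confidence band are
obtained, and how HILLS files round-trip.

The PMF estimate is f = −(γ/(γ−1))·V plus a constant fixed by zeroing
the mean over the water region |z| ≥ 3; the drifting constant of the
bias is thereby never reported. The 95% band is a normal-approximation
band over PMF estimates reconstructed at four cumulative checkpoints of
the history; symmetrisation adds the branch half-difference (the
standard error of the two-branch mean) in quadrature. The band is a
declared estimator — the analysis needs *some* dispersion measure and
nothing in the pipeline depends on its exact form.

## Convergence protocol

Three criteria on raw (unsymmetrised), water-zeroed PMFs:

1. max_z |f(z) − f(−z)| ≤ 4 kJ/mol. The pointwise reading ("at any
   specific z") is used; the report records which reading was applied.
2. RMS over z of (f(z) − f(−z))/2 ≤ 2.5 kJ/mol — the half-difference is
   the standard error of the two-branch mean at each node.
3. RMSD between the end PMF and the PMF a fixed lookback earlier
   ≤ 2.5 kJ/mol. Both are water-zeroed first so the growing additive
   constant cannot fake (or mask) stationarity.

The scheduler runs a base length, then extends in increments until all
three pass or the extension budget is exhausted (which returns a flagged
report, not an exception). Defaults scale the production protocol's
structure down: base 4000 depositions, increments of 1000 (¼ of base),
lookback 100 depositions (1/40 of base, mirroring a 50 ns lookback on a
2 μs base). Because the criteria measure symmetry and stationarity, not
accuracy, an unlucky run can stop with a still-underfilled (symmetric,
slowly-moving) bias; the recovery contract is therefore stochastic —
RMSD(f_sym, f₀) ≤ 2.5 kJ/mol for at least 2 of 3 seeds — and holds with
margin in practice (typical RMSD 0.5–1.6 kJ/mol).

## Partitioning

Trapezoidal quadrature of e^(−f/RT) over the bilayer (|z| ≤ 3) and water
(|z| ≥ 3) node spans, the shared boundary node contributing to both as a
zero-measure endpoint; ΔG = −RT ln[(I_B/I_W)(V_W/V_B)]. The integrand is
shifted by min f before exponentiation, making the result invariant to
any additive constant (tested to 10⁻⁹ kJ/mol). The ±3 nm boundary makes
V_B = V_W = 6 nm, so the volume ratio is 1 at the defaults but is kept
in the formula for non-default boundaries. log₁₀ κ = −ΔG/(ln 10·RT);
reports round ΔG and log κ to the nearest integer (ties away from zero),
reflecting that the convergence tolerances leave the ones digit as the
last significant place. The five reference (ΔG, log κ) pairs are bundled
as a worked-example verifier.

## Reweighting

Weights w_i ∝ e^(βV(z_i)) with V the *final* bias surface — the t→∞
form, not time-dependent weights with a normalisation correction. The
price of that simplicity is the filling transient, when the
instantaneous bias differs most from its converged shape; a configurable
equilibration cut (default: first 25% of frames) discards it. Weights
are normalised in log space. Residual branch asymmetry of the bias maps
directly onto the recovered left/right well occupancies (a 2.5 kJ/mol
asymmetry shifts the occupancy ratio by e^1), so distribution-level
fidelity (KS ≤ 0.05 against the exact Boltzmann law) needs a production
run well past minimal convergence: the reweighting validations use
2×10⁵-deposition runs, where the measured KS distance is 0.01–0.03
across seeds.

Densities are weighted histograms divided by bin width and in-range
weight, hence unit integral by construction; out-of-range weight is
dropped and the remainder renormalised. "Centre of mass" in the rod
reduction is the head/tail midpoint.

## Problem sizes and numerical choices

Default validation sizes, chosen to keep any single check within tens of
seconds on one CPU: recovery runs 4000+ depositions (seconds each),
reweighting production runs 2×10⁵ depositions (10⁷ steps, tens of
seconds), unbiased-equilibration checks 10⁷ steps. The integrator kernel
is numba-compiled when numba is importable; the fallback executes the
same floating-point operations in the same order, so results are
bit-identical either way. All randomness flows through
`numpy.random.default_rng(seed)`; noise is drawn per deposition
interval, which makes a run advanced in pieces bit-identical to a
one-shot run and is what makes the extension protocol reproducible.

Degenerate inputs: empty bias → state error on PMF reconstruction;
asymmetric grids are rejected wherever branch comparison is required;
hill centres outside the grid are range errors; a trajectory/max-length
mismatch in PE is a geometry error rather than silent clipping.

## Known limitations

* The stand-in is 1D: no lipid, water or ion degrees of freedom, no
  environment densities, and no box-fluctuation artifacts near |z| = 6.
* The convergence criteria certify symmetry and stationarity, not
  accuracy; the recovery guarantee is statistical over seeds.
* Final-bias reweighting is systematically biased if the run barely
  meets the convergence thresholds; the package warns when reweighting a
  run whose report failed, but cannot detect a merely-marginal one.
* The confidence band is a pragmatic block estimator, not a calibrated
  frequentist interval.
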