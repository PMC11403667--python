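"""Unbiased densities and solute orientation from a biased run.

Frames of a converged metadynamics trajectory are weighted by
exp(beta * V(z, t->inf)) to undo the bias.  The reweighted z-density then
matches the Boltzmann law of the model landscape, and the parallel
elongation PE = |head_z - tail_z| / L_max distinguishes an aligned,
membrane-embedded amphiphile (PE near its maximum) from an isotropic
tumbler (flat PE density).
"""

import numpy as np

import azipart as az

pot = az.make_model_potential(
    "amphiphile", {"well_depth": 45.0, "well_position": 1.0, "barrier_height": 10.0}
)
run = az.MetadynamicsRun(pot, az.MetadSettings(), seed=1)
bias, report, _ = az.extend_until_converged(run)
traj = run.trajectory()

ws = az.unbias_weights(traj, bias, 300.0)
print(f"frames reweighted : {ws.values.size} (converged={report.converged})")
print(f"reweighted <z^2>  : {ws.var() + ws.mean()**2:.3f} nm^2")

geom = az.SoluteGeometry()          # head +0.9 nm, tail -0.9 nm, L_max 2 nm
traj = az.attach_orientation(traj, geom, {"strength": 4.0}, seed=2)
pe_density, z_densities = az.orientation_summary(traj, bias, geom)
print(f"PE density mode   : {pe_density.mode():.3f} "
      f"(span/L_max = {geom.span / geom.max_length:.2f})")
print(f"head peak |z|     : {abs(z_densities['head'].mode()):.2f} nm")
print(f"tail peak |z|     : {abs(z_densities['tail'].mode()):.2f} nm")

# The embedded solute aligns with the membrane normal: PE concentrates
# near its geometric maximum and the head group sits farther from the
# bilayer midplane than the tail.
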