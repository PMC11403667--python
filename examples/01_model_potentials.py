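"""Build membrane-like model potentials and read off their ground truth.

Each built-in profile is a 1D free-energy landscape f0(z) along the
membrane-normal coordinate (z = 0 is the bilayer midplane).  The
amphiphile kind has interfacial wells at |z| = z_well and a central
barrier; the hydrophile kind is a single central barrier.  Every profile
knows its exact water-to-bilayer partition free energy by quadrature.
"""

import azipart as az

amph = az.make_model_potential(
    "amphiphile", {"well_depth": 45.0, "well_position": 1.0, "barrier_height": 10.0}
)
hydro = az.make_model_potential("hydrophile", {"barrier_height": 10.0})

for name, pot in [("amphiphile", amph), ("hydrophile", hydro)]:
    dg = pot.ground_truth_delta_g(temperature=300.0)
    logk = az.log_partition_coefficient(dg, 300.0)
    print(f"{name:11s}  f0(0) = {pot.evaluate(0.0):+6.1f} kJ/mol   "
          f"f0(1 nm) = {pot.evaluate(1.0):+6.1f} kJ/mol   "
          f"dG_W->B = {dg:+7.2f} kJ/mol   log10 kappa = {logk:+.2f}")

# The amphiphile binds the membrane strongly (large negative dG, log kappa
# ~ +7); the hydrophile slightly prefers water (small positive dG), the
# behaviour of a bare hydrophilic head group.
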