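"""Transcritical branch points and the small-g1 expansion of their locus.

A branch point (BP) is the parameter value at which the forest-free
equilibrium exchanges stability with a forest-containing branch: the root of
the invasion eigenvalue.  In the saturated-flammability regime the BP locus
satisfies (phi - mu - f1)/(phi + beta_F) = Bbar, and Bbar expands in powers
of the grassland flammability ceiling g1; the expansion error shrinks by one
order of g1 per term.
"""

import numpy as np

from fgba import ParameterSet, branch_point, series_branch_locus

params = ParameterSet(beta_G=50, beta_F=10, q=30, gamma=10, phi_G=1, phi_A=1,
                      mu=0.01, f0=0.01, g0=0.01, f1=0.5, g1=1.0)

g_bp = branch_point(params, "gamma", (1.0, 50.0))
print(f"grass-regrowth branch point: gamma = {g_bp:.4f} /yr")
print("  (the forest-free state is invadable below, stable above)\n")

phi_bp = branch_point(params, "phi", (0.1, 10.0))
print(f"forest-seeding branch point: phi = {phi_bp:.4f} /yr\n")

# series vs numerically located branch points, saturated-sigmoid regime
base = params.replace(theta_F=0.2, theta_G=0.2, s_F=0.015, s_G=0.015,
                      g0=0.0, f1=0.05)
print("locus value (phi - mu~)/(phi + beta_F) at the BP, series vs numeric:")
print("   g1     numeric    order0     order1     order2")
for g1 in (0.05, 0.1, 0.2):
    p = base.replace(g1=g1)
    phi = branch_point(p, "phi", (0.01, 20.0))
    v = (phi - (p.mu + p.f1)) / (phi + p.beta_F)
    row = [series_branch_locus(p, k) for k in (0, 1, 2)]
    print(f"  {g1:4.2f}  {v:9.6f}  " + "  ".join(f"{x:9.6f}" for x in row))
print("(each added order tracks the numeric locus one power of g1 closer)")
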