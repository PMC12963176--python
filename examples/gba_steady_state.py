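"""Locate the forest-free (grass-fire-ash) steady state and test invasibility.

The GBA equilibrium is the unique root of Phi_G(G) = calF(G); under strong
timescale separation it sits just below q/beta_G, and the closed-form
estimate (q/beta_G, gamma(1-q/beta_G)/(q+gamma), q(1-q/beta_G)/(q+gamma))
becomes accurate.  The sign of the invasion eigenvalue decides whether an
infinitesimal amount of forest can grow at that equilibrium.
"""

from fgba import ParameterSet, estimate_gba, solve_gba

sets = {
    "partially separated": ParameterSet(
        beta_G=50, beta_F=10, q=30, gamma=10, phi_G=1, phi_A=1, mu=0.01,
        f0=0.01, g0=0.01, f1=0.5, g1=1.0),
    "fully separated": ParameterSet(
        beta_G=5e4, beta_F=1e4, q=2e4, gamma=500, phi_G=1, phi_A=1, mu=0.01,
        f0=0.01, g0=0.01, f1=0.05, g1=0.1),
}

for name, params in sets.items():
    eq = solve_gba(params)
    print(f"{name}:")
    print(f"  exact root      G={eq.G:.6f}  B={eq.B:.6f}  A={eq.A:.6f}")
    try:
        G, B, A = estimate_gba(params)
        print(f"  estimate        G={G:.6f}  B={B:.6f}  A={A:.6f}"
              f"   (B/A = gamma/q = {B / A:.4g})")
    except ValueError:
        print("  estimate        not valid (q >= beta_G)")
    print(f"  stable within forest-free boundary: {eq.stable_within_gba}")
    lam = eq.invasion_eigenvalue
    verdict = "resists" if lam < 0 else "admits"
    print(f"  invasion eigenvalue {lam:+.4f} /yr -> {verdict} forest invasion")
    print()
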