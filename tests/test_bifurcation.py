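"""GBA steady state, invasion criteria, branch points, series and continuation."""

import numpy as np
import pytest

from fgba import (branch_point, calF, continuation_1d, estimate_gba,
                  fit_linear_regimes, forest_onset_sweep, gba_jacobian,
                  invasion_eigenvalue, mu_asymptotics, rhs_gba,
                  saturated_branch_relation, series_branch_locus, solve_gba,
                  transcritical_curvature)
from fgba.bifurcation import gba_jacobian_at

from conftest import draw_random_params


class TestCalF:
    def test_roots(self, partial):
        assert calF(1.0 - 1e-15, partial) == pytest.approx(0.0, abs=1e-10)
        assert calF(partial.q / partial.beta_G, partial) == pytest.approx(0.0, abs=1e-12)

    def test_reference_value(self, partial):
        assert calF(0.3, partial) == pytest.approx(8.75, rel=1e-12)

    def test_domain(self, partial):
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                calF(bad, partial)


class TestSolveGBA:
    def test_root_pinned_near_quench_ratio(self, separated):
        # strong timescale separation pins the root just below q/beta_G = 0.4
        eq = solve_gba(separated)
        assert eq.G == pytest.approx(0.4, abs=1e-3)

    def test_fixed_point_residual_on_random_draws(self):
        rng = np.random.default_rng(11)
        for p in draw_random_params(rng, 200):
            eq = solve_gba(p)
            assert np.max(np.abs(rhs_gba((eq.G, eq.B), p))) < 1e-10 * max(
                1.0, p.gamma, p.q)
            assert 0 < eq.G < min(1.0, p.q / p.beta_G)
            assert abs(eq.G + eq.B + eq.A - 1.0) < 1e-10

    def test_bracket(self, partial):
        assert solve_gba(partial).G < partial.q / partial.beta_G

    def test_slow_quenching_regime(self, partial):
        # q >= beta_G: the bracket is (0, 1) and a root still exists
        eq = solve_gba(partial.replace(q=80.0))
        assert 0 < eq.G < 1
        assert np.max(np.abs(rhs_gba((eq.G, eq.B), partial.replace(q=80.0)))) < 1e-9

    def test_uniqueness_by_dense_sign_scan(self):
        # the steady-state balance has exactly one sign change on the bracket
        rng = np.random.default_rng(12)
        for p in draw_random_params(rng, 100):
            hi = min(1.0, p.q / p.beta_G)
            G = np.linspace(1e-9, hi * (1 - 1e-9), 10_000)
            f = np.sign(p.Phi_G(G) - calF(G, p))
            changes = np.count_nonzero(np.diff(f) != 0)
            assert changes == 1


class TestEstimate:
    def test_reference_values(self, partial):
        assert estimate_gba(partial) == pytest.approx((0.6, 0.1, 0.3))

    def test_burning_ash_ratio(self, partial):
        G, B, A = estimate_gba(partial)
        assert B / A == pytest.approx(partial.gamma / partial.q, rel=1e-12)
        assert G + B + A == pytest.approx(1.0)

    def test_matches_exact_root_under_separation(self, separated):
        eq = solve_gba(separated)
        G_est, _, _ = estimate_gba(separated)
        assert abs(G_est - eq.G) < 1e-3

    def test_invalid_regime(self, partial):
        with pytest.raises(ValueError):
            estimate_gba(partial.replace(q=80.0))


class TestGBAJacobian:
    def test_matches_finite_differences(self, partial):
        eq = solve_gba(partial)
        J = gba_jacobian(partial)
        h = 1e-7
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            col = (rhs_gba(np.array([eq.G, eq.B]) + e, partial)
                   - rhs_gba(np.array([eq.G, eq.B]) - e, partial)) / (2 * h)
            assert np.allclose(J[:, j], col, rtol=1e-5, atol=1e-6)

    def test_always_stable_within_boundary(self):
        # eigenvalues of the forest-free linearisation are negative for all draws
        rng = np.random.default_rng(13)
        for p in draw_random_params(rng, 200):
            eq = solve_gba(p)
            J = gba_jacobian_at(eq.G, eq.B, p)
            assert np.trace(J) < 0
            assert np.all(np.linalg.eigvals(J).real < 0)
            assert eq.stable_within_gba


class TestInvasion:
    def test_high_mortality_blocks_invasion(self, partial):
        assert invasion_eigenvalue(partial.replace(mu=100.0)) < 0

    def test_reference_set_is_invasion_stable(self, partial):
        assert invasion_eigenvalue(partial) < 0

    def test_matches_full_jacobian_corner(self, partial):
        # the invasion eigenvalue is the top-left entry of the full
        # linearisation at F = 0 (block-triangular structure)
        from fgba import jacobian_reduced
        for gamma in (2.0, 6.0, 20.0):
            p = partial.replace(gamma=gamma)
            eq = solve_gba(p)
            J = jacobian_reduced(np.array([0.0, eq.G, eq.B]), p)
            assert J[0, 0] == pytest.approx(eq.invasion_eigenvalue, rel=1e-10)
            assert J[0, 1] == 0.0 and J[0, 2] == 0.0


class TestBranchPoint:
    def test_root_annihilates_eigenvalue(self, partial):
        g_bp = branch_point(partial, "gamma", (1.0, 50.0))
        assert abs(invasion_eigenvalue(partial.replace(gamma=g_bp))) < 1e-9

    def test_role_exchange_consistency(self, partial):
        # solve in phi, then re-solve in gamma at that phi: recovers gamma
        g_bp = branch_point(partial, "gamma", (1.0, 50.0))
        p_at = partial.replace(gamma=g_bp)
        phi_bp = branch_point(p_at, "phi", (0.1, 10.0))
        g_back = branch_point(partial.replace(phi_G=phi_bp, phi_A=phi_bp),
                              "gamma", (1.0, 50.0))
        assert g_back == pytest.approx(g_bp, abs=1e-6)

    def test_requires_sign_change(self, partial):
        with pytest.raises(ValueError):
            branch_point(partial, "gamma", (20.0, 50.0))

    def test_saturated_burning_relation(self, partial):
        # with the root well above the percolation threshold the branch
        # point obeys Bbar = (phi - mu~)/(phi + beta_F) to high accuracy
        p = partial.replace(theta_F=0.2, theta_G=0.2, s_F=0.015, s_G=0.015)
        phi_bp = branch_point(p, "phi", (0.1, 10.0))
        p_at = p.replace(phi_G=phi_bp, phi_A=phi_bp)
        eq = solve_gba(p_at)
        assert eq.G > p.theta_G + 2 * p.s_G
        B, rel = saturated_branch_relation(p_at)
        assert abs(B - rel) < 1e-8

    def test_transcritical_genericity(self, partial):
        g_bp = branch_point(partial, "gamma", (1.0, 50.0))
        assert abs(transcritical_curvature(partial.replace(gamma=g_bp))) > 1e-6


class TestSeries:
    def test_leading_term(self, partial):
        assert series_branch_locus(partial, 0) == pytest.approx(0.1, rel=1e-12)

    def test_second_order_terms(self, partial):
        # 0.1 + 0.03 - 0.015 term by term
        assert series_branch_locus(partial, 1) == pytest.approx(0.13, rel=1e-12)
        assert series_branch_locus(partial, 2) == pytest.approx(0.115, rel=1e-12)

    def test_invalid_regime_and_order(self, partial):
        with pytest.raises(ValueError):
            series_branch_locus(partial.replace(q=80.0), 0)
        with pytest.raises(ValueError):
            series_branch_locus(partial, 3)

    def test_error_scales_with_order(self, partial):
        # numeric branch-point locus in phi at beta_F = 10, saturated sigmoids
        base = partial.replace(theta_F=0.2, theta_G=0.2, s_F=0.015, s_G=0.015,
                               g0=0.0, f1=0.05)
        g1s = np.array([0.05, 0.1, 0.2])
        errs = np.empty((3, 3))
        for i, g1 in enumerate(g1s):
            p = base.replace(g1=g1)
            phi_bp = branch_point(p, "phi", (0.01, 20.0))
            v_num = (phi_bp - (p.mu + p.f1)) / (phi_bp + p.beta_F)
            for k in (0, 1, 2):
                errs[i, k] = abs(series_branch_locus(p, k) - v_num)
        # higher order is uniformly better at small g1 ...
        assert np.all(np.diff(errs, axis=1) < 0)
        # ... and the signed error scales like g1^(k+1)
        for k in (0, 1, 2):
            slope = np.polyfit(np.log(g1s), np.log(errs[:, k]), 1)[0]
            assert abs(slope - (k + 1)) < 0.5


class TestContinuation:
    def test_trivial_branch_exists_everywhere(self, partial):
        branches = continuation_1d(partial, "gamma", (1.0, 50.0), 1.0)
        triv = branches[0]
        assert np.all(triv.states[:, 0] == 0.0)
        assert len(triv) == 50
        # residual zero by construction: equilibria solve the GBA balance
        for v, s in zip(triv.values[::10], triv.states[::10]):
            r = rhs_gba((s[1], s[2]), partial.replace(gamma=v))
            assert np.max(np.abs(r)) < 1e-9

    def test_gamma_sweep_branch_point(self, partial):
        branches = continuation_1d(partial, "gamma", (1.0, 50.0), 1.0)
        bps = [v for lab, v, _ in branches[0].bifurcations if lab == "BP"]
        assert len(bps) == 1
        assert bps[0] == pytest.approx(branch_point(partial, "gamma", (1, 50)),
                                       abs=1e-8)
        # stability flips across the BP on the trivial branch
        below = [s for v, s in zip(branches[0].values, branches[0].stable)
                 if v < bps[0] - 0.5]
        above = [s for v, s in zip(branches[0].values, branches[0].stable)
                 if v > bps[0] + 0.5]
        assert not any(below) and all(above)

    def test_phi_sweep_fold_and_bistable_range(self, partial):
        # subcritical transcritical: stable forest branch folds back below
        # the BP, giving a bistable phi-range
        branches = continuation_1d(partial, "phi", (0.2, 3.0), 0.05)
        assert len(branches) == 2
        forest = branches[1]
        labs = {lab for lab, _, _ in forest.bifurcations}
        assert {"LP", "BP"} <= labs
        lp = [v for lab, v, _ in forest.bifurcations if lab == "LP"][0]
        bp = [v for lab, v, _ in forest.bifurcations if lab == "BP"][0]
        assert lp < bp
        # the forest branch carries stable points with high forest cover
        stable_F = forest.states[[s is True for s in forest.stable], 0]
        assert stable_F.size and stable_F.max() > 0.9
        # branch residuals vanish
        from fgba import rhs_fgba
        for v, s in zip(forest.values[::5], forest.states[::5]):
            p = partial.replace(phi_G=v, phi_A=v)
            assert np.max(np.abs(rhs_fgba(s, p))) < 1e-8

    def test_stability_consistent_with_eigenvalues(self, partial):
        branches = continuation_1d(partial, "phi", (0.2, 3.0), 0.05)
        for br in branches:
            for st, m in zip(br.stable, br.max_real_eig):
                if st is True:
                    assert m < 0
                elif st is False:
                    assert m > 0


class TestOnsetSweep:
    def test_takeover_matches_invasion_threshold(self, partial):
        # settling from F = 0.01 jumps to forest dominance at the first grid
        # value above the invasion branch point
        grid = np.arange(1.2, 1.7001, 0.05)
        res = forest_onset_sweep(partial, "phi", grid)
        bp = branch_point(partial, "phi", (0.1, 10.0))
        expected = grid[np.searchsorted(grid, bp)]
        assert res["threshold"] == pytest.approx(expected)
        # abrupt jump: threshold insensitive to the takeover cut
        for cut in (0.3, 0.7):
            r2 = forest_onset_sweep(partial, "phi", grid, takeover=cut)
            assert r2["threshold"] == pytest.approx(res["threshold"])

    def test_forest_suppressed_by_fire_spread(self, partial):
        # settled forest cover is nonincreasing in the fire spread rate
        p = partial.replace(phi_G=2.0, phi_A=2.0)
        grid = np.array([2.0, 6.0, 10.0, 14.0, 18.0])
        res = forest_onset_sweep(p, "beta_F", grid)
        F = res["states"][:, 0]
        assert np.all(np.diff(F) <= 1e-9)

    def test_below_threshold_forest_excluded(self, partial):
        res = forest_onset_sweep(partial, "phi", np.array([1.0]))
        assert res["states"][0, 0] < 1e-6
        assert res["threshold"] is None


class TestAsymptotics:
    def test_closed_form_unavailable(self, partial):
        with pytest.raises(NotImplementedError):
            mu_asymptotics(partial)

    def test_empirical_linear_regimes(self, partial):
        # the forest branch in mu is close to linear near its ends; the
        # low-F line extrapolates to zero forest at the fold/endpoint region
        branches = continuation_1d(partial, "mu", (0.001, 1.0), 0.02)
        forest = branches[1]
        fits = fit_linear_regimes(forest, low_band=(0.0, 0.35),
                                  high_band=(0.8, 1.0))
        F = forest.states[:, 0]
        for key, band in (("low", (0.0, 0.35)), ("high", (0.8, 1.0))):
            slope, icpt = fits[key]
            m = (F >= band[0]) & (F <= band[1]) & (F > 1e-12)
            pred = slope * forest.values[m] + icpt
            assert np.max(np.abs(pred - F[m])) < 0.05
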