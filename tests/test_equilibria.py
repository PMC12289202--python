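"""Isoclines, fixed-point location and linear stability."""

import math

import numpy as np
import pytest

from coevodyn import (
    BASELINE,
    BoundaryJacobianError,
    TraitState,
    find_fixed_points,
    host_isocline,
    host_selection_gradient,
    integrate_trajectory,
    jacobian,
    partner_isocline_alpha,
    partner_isocline_beta,
    partner_selection_gradient,
    sample_isoclines,
)


class TestHostIsocline:
    def test_empty_at_beta_zero(self):
        assert host_isocline(0.0, BASELINE) == ()

    def test_empty_below_existence_bound(self):
        # f(1-f) <= 1/4 means no solution for beta^2 < 4 cD
        assert host_isocline(0.5, BASELINE) == ()
        bound = 2 * math.sqrt(BASELINE.cD)
        for beta in np.linspace(-bound + 1e-6, bound - 1e-6, 41):
            assert host_isocline(float(beta), BASELINE) == ()

    @pytest.mark.parametrize("beta", [1.0, -1.0, 0.7, -2.5])
    def test_solution_zeroes_host_gradient(self, beta):
        (alpha,) = host_isocline(beta, BASELINE)
        assert alpha >= 0
        g = host_selection_gradient(TraitState(alpha, beta), BASELINE)
        assert abs(g) < 1e-12

    def test_known_value_at_beta_one(self):
        # f(1-f) = 0.1 on the f > 1/2 branch: alpha = logit((1+sqrt(0.6))/2)
        (alpha,) = host_isocline(1.0, BASELINE)
        assert alpha == pytest.approx(2.0634, abs=1e-3)

    @pytest.mark.parametrize("sign", [1.0, -1.0])
    def test_asymptote_approaches_zero_discrimination(self, sign):
        # the approach to alpha = 0 is logarithmic: alpha ~ log(beta^2/cD)/|beta|
        alphas = [host_isocline(sign * b, BASELINE)[0] for b in (2.0, 10.0, 50.0, 500.0)]
        assert all(a > 0 for a in alphas)
        assert alphas[0] > alphas[1] > alphas[2] > alphas[3]
        assert alphas[2] < 0.25 and alphas[3] < 0.03

    def test_never_crosses_commensalistic_axis(self):
        """Host gradient at beta=0 is -cD < 0 for every positive cD, so no
        commensalistic fixed point can exist anywhere in the cost sweeps."""
        for cD in (0.05, 0.1, 0.26, 0.35):
            p = BASELINE.with_(cD=cD)
            assert host_isocline(0.0, p) == ()
            assert host_selection_gradient(TraitState(1.0, 0.0), p) == -cD


class TestPartnerIsocline:
    def test_closed_form_at_beta_zero(self):
        # f = 1/2 exactly: alpha * 0.5 * 3.2 = 0.6
        (alpha,) = partner_isocline_alpha(0.0, BASELINE)
        assert alpha == pytest.approx(0.375, rel=1e-10)

    @pytest.mark.parametrize("beta,n_roots", [(-1.0, 1), (0.0, 1), (1.0, 2), (3.0, 0)])
    def test_root_multiplicity(self, beta, n_roots):
        roots = partner_isocline_alpha(beta, BASELINE)
        assert len(roots) == n_roots
        for alpha in roots:
            g = partner_selection_gradient(TraitState(alpha, beta), BASELINE)
            assert abs(g) < 1e-10

    def test_known_values(self):
        assert partner_isocline_alpha(-1.0, BASELINE)[0] == pytest.approx(0.28, abs=0.01)
        # near the mutualistic attractor the upper branch passes through
        # (alpha ~ 2.06, beta ~ 1.0)
        assert partner_isocline_alpha(1.0, BASELINE)[-1] == pytest.approx(2.06, abs=0.05)
        assert partner_isocline_alpha(1.0034, BASELINE)[-1] == pytest.approx(2.065, abs=0.01)

    def test_beta_parameterization_consistent(self):
        for alpha in (0.375, 1.0, 2.0):
            beta = partner_isocline_beta(alpha, BASELINE)
            g = partner_selection_gradient(TraitState(alpha, beta), BASELINE)
            assert abs(g) < 1e-10

    def test_approaches_commensalism_at_high_discrimination(self):
        # beta(alpha) ~ log(alpha * wP_hat(0) / cP) / alpha -> 0+ slowly
        betas = [partner_isocline_beta(a, BASELINE) for a in (2.0, 10.0, 50.0, 200.0)]
        assert all(b > 0 for b in betas[1:])
        assert betas[1] > betas[2] > betas[3]
        assert betas[2] < 0.12 and betas[3] < 0.05


class TestFixedPoints:
    def test_baseline_has_three_fixed_points(self, baseline_fps):
        assert len(baseline_fps) == 3

    def test_baseline_locations_and_labels(self, baseline_fps):
        expected = [
            (0.30, -0.64, "stable", "antagonistic"),
            (0.50, 0.64, "unstable", "mutualistic"),
            (2.06, 1.00, "stable", "mutualistic"),
        ]
        for fp, (a, b, stab, itype) in zip(baseline_fps, expected):
            assert fp.alpha == pytest.approx(a, abs=0.05)
            assert fp.beta == pytest.approx(b, abs=0.05)
            assert fp.stability == stab
            assert fp.interaction_type == itype

    def test_methods_agree(self, baseline_fps):
        iso = find_fixed_points(BASELINE, method="isocline")
        assert len(iso) == len(baseline_fps)
        for a, b in zip(iso, baseline_fps):
            assert math.hypot(a.alpha - b.alpha, a.beta - b.beta) < 1e-8

    def test_high_partner_cost_leaves_only_antagonism(self):
        fps = find_fixed_points(BASELINE.with_(cP=0.9), method="isocline")
        assert len(fps) == 1
        assert fps[0].interaction_type == "antagonistic"
        assert fps[0].stability == "stable"

    def test_gradients_vanish_at_fixed_points(self, baseline_fps):
        for fp in baseline_fps:
            assert abs(host_selection_gradient(fp.state, BASELINE)) < 1e-10
            assert abs(partner_selection_gradient(fp.state, BASELINE)) < 1e-10

    def test_fixed_points_lie_on_both_isoclines(self, baseline_fps):
        for fp in baseline_fps:
            alphas = host_isocline(fp.beta, BASELINE)
            assert min(abs(a - fp.alpha) for a in alphas) < 1e-6
            beta = partner_isocline_beta(fp.alpha, BASELINE)
            assert abs(beta - fp.beta) < 1e-6


class TestJacobian:
    def test_boundary_is_flagged(self):
        with pytest.raises(BoundaryJacobianError):
            jacobian(TraitState(0.0, 1.0), BASELINE)

    def test_host_row_scales_with_vH(self):
        p = BASELINE.with_(vH=0.0)
        J = jacobian(TraitState(1.0, 1.0), p)
        assert np.all(J[0] == 0.0)

    def test_matches_finite_differences(self, rng):
        from coevodyn.dynamics import trait_derivatives

        h = 1e-6
        for _ in range(100):
            a = rng.uniform(0.05, 6.0)
            b = rng.uniform(-3.0, 3.0)
            J = jacobian(TraitState(a, b), BASELINE)
            fd = np.empty((2, 2))
            for j, (da, db) in enumerate([(h, 0.0), (0.0, h)]):
                up = trait_derivatives(TraitState(a + da, b + db), BASELINE)
                dn = trait_derivatives(TraitState(a - da, b - db), BASELINE)
                fd[:, j] = (np.array(up) - np.array(dn)) / (2 * h)
            assert np.allclose(J, fd, rtol=1e-5, atol=1e-10)


class TestStability:
    def test_eigenvalues_scale_linearly_with_common_speed_factor(self, baseline_fps):
        k = 3.7
        scaled = BASELINE.with_(vH=BASELINE.vH * k, vP=BASELINE.vP * k)
        for fp in find_fixed_points(scaled):
            match = min(baseline_fps, key=lambda q: q.distance_to(fp.state))
            assert fp.stability == match.stability
            base_eigs = sorted(match.eigenvalues, key=lambda z: (z.real, z.imag))
            new_eigs = sorted(fp.eigenvalues, key=lambda z: (z.real, z.imag))
            for lam_new, lam_base in zip(new_eigs, base_eigs):
                assert lam_new == pytest.approx(k * lam_base, rel=1e-6)

    def test_stable_points_absorb_small_perturbations(self, baseline_fps, attractors):
        for fp in attractors.values():
            start = TraitState(fp.alpha + 1e-3, fp.beta + 1e-3)
            traj = integrate_trajectory(start, BASELINE, t_end=1e6,
                                        attractors=[fp])
            assert traj.converged
            assert fp.distance_to(traj.final) < 2e-3

    def test_unstable_point_repels_compass_perturbations(self, baseline_fps, attractors):
        saddle = [fp for fp in baseline_fps if fp.stability == "unstable"][0]
        escaped = 0
        for k in range(8):
            angle = k * math.pi / 4
            start = TraitState(
                saddle.alpha + 1e-3 * math.cos(angle),
                saddle.beta + 1e-3 * math.sin(angle),
            )
            traj = integrate_trajectory(
                start, BASELINE, t_end=2e6, attractors=list(attractors.values())
            )
            if saddle.distance_to(traj.final) > 0.1:
                escaped += 1
        assert escaped >= 1


def test_isocline_samples_are_roots(baseline):
    df = sample_isoclines(baseline, n=60)
    assert set(df["isocline_id"]) == {"host", "partner"}
    for _, row in df.iterrows():
        s = TraitState(row["alpha"], row["beta"])
        g = (
            host_selection_gradient(s, baseline)
            if row["isocline_id"] == "host"
            else partner_selection_gradient(s, baseline)
        )
        assert abs(g) < 1e-9
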