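"""Trait-ODE integration, boundary rule, convergence and pathway labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevodyn import (
    BASELINE,
    Trajectory,
    TraitState,
    UnclassifiableTrajectoryError,
    classify_transition,
    integrate_trajectory,
    trait_derivatives,
)


class TestTraitDerivatives:
    def test_boundary_clamp_active(self):
        # alpha=0, beta=0: host gradient -cD < 0 => clamped; partner drifts
        # towards antagonism at vP * (-cP/2)
        da, db = trait_derivatives(TraitState(0.0, 0.0), BASELINE)
        assert da == 0.0
        assert db == pytest.approx(-0.006, rel=1e-12)

    def test_no_clamp_off_boundary(self):
        da, db = trait_derivatives(TraitState(1.0, 0.0), BASELINE)
        assert da == pytest.approx(BASELINE.vH * (-BASELINE.cD), rel=1e-12)

    def test_no_clamp_when_selection_positive_on_boundary(self):
        # G_H(0, -3) = 9/4 - 0.1 > 0: discrimination is selected for
        da, _ = trait_derivatives(TraitState(0.0, -3.0), BASELINE)
        assert da == pytest.approx(BASELINE.vH * (9.0 * 0.25 - 0.1), rel=1e-12)

    def test_negative_alpha_evaluated_at_boundary(self):
        assert trait_derivatives(TraitState(-1e-9, 0.0), BASELINE) == \
            trait_derivatives(TraitState(0.0, 0.0), BASELINE)


class TestIntegration:
    def test_small_perturbation_returns_to_attractor(self, attractors):
        fp = attractors["M"]
        start = TraitState(fp.alpha + 1e-4, fp.beta + 1e-4)
        traj = integrate_trajectory(start, BASELINE, attractors=[fp])
        assert traj.converged
        dist = np.hypot(traj.alphas - fp.alpha, traj.betas - fp.beta)
        assert dist.max() < 1e-2

    def test_strongly_antagonistic_start_reaches_mutualism_at_equal_speeds(
        self, attractors
    ):
        traj = integrate_trajectory(
            TraitState(0.0, -3.0), BASELINE, attractors=list(attractors.values())
        )
        assert traj.converged_to is attractors["M"]

    def test_mutualistic_start_lost_under_fast_partner_evolution(self):
        from coevodyn.basins import stable_attractors

        p = BASELINE.with_(vH=0.001)
        att = stable_attractors(p)
        traj = integrate_trajectory(
            TraitState(0.0, 2.0), p, t_end=2e6, attractors=list(att.values())
        )
        assert traj.converged_to is att["A"]
        assert traj.pathway_label == "M_to_A"

    def test_alpha_never_negative_and_times_increase(self, attractors):
        traj = integrate_trajectory(
            TraitState(0.0, 0.5), BASELINE, attractors=list(attractors.values())
        )
        assert np.all(traj.alphas >= 0.0)
        assert np.all(np.diff(traj.times) > 0)

    def test_rejects_invalid_initial_conditions(self):
        with pytest.raises(ValueError):
            integrate_trajectory(TraitState(-0.5, 0.0), BASELINE)
        with pytest.raises(ValueError):
            integrate_trajectory(TraitState(0.0, 6.0), BASELINE)
        with pytest.raises(ValueError):
            integrate_trajectory(TraitState(0.0, 0.0), BASELINE, t_end=-1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        alpha0=st.floats(0.0, 4.0),
        beta0=st.floats(-3.0, 3.0),
    )
    def test_alpha_nonnegativity_preserved(self, alpha0, beta0):
        traj = integrate_trajectory(
            TraitState(alpha0, beta0), BASELINE, t_end=5e4,
            rtol=1e-6, atol=1e-8, n_dense=200,
        )
        assert np.all(traj.alphas >= 0.0)

    def test_all_starts_converge_to_one_of_two_attractors(self, attractors):
        """No limit cycles: a coarse start grid always reaches M or A."""
        for a0 in (0.0, 1.0, 2.5):
            for b0 in (-2.0, -0.5, 0.5, 2.0):
                traj = integrate_trajectory(
                    TraitState(a0, b0), BASELINE, t_end=2e6,
                    attractors=list(attractors.values()),
                )
                assert traj.converged_to in attractors.values()


class TestApproachGeometry:
    def test_oscillatory_approach_to_antagonistic_attractor(self, attractors):
        """Complex eigenvalues: the alpha-deviation changes sign at least
        twice on the way in."""
        fp = attractors["A"]
        traj = integrate_trajectory(
            TraitState(fp.alpha + 0.1, fp.beta + 0.1), BASELINE, attractors=[fp]
        )
        dev = traj.alphas - fp.alpha
        dev = dev[np.abs(dev) > 1e-6]
        sign_changes = int(np.sum(np.diff(np.sign(dev)) != 0))
        assert sign_changes >= 2

    def test_monotone_final_approach_to_mutualistic_attractor(self, attractors):
        """Real eigenvalues: distance decreases monotonically close in."""
        fp = attractors["M"]
        traj = integrate_trajectory(
            TraitState(fp.alpha + 0.1, fp.beta + 0.1), BASELINE, attractors=[fp]
        )
        dist = np.hypot(traj.alphas - fp.alpha, traj.betas - fp.beta)
        tail = dist[dist < 0.05]
        assert np.all(np.diff(tail) <= 1e-12)


class TestTimeRescaling:
    def test_common_speed_factor_only_rescales_time(self, attractors):
        """Multiplying both speeds by k leaves the trait-space path (and all
        labels) unchanged; only the clock changes."""
        k = 5.0
        start = TraitState(0.2, -1.5)
        slow = integrate_trajectory(start, BASELINE,
                                    attractors=list(attractors.values()))
        fast_params = BASELINE.with_(vH=BASELINE.vH * k, vP=BASELINE.vP * k)
        from coevodyn.basins import stable_attractors

        fast = integrate_trajectory(start, fast_params,
                                    attractors=list(stable_attractors(fast_params).values()))
        assert slow.pathway_label == fast.pathway_label
        assert slow.times[-1] == pytest.approx(k * fast.times[-1], rel=1e-3)
        # compare the paths at matched phases
        a_interp = np.interp(fast.times * k, slow.times, slow.alphas)
        b_interp = np.interp(fast.times * k, slow.times, slow.betas)
        assert np.allclose(a_interp, fast.alphas, atol=1e-4)
        assert np.allclose(b_interp, fast.betas, atol=1e-4)


class TestClassifyTransition:
    def _synthetic(self, betas, converged=True):
        n = len(betas)
        return Trajectory(
            times=np.arange(n, dtype=float),
            alphas=np.ones(n),
            betas=np.asarray(betas, dtype=float),
            params=BASELINE,
            converged=converged,
        )

    def test_no_crossing_is_none(self):
        assert classify_transition(self._synthetic([-1.0, -0.5, -0.6])) == "none"

    def test_single_crossings(self):
        assert classify_transition(self._synthetic([1.0, 0.2, -0.5])) == "M_to_A"
        assert classify_transition(self._synthetic([-1.0, -0.1, 0.8])) == "A_to_M"

    def test_back_and_forth(self):
        assert (
            classify_transition(self._synthetic([-1.0, 0.5, 0.8, -0.3, -0.6]))
            == "back_and_forth"
        )

    def test_jitter_below_epsilon_not_counted(self):
        betas = [-1.0, -5e-4, 5e-4, -5e-4, -1.0]
        assert classify_transition(self._synthetic(betas)) == "none"

    def test_commensalistic_start_is_other(self):
        assert classify_transition(self._synthetic([0.0, -0.5, -1.0])) == "other"

    def test_unconverged_is_unclassifiable(self):
        with pytest.raises(UnclassifiableTrajectoryError):
            classify_transition(self._synthetic([-1.0, 1.0], converged=False))

    def test_integrated_back_and_forth_example(self, attractors):
        """Moderate antagonistic start with intermediate discrimination under
        equal speeds: transient mutualism, then back to antagonism."""
        traj = integrate_trajectory(
            TraitState(0.4, -1.5), BASELINE, attractors=list(attractors.values())
        )
        assert traj.converged_to is attractors["A"]
        assert traj.pathway_label == "back_and_forth"
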