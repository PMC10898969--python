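"""Jacobian analysis, Turing conditions, dispersion relation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from turingmin.kinetics import compile_scheme, positive_steady_states
from turingmin.reactions import Reaction, ReactionScheme
from turingmin.stability import (
    Diffusivities,
    JacobianSummary,
    NotTuringCapableError,
    classify_pattern_type,
    delta_critical,
    dispersion,
    growth_rate_max,
    jacobian_at,
    turing_report,
    wavenumber_band,
)


def _random_jacobians(n, seed=0, scale=3.0):
    rng = np.random.default_rng(seed)
    return rng.uniform(-scale, scale, size=(n, 4))


def _turing_capable_jacobians(n, seed=0):
    """Random Jacobians satisfying trace<0, det>0 with the type-I structure."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        j11 = rng.uniform(0.05, 3)
        j22 = -rng.uniform(0.05, 3) - j11  # trace < 0
        j12 = -rng.uniform(0.05, 3)
        j21 = rng.uniform(0.05, 3)
        j = JacobianSummary(j11, j12, j21, j22)
        if j.det > 1e-3:
            out.append(j)
    return out


class TestJacobian:
    def test_two_bimolecular_reactions_give_zero_determinant(self):
        # only reactant combinations 2U and U+V: det(J*) = 0 at any
        # positive steady state (homogeneous quadratics)
        s = ReactionScheme((Reaction(2, 0, 3, 1, 1.0), Reaction(1, 1, 0, 0, 2.0)))
        k = compile_scheme(s)
        # steady states form a curve here, so probe the identity directly:
        # pick u, solve F(u,v)=0 for v, and evaluate det
        for u in (0.5, 1.0, 2.0):
            v = (k.a[3] * u * u) / (-k.a[4] * u)
            j11 = k.f_u(u, v)
            j12 = k.f_v(u, v)
            j21 = k.g_u(u, v)
            j22 = k.g_v(u, v)
            assert j11 * j22 - j12 * j21 == pytest.approx(0.0, abs=1e-12)

    def test_interspecific_preserving_V_class_sign_pattern(self):
        # 2U -> n1 U + m1 V; U+V -> V; V -> n3 U with n1-2 > m1 n3:
        # det > 0, J12 < 0, J21 > 0, J22 < 0 at the steady state
        s = ReactionScheme((Reaction(2, 0, 5, 1, 1.0), Reaction(1, 1, 0, 1, 9.0),
                            Reaction(0, 1, 2, 0, 1.0)))
        k = compile_scheme(s)
        (ss,) = positive_steady_states(k)
        j = jacobian_at(k, ss)
        assert j.det > 0 and j.j12 < 0 and j.j21 > 0 and j.j22 < 0

    def test_zero_coefficients_give_zero_matrix(self):
        from turingmin.kinetics import KineticCoefficients, SteadyState

        j = jacobian_at(KineticCoefficients((0,) * 6, (0,) * 6),
                        SteadyState(1.0, 1.0, 0.0))
        assert (j.j11, j.j12, j.j21, j.j22) == (0, 0, 0, 0)

    def test_trace_det_identities(self):
        j = JacobianSummary(1.5, -2.0, 3.0, -2.5)
        assert j.trace == 1.5 - 2.5
        assert j.det == 1.5 * -2.5 - (-2.0) * 3.0


class TestPatternClassification:
    @pytest.mark.parametrize(
        "entries,expected",
        [
            ((1, -1, 1, -1), "I"),
            ((-1, 1, -1, 1), "I"),      # relabelled U <-> V
            ((1, 1, -1, -1), "II"),
            ((-1, -1, 1, 1), "II"),     # relabelled
            ((1, 1, 1, 1), "none"),
            ((-1, -1, -1, -1), "none"),
            ((1, 0, 1, -1), "none"),    # zero entry never matches
        ],
    )
    def test_sign_patterns(self, entries, expected):
        assert classify_pattern_type(JacobianSummary(*entries)) == expected


class TestDeltaCritical:
    def test_closed_form_example(self):
        # J = [[1, -2], [3, -2]]: delta_c = (sqrt(4) + sqrt(6))^2
        j = JacobianSummary(1, -2, 3, -2)
        assert delta_critical(j) == pytest.approx((2 + np.sqrt(6)) ** 2, rel=1e-12)

    def test_bisection_oracle(self):
        # independent check: bisect on "does an unstable band exist at delta"
        for j in _turing_capable_jacobians(50, seed=3):
            dc = delta_critical(j)
            lo, hi = 1e-6, 1e12
            for _ in range(100):
                mid = np.sqrt(lo * hi)
                if wavenumber_band(j, Diffusivities(1.0, mid)) is not None:
                    hi = mid
                else:
                    lo = mid
            assert dc == pytest.approx(np.sqrt(lo * hi), rel=1e-6)

    def test_band_flips_exactly_at_threshold(self):
        for j in _turing_capable_jacobians(200, seed=4):
            dc = delta_critical(j)
            assert wavenumber_band(j, Diffusivities(1.0, 1.01 * dc)) is not None
            assert wavenumber_band(j, Diffusivities(1.0, 0.99 * dc)) is None

    def test_nonnegative_trace_rejected(self):
        with pytest.raises(NotTuringCapableError):
            delta_critical(JacobianSummary(1, -2, 3, -0.5))  # trace > 0

    def test_relabelled_jacobian_handled(self):
        j = JacobianSummary(1, -2, 3, -2)
        assert delta_critical(j.swapped()) == pytest.approx(delta_critical(j))

    def test_continuity_in_entries(self):
        j = JacobianSummary(1, -2, 3, -2)
        eps = 1e-7
        j2 = JacobianSummary(1, -2 + eps, 3, -2)
        assert delta_critical(j2) == pytest.approx(delta_critical(j), rel=1e-5)


class TestDispersion:
    def test_matches_eigenvalue_oracle_on_1000_jacobians(self):
        rng = np.random.default_rng(7)
        k_grid = np.logspace(-2, 1, 7)
        d = Diffusivities(1.0, 10.0)
        for row in _random_jacobians(1000, seed=8):
            j = JacobianSummary(*row)
            lam, det = dispersion(j, d, k_grid)
            for kk, l_closed, det_closed in zip(k_grid, lam, det):
                jt = np.array([[j.j11 - d.du * kk**2, j.j12],
                               [j.j21, j.j22 - d.dv * kk**2]])
                ev = np.linalg.eigvals(jt)
                assert l_closed == pytest.approx(np.max(ev.real), abs=1e-10)
                assert det_closed == pytest.approx(np.linalg.det(jt), rel=1e-9, abs=1e-10)

    def test_zero_wavenumber_recovers_kinetic_eigenvalue(self):
        j = JacobianSummary(1, -2, 3, -2)
        lam, _ = dispersion(j, Diffusivities(1, 10), np.array([1e-12]))
        ev = np.linalg.eigvals(j.as_matrix())
        assert lam[0] == pytest.approx(np.max(ev.real), abs=1e-8)

    def test_positive_growth_exactly_inside_band(self):
        for j in _turing_capable_jacobians(30, seed=5):
            dc = delta_critical(j)
            d = Diffusivities(1.0, 1.5 * dc)
            km, kp = wavenumber_band(j, d)
            inside = np.sqrt(np.linspace(km**2 * 1.01, kp**2 * 0.99, 9))
            outside = np.array([km * 0.9, kp * 1.1])
            lam_in, _ = dispersion(j, d, inside)
            lam_out, _ = dispersion(j, d, outside)
            assert (lam_in > 0).all()
            assert (lam_out < 0).all()

    def test_spatial_trace_never_exceeds_kinetic_trace(self):
        d = Diffusivities(0.5, 7.0)
        k_grid = np.logspace(-3, 2, 20)
        for row in _random_jacobians(100, seed=9):
            j = JacobianSummary(*row)
            k2 = k_grid**2
            tr_k = (j.j11 - d.du * k2) + (j.j22 - d.dv * k2)
            assert (tr_k <= j.trace + 1e-12).all()


class TestTuringReport:
    def scheme_Ia(self, rho=1.2):
        return ReactionScheme((Reaction(2, 0, 4, 3, 1.0), Reaction(1, 1, 0, 0, rho),
                               Reaction(0, 0, 1, 0, 1.0)))

    def test_full_pipeline_on_capable_scheme(self):
        k = compile_scheme(self.scheme_Ia())
        (rep,) = turing_report(k, Diffusivities(1.0, 15.0))
        assert rep.kinetically_stable
        assert rep.pattern_type == "I"
        assert rep.delta_c == pytest.approx(11.8787753826, rel=1e-9)
        assert rep.k_minus < rep.k_max < rep.k_plus
        assert rep.lambda_max > 0
        assert rep.pattern_predicted

    def test_below_threshold_no_band(self):
        k = compile_scheme(self.scheme_Ia())
        (rep,) = turing_report(k, Diffusivities(1.0, 10.0))
        assert rep.turing_capable and not rep.pattern_predicted

    def test_missing_autocatalysis_never_patterns(self):
        # without a 2U reaction increasing U, a4 <= 0 and J11 cannot be
        # positive: no steady state can be Turing-capable
        s = ReactionScheme((Reaction(2, 0, 1, 1, 1.0), Reaction(1, 1, 0, 0, 1.0),
                            Reaction(0, 0, 2, 1, 1.0)))
        for rep in turing_report(compile_scheme(s)):
            assert rep.pattern_type == "none"

    def test_relabelling_involution(self):
        s = self.scheme_Ia()
        k = compile_scheme(s)
        km = compile_scheme(s.mirrored())
        (rep,) = turing_report(k)
        (repm,) = turing_report(km)
        assert rep.pattern_type == repm.pattern_type == "I"
        assert repm.delta_c == pytest.approx(rep.delta_c, rel=1e-9)
        assert repm.steady_state.u_star == pytest.approx(rep.steady_state.v_star)
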