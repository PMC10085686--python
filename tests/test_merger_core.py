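"""Unit and property tests for the core circuit model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mergenet.errors import (
    ConvergenceError,
    DomainError,
    InvalidParameterError,
    InvalidStateError,
)
from mergenet.merger_core import (
    FULL_SPECIES,
    MERGER_SPECIES,
    AssumptionReport,
    FullCircuitParams,
    InducerPair,
    MergerParams,
    SteadyStateResult,
    broken_merging_output,
    check_assumptions,
    free_ribosomes,
    full_model_output,
    full_rhs,
    merger_rhs,
    michaelis_constant,
    reduced_merger_output,
    sensitivity_constant,
    solve_full_steady_state,
    solve_merger_steady_state,
    solve_steady_state,
)
from mergenet import presets

positive = st.floats(min_value=1e-3, max_value=1e3)


def make_merger(**kw) -> MergerParams:
    base = dict(k_X=1.0, k_Y=1.0, a=1.0, b=1.0, k=1.0, gamma=1.0, P_XT=1.0)
    base.update(kw)
    return MergerParams(**base)


def converged_result(P_X=1.0, P_Y=1.0, C=0.0) -> SteadyStateResult:
    return SteadyStateResult(values=np.array([P_X, P_Y, C]),
                             names=MERGER_SPECIES, converged=True,
                             residual_norm=0.0, method="root", tolerance=1e-9)


class TestMichaelisConstant:
    def test_direct_evaluation(self):
        assert michaelis_constant(a=1, b=0, k=0, gamma=1) == 1.0
        assert michaelis_constant(a=2, b=1, k=2, gamma=1) == 2.0

    def test_halving_association_doubles_constant(self):
        k1 = michaelis_constant(a=4.0, b=2.0, k=3.0, gamma=1.0)
        k2 = michaelis_constant(a=2.0, b=2.0, k=3.0, gamma=1.0)
        assert k2 == pytest.approx(2.0 * k1)

    def test_nonpositive_association_rejected(self):
        with pytest.raises(InvalidParameterError):
            michaelis_constant(a=0.0, b=1.0, k=1.0, gamma=1.0)
        with pytest.raises(InvalidParameterError):
            michaelis_constant(a=-1.0, b=1.0, k=1.0, gamma=1.0)


class TestSensitivityConstant:
    def test_direct_evaluation(self):
        # K = (0 + 9 + 1)/10 = 1, c = 1*10*1/(10*1) = 1
        p = make_merger(gamma=1.0, k_Y=10.0, a=10.0, b=1e-12, k=9.0, k_X=1.0)
        assert sensitivity_constant(p) == pytest.approx(1.0, rel=1e-9)

    def test_linear_in_k_Y(self):
        p = make_merger(k_Y=2.0)
        p2 = make_merger(k_Y=4.0)
        assert sensitivity_constant(p2) == pytest.approx(
            2.0 * sensitivity_constant(p))

    @given(k_X=positive, k_Y=positive, a=positive, b=positive, k=positive,
           gamma=positive)
    def test_matches_independent_rederivation(self, k_X, k_Y, a, b, k, gamma):
        p = MergerParams(k_X=k_X, k_Y=k_Y, a=a, b=b, k=k, gamma=gamma, P_XT=1.0)
        K = (b + k + gamma) / a
        expected = gamma * k_Y * K / ((k + gamma) * k_X)
        assert sensitivity_constant(p) == pytest.approx(expected, rel=1e-12)


class TestReducedMergerOutput:
    def test_reference_slope_arithmetic(self):
        out = reduced_merger_output(220428.0, InducerPair(X=100.0, Y=40.0))
        assert out == pytest.approx(88171.2)

    def test_zero_numerator(self):
        assert reduced_merger_output(5.0, InducerPair(X=10.0, Y=0.0)) == 0.0

    def test_direct_product(self):
        assert reduced_merger_output(2.0, InducerPair(X=1.5, Y=3.0)) == pytest.approx(4.0)

    def test_zero_X_is_domain_error(self):
        with pytest.raises(DomainError):
            reduced_merger_output(1.0, InducerPair(X=0.0, Y=1.0))

    @given(c=positive, x=positive, y=positive, alpha=positive)
    def test_exact_ratio_invariance(self, c, x, y, alpha):
        base = reduced_merger_output(c, InducerPair(x, y))
        scaled = reduced_merger_output(c, InducerPair(alpha * x, alpha * y))
        assert scaled == pytest.approx(base, rel=1e-12)


class TestMergerRhs:
    def test_all_zero_fixed_point(self):
        p = make_merger()
        d = merger_rhs(np.zeros(3), p, InducerPair(0.0, 0.0), R=1.0)
        assert np.all(d == 0.0)

    @given(P_X=positive, P_Y=positive, C=positive, a=positive, b=positive,
           k=positive)
    @settings(max_examples=50)
    def test_protease_sum_rule(self, P_X, P_Y, C, a, b, k):
        # d(P_X + C)/dt = k_X*X*R - gamma*(P_X + C), independent of a, b, k
        u = InducerPair(X=2.0, Y=3.0)
        R = 1.5
        p = make_merger(a=a, b=b, k=k)
        d = merger_rhs([P_X, P_Y, C], p, u, R)
        expected = p.k_X * u.X * R - p.gamma * (P_X + C)
        assert d[0] + d[2] == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_negative_state_rejected(self):
        with pytest.raises(InvalidStateError):
            merger_rhs([-0.1, 0.0, 0.0], make_merger(), InducerPair(1, 1), 1.0)

    def test_zero_derivative_at_solver_steady_state(self):
        p = make_merger()
        u = InducerPair(X=2.0, Y=3.0)
        ss = solve_merger_steady_state(p, u, R=1.0, check_uniqueness=False)
        assert ss.converged
        d = merger_rhs(ss.values, p, u, R=1.0)
        assert np.max(np.abs(d)) <= ss.tolerance


class TestSolveSteadyState:
    def test_birth_death_closed_form(self):
        ss = solve_steady_state(lambda y: np.array([2.0 - y[0]]), [0.0])
        assert ss.converged
        assert ss.values[0] == pytest.approx(2.0, abs=1e-8)

    def test_no_production_gives_zero_output(self):
        p = make_merger(k_Y=0.0)
        ss = solve_merger_steady_state(p, InducerPair(2.0, 3.0), R=1.0)
        assert ss.converged
        assert ss["P_Y"] == pytest.approx(0.0, abs=1e-8)

    def test_against_algebraic_quadratic_oracle(self):
        # At steady state P_Y solves
        #   gamma*P_Y^2 + (gamma*K + (k+gamma)*P_XT - beta_Y)*P_Y - beta_Y*K = 0
        # with P_XT = k_X*X*R/gamma and beta_Y = k_Y*Y*R.
        p = make_merger(k_X=0.5, k_Y=2.0, a=30.0, b=5.0, k=40.0, gamma=1.0)
        u = InducerPair(X=4.0, Y=1.5)
        R = 2.0
        K = p.K
        P_XT = p.k_X * u.X * R / p.gamma
        beta_Y = p.k_Y * u.Y * R
        roots = np.roots([p.gamma,
                          p.gamma * K + (p.k + p.gamma) * P_XT - beta_Y,
                          -beta_Y * K])
        P_Y_expected = float(max(roots))
        assert P_Y_expected > 0
        ss = solve_merger_steady_state(p, u, R=R)
        assert ss.converged
        assert ss["P_Y"] == pytest.approx(P_Y_expected, rel=1e-6)
        C_expected = P_XT * P_Y_expected / (K + P_Y_expected)
        assert ss["C"] == pytest.approx(C_expected, rel=1e-6)
        assert ss["P_X"] == pytest.approx(P_XT - C_expected, rel=1e-6)

    def test_unique_from_distinct_initializations(self):
        p = make_merger()
        ss = solve_merger_steady_state(p, InducerPair(1.0, 2.0), R=1.0,
                                       check_uniqueness=True)
        assert ss.converged
        assert ss.uniqueness_gap <= 10 * ss.tolerance

    def test_nonconvergence_is_reported_not_silent(self):
        ss = solve_steady_state(lambda y: np.array([1.0]), [0.0], t_max=5.0)
        assert not ss.converged
        assert ss.residual_norm > 0

    def test_negative_init_rejected(self):
        with pytest.raises(InvalidStateError):
            solve_steady_state(lambda y: -y, [-1.0])


class TestBrokenMergingOutput:
    AMP = dict(k6=300.0, R_tot=10.0, gamma=1.0)

    def test_zero_Y_T(self):
        assert broken_merging_output(**self.AMP, c1=0.1, c2=0.2,
                                     X_T=5.0, Y_T=0.0) == 0.0

    def test_saturation_limit(self):
        limit = self.AMP["k6"] * self.AMP["R_tot"] / self.AMP["gamma"]
        out = broken_merging_output(**self.AMP, c1=0.1, c2=1.0,
                                    X_T=0.0, Y_T=1e12)
        assert out == pytest.approx(limit, rel=1e-9)

    def test_proportional_to_R_tot(self):
        kw = dict(k6=300.0, gamma=1.0, c1=0.03, c2=0.2, X_T=3.0, Y_T=7.0)
        full = broken_merging_output(R_tot=10.0, **kw)
        half = broken_merging_output(R_tot=5.0, **kw)
        assert half == pytest.approx(full / 2.0, rel=1e-12)

    @given(y1=positive, y2=positive)
    def test_monotone_in_Y_T(self, y1, y2):
        lo, hi = sorted([y1, y2])
        if hi - lo < 1e-9:
            return
        f = lambda y: broken_merging_output(**self.AMP, c1=0.1, c2=0.5,
                                            X_T=2.0, Y_T=y)
        assert f(lo) < f(hi)

    @given(x1=positive, x2=positive)
    def test_decreasing_in_X_T(self, x1, x2):
        lo, hi = sorted([x1, x2])
        if hi - lo < 1e-9:
            return
        f = lambda x: broken_merging_output(**self.AMP, c1=0.1, c2=0.5,
                                            X_T=x, Y_T=2.0)
        assert f(lo) > f(hi)


class TestCheckAssumptions:
    def test_first_order_margin(self):
        p = make_merger(a=1.0, b=0.0, k=0.0, gamma=1.0)  # K = 1
        ss = converged_result(P_Y=p.K / 100.0)
        report = check_assumptions(p, ss, strictness=0.1)
        assert report.a1_pass
        assert report.a1_margin == pytest.approx(0.01)

    def test_dilution_boundary_fails(self):
        # gamma exactly equals P_XT*(k+gamma)/K  -> margin 1
        p = make_merger(a=2.0, b=2.0, k=1.0, gamma=1.0, P_XT=1.0)  # K = 2
        assert p.gamma == pytest.approx(p.P_XT * (p.k + p.gamma) / p.K)
        report = check_assumptions(p, converged_result(P_Y=1e-6), strictness=0.5)
        assert not report.a2_pass
        assert report.a2_margin == pytest.approx(1.0)

    def test_unconverged_state_rejected(self):
        bad = SteadyStateResult(values=np.ones(3), names=MERGER_SPECIES,
                                converged=False, residual_norm=1.0,
                                method="integration", tolerance=1e-9)
        with pytest.raises(ConvergenceError):
            check_assumptions(make_merger(), bad)

    def test_violating_fast_degradation_worsens_reduced_agreement(self):
        # Paired simulation: with K held fixed, a weak protease (small k)
        # breaks the fast-degradation condition and the closed form drifts
        # from the ODE steady state.
        u = InducerPair(X=2.0, Y=1.0)
        R = 1.0

        def disagreement(k, a):
            p = make_merger(k_X=0.05, k_Y=1.0, a=a, b=1.0, k=k)
            ss = solve_merger_steady_state(p, u, R=R, check_uniqueness=False)
            reduced = sensitivity_constant(p) * u.Y / u.X
            return abs(ss["P_Y"] - reduced) / reduced

        K = (1.0 + 50.0 + 1.0) / 20.0  # keep K fixed between the two runs
        good = disagreement(k=50.0, a=(1.0 + 50.0 + 1.0) / K)
        bad = disagreement(k=0.5, a=(1.0 + 0.5 + 1.0) / K)
        assert bad > good


class TestFullModel:
    def test_zero_dna_copies_silences_output(self):
        from dataclasses import replace

        p = presets.reference_full_params()
        p = replace(p,
                    sensor_X=replace(p.sensor_X, dna_copies=0.0),
                    sensor_Y=replace(p.sensor_Y, dna_copies=0.0))
        ss = solve_full_steady_state(p, InducerPair(100.0, 40.0),
                                     check_uniqueness=False)
        assert ss.converged
        assert ss["P_Y"] == pytest.approx(0.0, abs=1e-9)
        assert ss["m_X"] == pytest.approx(0.0, abs=1e-9)

    def test_ribosome_conservation_along_trajectory(self, ref_full_comp):
        # Free ribosomes are defined by conservation, so free + bound is
        # identically R_tot at any state, including transient ones.
        rng = np.random.default_rng(0)
        for _ in range(5):
            state = rng.uniform(0.0, 0.5, size=9)
            full_rhs(state, ref_full_comp, InducerPair(100.0, 40.0), aTc=20.0)
            total = free_ribosomes(state, ref_full_comp) + state[3] + state[4] + state[5]
            assert total == pytest.approx(ref_full_comp.R_tot, rel=1e-15)

    def test_steady_state_matches_reduced_law_within_5pct(self, ref_full,
                                                          ref_lumped,
                                                          ref_slope_uM):
        report = check_assumptions(ref_lumped,
                                   solve_full_steady_state(
                                       ref_full, presets.OPERATING_POINT,
                                       check_uniqueness=False),
                                   strictness=0.1)
        assert report.all_pass
        for X in (50.0, 100.0, 400.0):
            for Y in (5.0, 20.0, 50.0):
                u = InducerPair(X, Y)
                full = full_model_output(ref_full, u, calibrated=False)
                reduced = reduced_merger_output(ref_slope_uM, u)
                assert full == pytest.approx(reduced, rel=0.05)

    def test_resource_sensitivity_attenuated(self, ref_full):
        u = presets.OPERATING_POINT
        nominal = full_model_output(ref_full, u, calibrated=False)
        perturbed = full_model_output(ref_full, u, resource_scale=0.5,
                                      calibrated=False)
        assert abs(perturbed - nominal) / nominal <= 0.1

    def test_full_ratio_invariance_within_10pct(self, ref_full):
        outs = [full_model_output(ref_full, InducerPair(X, 0.4 * X),
                                  calibrated=False)
                for X in (50.0, 75.0, 100.0)]
        mean = np.mean(outs)
        assert max(abs(o - mean) / mean for o in outs) <= 0.10

    def test_species_names_stable(self):
        assert FULL_SPECIES == ("m_X", "m_Y", "m_W", "c_X", "c_Y", "c_W",
                                "P_X", "P_Y", "C")

    def test_with_tir_scale_rescales_K6_inverse(self, ref_full):
        doubled = ref_full.with_tir_scale(2.0)
        assert 1.0 / doubled.K6 == pytest.approx(2.0 / ref_full.K6, rel=1e-12)


def test_inducer_pair_validation():
    with pytest.raises(InvalidParameterError):
        InducerPair(-1.0, 0.0)
    with pytest.raises(DomainError):
        _ = InducerPair(0.0, 1.0).ratio
    assert InducerPair(4.0, 1.0).ratio == 0.25
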