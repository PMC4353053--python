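"""Steady state, characteristic polynomial, Routh-Hurwitz and Turing conditions."""

import math

import numpy as np
import pytest

from bsrd import (CouplingParams, IncompatibleCouplingError, JacobianVariant,
                  KineticParams, RegimePrediction, StateVector, char_poly_coeffs,
                  classify_regime, compatibility_residual, critical_diffusion,
                  full_jacobian, kinetics_jacobian, reference_spec,
                  routh_hurwitz_report, steady_state, turing_conditions)
from bsrd.kinetics import JacobianBlocks

FIVE_TWELFTHS = 5.0 / 12.0
REFERENCE_COUPLING = CouplingParams(alpha1=FIVE_TWELFTHS, beta1=FIVE_TWELFTHS,
                                    alpha2=5.0, kappa2=5.0)


def diag_blocks(d1, d2, d3, d4) -> JacobianBlocks:
    full = np.diag([d1, d2, d3, d4]).astype(float)
    return JacobianBlocks(bulk_block=full[:2, :2], surface_block=full[2:, 2:],
                          full=full, variant=JacobianVariant.PURE_KINETICS,
                          includes_gamma=False)


def random_block_jacobian(rng) -> JacobianBlocks:
    full = np.zeros((4, 4))
    full[:2, :2] = rng.uniform(-3, 3, (2, 2))
    full[2:, 2:] = rng.uniform(-3, 3, (2, 2))
    full[2:, :2] = rng.uniform(-3, 3, (2, 2))
    return JacobianBlocks(bulk_block=full[:2, :2], surface_block=full[2:, 2:],
                          full=full, variant=JacobianVariant.PURE_KINETICS,
                          includes_gamma=True)


class TestSteadyState:
    def test_reference_parameters(self):
        st = steady_state(KineticParams(0.1, 0.9), REFERENCE_COUPLING)
        assert st.as_tuple() == (1.0, 0.9, 1.0, 0.9)

    def test_symmetric_rates(self):
        st = steady_state(KineticParams(1.0, 1.0), CouplingParams())
        assert st.as_tuple() == (2.0, 0.25, 2.0, 0.25)

    def test_incompatible_coupling_raises(self):
        bad = CouplingParams(alpha1=1.0, beta1=0.0, kappa1=1.0, beta2=1.0,
                             alpha2=2.0, kappa2=4.0)  # residual = (0-1)(4-2)-1 = -3
        assert compatibility_residual(bad) != 0.0
        with pytest.raises(IncompatibleCouplingError, match="compatibility"):
            steady_state(KineticParams(0.1, 0.9), bad)

    def test_product_condition_alone_is_not_enough(self):
        """A coupling can satisfy the eliminated product condition while its
        fluxes do not balance at the uniform state; this must be rejected."""
        sneaky = CouplingParams(alpha1=FIVE_TWELFTHS)  # residual is exactly 0
        assert compatibility_residual(sneaky) == 0.0
        with pytest.raises(IncompatibleCouplingError, match="flux"):
            steady_state(KineticParams(0.1, 0.9), sneaky)


@pytest.mark.parametrize("coupling, expected", [
    (REFERENCE_COUPLING, 0.0),
    (CouplingParams(alpha1=2.0, beta1=2.0, kappa2=1.3, alpha2=-4.0, beta2=9.9), 0.0),
    (CouplingParams(alpha1=1.0, beta1=0.0, kappa1=1.0, beta2=1.0, alpha2=2.0,
                    kappa2=3.0), -2.0),
])
def test_compatibility_residual(coupling, expected):
    assert compatibility_residual(coupling) == pytest.approx(expected, abs=1e-15)


class TestCharPoly:
    def test_zero_matrix(self):
        c = char_poly_coeffs(diag_blocks(0, 0, 0, 0))
        assert (c.a1, c.a2, c.a3, c.a4) == (0.0, 0.0, 0.0, 0.0)

    def test_known_diagonal_spectrum(self):
        c = char_poly_coeffs(diag_blocks(-1, -2, -3, -4))
        assert (c.a1, c.a2, c.a3, c.a4) == pytest.approx((10.0, 35.0, 50.0, 24.0))

    def test_reference_constant_coefficient(self):
        spec = reference_spec(1.0, 1.0)
        J = full_jacobian(StateVector(1.0, 0.9, 1.0, 0.9), spec, "pure_kinetics")
        c = char_poly_coeffs(J)
        assert c.a4 == pytest.approx(500.0**4, rel=1e-12)

    def test_matches_numpy_and_block_factorization(self):
        """Coefficients equal those of det(lam I - J) and of the expanded
        product of the two block quadratics."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            J = random_block_jacobian(rng)
            c = char_poly_coeffs(J).as_array()
            assert c == pytest.approx(np.real(np.poly(J.full)), rel=1e-10, abs=1e-10)
            tr_o, det_o = np.trace(J.bulk_block), np.linalg.det(J.bulk_block)
            tr_g, det_g = np.trace(J.surface_block), np.linalg.det(J.surface_block)
            prod = np.polymul([1.0, -tr_o, det_o], [1.0, -tr_g, det_g])
            assert c == pytest.approx(prod, rel=1e-12, abs=1e-12)

    def test_non_block_triangular_rejected(self):
        J = diag_blocks(-1, -2, -3, -4)
        J.full[0, 3] = 1.0
        with pytest.raises(ValueError):
            char_poly_coeffs(J)


class TestRouthHurwitz:
    def test_hurwitz_diagonal_matrix(self):
        rep = routh_hurwitz_report(diag_blocks(-1, -2, -3, -4))
        assert rep.overall
        assert all(c.satisfied for c in rep.conditions)

    def test_reference_full_variant_fails_determinant_product(self):
        spec = reference_spec(1.0, 1.0)
        J = full_jacobian(StateVector(1.0, 0.9, 1.0, 0.9), spec, "full_jacobian")
        rep = routh_hurwitz_report(J)
        assert not rep["coeff4"].satisfied       # DetO * DetG < 0
        assert not rep.overall

    def test_reference_pure_variant_is_stable(self):
        spec = reference_spec(1.0, 1.0)
        J = full_jacobian(StateVector(1.0, 0.9, 1.0, 0.9), spec, "pure_kinetics")
        rep = routh_hurwitz_report(J)
        assert rep.overall
        assert np.max(np.linalg.eigvals(J.full).real) < 0

    def test_degenerate_constant_coefficient_rejected(self):
        with pytest.raises(ValueError, match="a4"):
            routh_hurwitz_report(diag_blocks(-1, 0, -3, -4))

    def test_eigenvalue_oracle(self):
        """Over random block-triangular Jacobians the six conditions hold iff
        every eigenvalue has negative real part."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 300:
            J = random_block_jacobian(rng)
            if abs(np.linalg.det(J.bulk_block) * np.linalg.det(J.surface_block)) < 1e-6:
                continue
            stable = np.max(np.linalg.eigvals(J.full).real) < 0
            assert routh_hurwitz_report(J).overall == stable
            checked += 1


class TestCriticalDiffusion:
    def test_reference_value_is_the_quadratic_root(self):
        jac = kinetics_jacobian(1.0, 0.9)
        d = critical_diffusion(jac)
        expected = np.max(np.roots([0.64, -5.6, 1.0]))
        assert d == pytest.approx(expected, rel=1e-12)
        # the discriminant vanishes at the critical value
        fu, gv, det = 0.8, -1.0, 1.0
        assert (d * fu + gv) ** 2 - 4 * d * det == pytest.approx(0.0, abs=1e-9)

    def test_no_finite_critical_value_for_nonpositive_fu(self):
        jac = np.array([[-0.5, 1.0], [-1.0, -0.2]])
        assert critical_diffusion(jac) == math.inf

    def test_requires_diffusion_free_stability(self):
        with pytest.raises(ValueError):
            critical_diffusion(np.array([[1.0, 0.0], [0.0, 1.0]]))  # trace > 0

    def test_marginal_mode_consistency(self):
        """Slightly below the critical ratio no wavenumber destabilizes the
        surface factor; slightly above, a band with negative Det(M) exists."""
        from bsrd import Mode, mode_growth, Geometry, spec_from_flat
        jac = kinetics_jacobian(1.0, 0.9)
        d_crit = critical_diffusion(jac)
        L = np.linspace(1e-3, 2000.0, 40000)
        for d, expect_unstable in ((d_crit * 0.995, False), (d_crit * 1.005, True)):
            spec = spec_from_flat(dict(a=0.1, b=0.9, gamma_omega=500.0,
                                       gamma_gamma=500.0, d_omega=1.0, d_gamma=d))
            gg = 500.0
            fu, fv = jac[0]
            gu, gv = jac[1]
            det_vals = d * L**2 - gg * (d * fu + gv) * L + gg**2 * (fu * gv - fv * gu)
            assert (det_vals.min() < 0) == expect_unstable


class TestTuringConditions:
    @pytest.mark.parametrize("do, dg, bulk_on, surf_on", [
        (1.0, 1.0, False, False),
        (1.0, 20.0, False, True),
        (20.0, 1.0, True, False),
        (20.0, 20.0, True, True),
    ])
    def test_reference_regimes(self, do, dg, bulk_on, surf_on):
        rep = turing_conditions(reference_spec(do, dg))
        assert rep.bulk_diffusion.can_destabilize == bulk_on
        assert rep.surface_diffusion.can_destabilize == surf_on
        assert rep.ode_conditions.overall  # diffusion-free state is stable
        assert rep.d_crit_bulk == pytest.approx(rep.d_crit_surface)
        assert rep.d_crit_surface == pytest.approx(8.5676, abs=1e-3)

    def test_equal_diffusion_never_destabilizes(self):
        """With d = 1 in both compartments no valid (a, b) destabilizes
        either subsystem when it is stable without diffusion."""
        for a in (0.05, 0.1, 0.5, 1.0):
            for b in (0.5, 0.9, 1.5, 2.5):
                jac = kinetics_jacobian(a + b, b / (a + b) ** 2)
                tr = np.trace(jac)
                det = np.linalg.det(jac)
                if not (tr < 0 and det > 0):
                    continue
                from bsrd import spec_from_flat
                spec = spec_from_flat(dict(a=a, b=b, gamma_omega=500.0,
                                           gamma_gamma=500.0))
                rep = turing_conditions(spec)
                assert not rep.bulk_diffusion.can_destabilize
                assert not rep.surface_diffusion.can_destabilize


@pytest.mark.parametrize("do, dg, expected", [
    (1.0, 1.0, RegimePrediction.NO_PATTERNS),
    (1.0, 20.0, RegimePrediction.SURFACE_ONLY_WITH_BOUNDARY_LAYER),
    (20.0, 1.0, RegimePrediction.BULK_DOMINANT),
    (20.0, 20.0, RegimePrediction.BULK_AND_SURFACE),
])
def test_classify_regime(do, dg, expected):
    assert classify_regime(reference_spec(do, dg)) is expected
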