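"""Steady state, Routh-Hurwitz stability and Turing (diffusion-driven) instability.

The linearized coupled system has a block lower-triangular 4x4 Jacobian, so its
quartic characteristic polynomial factors into the bulk and surface quadratics

    p4(lam) = (lam^2 - TrO*lam + DetO) * (lam^2 - TrG*lam + DetG),

with TrO, DetO (TrG, DetG) the trace/determinant of the bulk (surface) diagonal
block.  The six Routh-Hurwitz conditions expressed in these block invariants are
necessary and sufficient for all four roots to have negative real part.  Turing
instability additionally requires, for the bulk and/or the surface two-species
subsystem, the classical conditions d*f_u + g_v > 0 and
(d*f_u + g_v)^2 - 4*d*(f_u*g_v - f_v*g_u) > 0, which hold exactly when the
diffusion ratio d exceeds a critical value d_crit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .kinetics import JacobianBlocks, JacobianVariant, full_jacobian, kinetics_jacobian
from .params import CouplingParams, KineticParams, ModelSpec, StateVector

#: relative tolerance for strict-sign decisions at condition boundaries
SIGN_RTOL = 1e-12


class IncompatibleCouplingError(ValueError):
    """Coupling coefficients violate the steady-state compatibility condition
    (beta1 - alpha1)*(kappa2 - alpha2) - kappa1*beta2 = 0."""


def compatibility_residual(c: CouplingParams) -> float:
    """Residual of the compatibility condition; zero iff a uniform steady state
    common to bulk and surface exists."""
    return (c.beta1 - c.alpha1) * (c.kappa2 - c.alpha2) - c.kappa1 * c.beta2


def steady_state(k: KineticParams, c: CouplingParams, tol: float = 1e-10) -> StateVector:
    """Unique uniform steady state (a+b, b/(a+b)^2, a+b, b/(a+b)^2).

    Raises :class:`IncompatibleCouplingError` when the compatibility condition
    (beta1 - alpha1)*(kappa2 - alpha2) - kappa1*beta2 = 0 fails, since then no
    uniform state can satisfy both the kinetics and the flux conditions.
    """
    res = compatibility_residual(c)
    scale = 1.0 + max(abs(c.alpha1), abs(c.alpha2), abs(c.beta1),
                      abs(c.beta2), abs(c.kappa1), abs(c.kappa2)) ** 2
    if abs(res) > tol * scale:
        raise IncompatibleCouplingError(
            "coupling coefficients violate the compatibility condition "
            f"(beta1-alpha1)(kappa2-alpha2) - kappa1*beta2 = {res:g} != 0"
        )
    total = k.a + k.b
    if total <= 0:
        raise ValueError("a + b must be positive")
    U, V = total, k.b / total**2
    # the product condition above is only the eliminated necessary condition;
    # a common uniform state additionally needs both fluxes to vanish at it
    h1 = c.alpha1 * U - c.beta1 * U - c.kappa1 * V
    h2 = c.alpha2 * V - c.beta2 * U - c.kappa2 * V
    hscale = 1.0 + max(U, V) * math.sqrt(scale)
    if max(abs(h1), abs(h2)) > tol * hscale:
        raise IncompatibleCouplingError(
            "coupling fluxes do not vanish at the candidate uniform state "
            f"(h1={h1:g}, h2={h2:g}); the compatibility condition "
            "(beta1-alpha1)(kappa2-alpha2) - kappa1*beta2 = 0 is necessary but the "
            "individual flux balances depend on (a, b)"
        )
    return StateVector(u=U, v=V, r=U, s=V)


# ---------------------------------------------------------------------------
# characteristic polynomial and Routh-Hurwitz conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CharPolyCoeffs:
    """Coefficients of lam^4 + a1 lam^3 + a2 lam^2 + a3 lam + a4."""

    a1: float
    a2: float
    a3: float
    a4: float

    def as_array(self) -> np.ndarray:
        return np.array([1.0, self.a1, self.a2, self.a3, self.a4])


@dataclass(frozen=True)
class Condition:
    """One strict-sign condition: ``value`` must satisfy ``relation`` ('>0' or '<0')."""

    label: str
    value: float
    relation: str
    satisfied: bool
    marginal: bool


@dataclass(frozen=True)
class ConditionReport:
    conditions: tuple[Condition, ...]
    overall: bool
    variant: JacobianVariant | None = None

    def __getitem__(self, label: str) -> Condition:
        for cond in self.conditions:
            if cond.label == label:
                return cond
        raise KeyError(label)


def _strict(label: str, value: float, relation: str, scale: float = 1.0) -> Condition:
    """Evaluate a strict inequality with a relative tolerance; values within
    tolerance of zero are 'marginal' and count as not satisfied."""
    thresh = SIGN_RTOL * max(1.0, abs(scale))
    marginal = abs(value) <= thresh
    if relation == ">0":
        sat = value > thresh
    elif relation == "<0":
        sat = value < -thresh
    else:  # pragma: no cover - internal misuse
        raise ValueError(relation)
    return Condition(label=label, value=value, relation=relation,
                     satisfied=sat, marginal=marginal)


def _block_invariants(J: JacobianBlocks):
    tr_o = float(np.trace(J.bulk_block))
    tr_g = float(np.trace(J.surface_block))
    det_o = float(np.linalg.det(J.bulk_block))
    det_g = float(np.linalg.det(J.surface_block))
    return tr_o, tr_g, det_o, det_g


def _require_block_triangular(J: JacobianBlocks) -> None:
    if not np.all(J.full[:2, 2:] == 0.0):
        raise ValueError("Jacobian is not block lower-triangular "
                         "(bulk kinetics must not depend on the surface fields)")


def char_poly_coeffs(J: JacobianBlocks) -> CharPolyCoeffs:
    """Quartic characteristic-polynomial coefficients from the block invariants."""
    _require_block_triangular(J)
    tr_o, tr_g, det_o, det_g = _block_invariants(J)
    return CharPolyCoeffs(
        a1=-(tr_o + tr_g),
        a2=det_o + det_g + tr_o * tr_g,
        a3=-(det_o * tr_g + det_g * tr_o),
        a4=det_o * det_g,
    )


def _routh_hurwitz_conditions(tr_o, tr_g, det_o, det_g, labels) -> tuple[Condition, ...]:
    """The six block-invariant conditions equivalent to Re(lam) < 0 for all roots."""
    tr = tr_o + tr_g
    scale = max(abs(tr_o), abs(tr_g), abs(det_o), abs(det_g), 1.0)
    c1 = _strict(labels[0], tr, "<0", scale)
    c2 = _strict(labels[1], det_o + det_g + tr_o * tr_g, ">0", scale**2)
    c3 = _strict(labels[2], det_o * tr_g + det_g * tr_o, "<0", scale**2)
    c4 = _strict(labels[3], det_o * det_g, ">0", scale**2)
    # c5 is 2*(a1*a2 - a3) and c6 is a3*(a1*a2 - a3) - a1^2*a4, both written in
    # block invariants (expand with a1 = -tr, a3 = -(det_o*tr_g + det_g*tr_o))
    c5 = _strict(labels[4],
                 -(tr_g * tr + 2.0 * det_o) * tr_o - (tr_o * tr + 2.0 * det_g) * tr_g,
                 ">0", scale**2)
    c6 = _strict(labels[5],
                 ((det_o - det_g) ** 2 + (det_o * tr_g + det_g * tr_o) * tr) * tr_o * tr_g,
                 ">0", scale**4)
    return (c1, c2, c3, c4, c5, c6)


#: labels of the six stability conditions, in the order trace, sum, cross, product,
#: first and second Hurwitz-determinant conditions
RH_LABELS = ("trace", "coeff2", "coeff3", "coeff4", "hurwitz2", "hurwitz3")


def routh_hurwitz_report(J: JacobianBlocks) -> ConditionReport:
    """Routh-Hurwitz test on the quartic of a block lower-triangular 4x4 Jacobian.

    ``overall`` is True iff every root of the characteristic polynomial has
    negative real part.  Requires a nondegenerate constant coefficient
    (a4 = DetO*DetG != 0); a zero root makes the quartic test meaningless.
    """
    _require_block_triangular(J)
    tr_o, tr_g, det_o, det_g = _block_invariants(J)
    a4 = det_o * det_g
    scale = max(abs(tr_o), abs(tr_g), abs(det_o), abs(det_g), 1.0)
    if abs(a4) <= SIGN_RTOL * scale**2:
        raise ValueError("degenerate characteristic polynomial: a4 = DetO*DetG = 0 "
                         "(lam = 0 is a root; the quartic Routh-Hurwitz test does not apply)")
    conds = _routh_hurwitz_conditions(tr_o, tr_g, det_o, det_g, RH_LABELS)
    return ConditionReport(conditions=conds, overall=all(c.satisfied for c in conds),
                           variant=J.variant)


# ---------------------------------------------------------------------------
# critical diffusion and Turing conditions
# ---------------------------------------------------------------------------

def critical_diffusion(jac2x2: np.ndarray) -> float:
    """Critical diffusion ratio of a two-species subsystem with Jacobian
    [[f_u, f_v], [g_u, g_v]] at a steady state that is stable without diffusion.

    Returns the larger root d+ of (d*f_u + g_v)^2 = 4*d*Det; for every d > d+
    both Turing conditions d*f_u + g_v > 0 and (d*f_u + g_v)^2 - 4*d*Det > 0
    hold.  Returns +inf when f_u <= 0 (no finite critical value exists).
    """
    jac = np.asarray(jac2x2, dtype=float)
    fu, fv = jac[0]
    gu, gv = jac[1]
    tr = fu + gv
    det = fu * gv - fv * gu
    scale = max(1.0, float(np.abs(jac).max()) ** 2)
    if not (tr < SIGN_RTOL * scale and det > -SIGN_RTOL * scale):
        raise ValueError(
            "critical diffusion requires a diffusion-free stable state "
            f"(trace {tr:g} < 0 and determinant {det:g} > 0)")
    if fu <= 0.0:
        return math.inf
    # (d*fu + gv)^2 - 4*d*det = fu^2 d^2 + (2 fu gv - 4 det) d + gv^2 = 0
    bq = 2.0 * fu * gv - 4.0 * det
    disc = bq * bq - 4.0 * fu * fu * gv * gv
    if disc < 0:  # pragma: no cover - impossible for det > 0, fu > 0
        raise ValueError("marginal-stability quadratic has no real root")
    return (-bq + math.sqrt(disc)) / (2.0 * fu * fu)


class RegimePrediction(str, Enum):
    """Which compartments the linear theory predicts to pattern."""

    NO_PATTERNS = "no_patterns"
    SURFACE_ONLY_WITH_BOUNDARY_LAYER = "surface_only_with_boundary_layer"
    BULK_DOMINANT = "bulk_dominant"
    BULK_AND_SURFACE = "bulk_and_surface"


@dataclass(frozen=True)
class DiffusionConditions:
    """The two classical Turing inequalities for one compartment, gamma-free."""

    trace_condition: Condition       # d*f_u + g_v > 0
    discriminant_condition: Condition  # (d*f_u + g_v)^2 - 4*d*Det > 0
    d: float
    d_crit: float

    @property
    def can_destabilize(self) -> bool:
        return self.trace_condition.satisfied and self.discriminant_condition.satisfied


@dataclass(frozen=True)
class TuringReport:
    """Necessary conditions for diffusion-driven instability of the coupled system."""

    ode_conditions: ConditionReport
    bulk_diffusion: DiffusionConditions
    surface_diffusion: DiffusionConditions
    variant: JacobianVariant
    steady: StateVector

    @property
    def d_crit_bulk(self) -> float:
        return self.bulk_diffusion.d_crit

    @property
    def d_crit_surface(self) -> float:
        return self.surface_diffusion.d_crit

    @property
    def necessary_conditions_met(self) -> bool:
        return self.ode_conditions.overall and (
            self.bulk_diffusion.can_destabilize or self.surface_diffusion.can_destabilize)


def _diffusion_conditions(jac: np.ndarray, d: float, prefix: str) -> DiffusionConditions:
    fu, fv = jac[0]
    gu, gv = jac[1]
    det = fu * gv - fv * gu
    lhs1 = d * fu + gv
    lhs2 = lhs1 * lhs1 - 4.0 * d * det
    scale = max(1.0, d * float(np.abs(jac).max())) ** 2
    tr_cond = _strict(f"{prefix}_trace", lhs1, ">0", scale)
    disc_cond = _strict(f"{prefix}_discriminant", lhs2, ">0", scale)
    tr = fu + gv
    d_crit = critical_diffusion(jac) if (tr < 0 and det > 0) else math.nan
    return DiffusionConditions(trace_condition=tr_cond, discriminant_condition=disc_cond,
                               d=d, d_crit=d_crit)


def turing_conditions(
    spec: ModelSpec,
    variant: JacobianVariant | str = JacobianVariant.PURE_KINETICS,
) -> TuringReport:
    """Evaluate the necessary conditions for diffusion-driven instability.

    The six diffusion-free conditions are evaluated on the gamma-scaled 4x4
    Jacobian of the requested variant; the per-compartment diffusion conditions
    are always evaluated gamma-free with pure reaction partials (they are
    invariant under the gamma scaling).
    """
    variant = JacobianVariant(variant)
    st = steady_state(spec.kinetics, spec.coupling)
    J = full_jacobian(st, spec, variant)
    tr_o, tr_g, det_o, det_g = _block_invariants(J)
    labels = tuple(f"ode_{lab}" for lab in RH_LABELS)
    ode_conds = _routh_hurwitz_conditions(tr_o, tr_g, det_o, det_g, labels)
    ode = ConditionReport(conditions=ode_conds,
                          overall=all(c.satisfied for c in ode_conds),
                          variant=variant)
    jac_bulk = kinetics_jacobian(st.u, st.v)
    jac_surf = kinetics_jacobian(st.r, st.s)
    bulk = _diffusion_conditions(jac_bulk, spec.transport.d_omega, "bulk")
    surf = _diffusion_conditions(jac_surf, spec.transport.d_gamma, "surface")
    return TuringReport(ode_conditions=ode, bulk_diffusion=bulk, surface_diffusion=surf,
                        variant=variant, steady=st)


def classify_regime(spec: ModelSpec) -> RegimePrediction:
    """Map (d_omega vs d_crit_bulk, d_gamma vs d_crit_surface) onto the four
    patterning predictions of the linear theory."""
    report = turing_conditions(spec, JacobianVariant.PURE_KINETICS)
    bulk_on = report.bulk_diffusion.can_destabilize
    surf_on = report.surface_diffusion.can_destabilize
    if bulk_on and surf_on:
        return RegimePrediction.BULK_AND_SURFACE
    if bulk_on:
        return RegimePrediction.BULK_DOMINANT
    if surf_on:
        return RegimePrediction.SURFACE_ONLY_WITH_BOUNDARY_LAYER
    return RegimePrediction.NO_PATTERNS
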