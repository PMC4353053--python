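"""Reaction kinetics, Robin coupling fluxes and Jacobians.

Bulk and surface both carry activator-depleted kinetics

    f(u, v) = a - u + u^2 v,      g(u, v) = b - u^2 v,

and the surface kinetics are augmented by the (linear) coupling fluxes,

    f3 = gamma_Gamma * (f(r, s) - h1),   f4 = gamma_Gamma * (g(r, s) - h2).

Because f1, f2 do not depend on (r, s), the 4x4 Jacobian of (f1, f2, f3, f4)
is block lower-triangular; the linear stability theory exploits this.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .params import CouplingParams, KineticParams, ModelSpec, StateVector


class JacobianVariant(str, Enum):
    """Which surface diagonal block the 4x4 Jacobian carries.

    ``FULL`` is the literal linearization of the augmented surface kinetics
    (its surface block includes the -alpha1, -alpha2 coupling terms).
    ``PURE_KINETICS`` drops the coupling from the diagonal surface block and
    keeps only the reaction partials; the Turing conditions and the per-mode
    dispersion matrix are stated with this block.
    """

    FULL = "full_jacobian"
    PURE_KINETICS = "pure_kinetics"


@dataclass(frozen=True)
class JacobianBlocks:
    """4x4 Jacobian of the augmented kinetics together with its diagonal blocks."""

    bulk_block: np.ndarray     # 2x2, d(f1,f2)/d(u,v)
    surface_block: np.ndarray  # 2x2, d(f3,f4)/d(r,s) per the chosen variant
    full: np.ndarray           # 4x4 block lower-triangular matrix
    variant: JacobianVariant
    includes_gamma: bool


def eval_bulk_kinetics(u, v, p: KineticParams):
    """Activator-depleted reaction rates (f, g) = (a - u + u^2 v, b - u^2 v)."""
    u2v = u * u * v
    return p.a - u + u2v, p.b - u2v


def eval_coupling(state: StateVector, c: CouplingParams):
    """Linear Robin coupling fluxes (h1, h2)."""
    h1 = c.alpha1 * state.r - c.beta1 * state.u - c.kappa1 * state.v
    h2 = c.alpha2 * state.s - c.beta2 * state.u - c.kappa2 * state.v
    return h1, h2


def eval_surface_kinetics(state: StateVector, spec: ModelSpec):
    """Augmented surface kinetics (f3, f4) = gamma_Gamma * (f(r,s) - h1, g(r,s) - h2)."""
    gg = spec.transport.gamma_gamma
    f, g = eval_bulk_kinetics(state.r, state.s, spec.kinetics)
    h1, h2 = eval_coupling(state, spec.coupling)
    return gg * (f - h1), gg * (g - h2)


def kinetics_jacobian(u: float, v: float) -> np.ndarray:
    """2x2 matrix of reaction partials [[f_u, f_v], [g_u, g_v]] (no gamma factor)."""
    return np.array([[-1.0 + 2.0 * u * v, u * u],
                     [-2.0 * u * v, -u * u]])


def full_jacobian(
    state: StateVector,
    spec: ModelSpec,
    variant: JacobianVariant | str = JacobianVariant.FULL,
) -> JacobianBlocks:
    """4x4 Jacobian of the augmented kinetics (f1..f4) at ``state``.

    Bulk rows are gamma_Omega times the reaction partials and do not depend on
    (r, s).  The lower-left 2x2 block holds -gamma_Gamma times the (u, v)
    partials of the coupling fluxes.  The surface diagonal block depends on the
    variant (see :class:`JacobianVariant`).
    """
    variant = JacobianVariant(variant)
    go = spec.transport.gamma_omega
    gg = spec.transport.gamma_gamma
    c = spec.coupling

    jb = go * kinetics_jacobian(state.u, state.v)
    js_kin = kinetics_jacobian(state.r, state.s)
    if variant is JacobianVariant.FULL:
        js = gg * (js_kin - np.array([[c.alpha1, 0.0], [0.0, c.alpha2]]))
    else:
        js = gg * js_kin

    # h1_u = -beta1, h1_v = -kappa1, h2_u = -beta2, h2_v = -kappa2
    lower_left = gg * np.array([[c.beta1, c.kappa1], [c.beta2, c.kappa2]])

    full = np.zeros((4, 4))
    full[:2, :2] = jb
    full[2:, :2] = lower_left
    full[2:, 2:] = js
    return JacobianBlocks(bulk_block=jb, surface_block=js, full=full,
                          variant=variant, includes_gamma=True)
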