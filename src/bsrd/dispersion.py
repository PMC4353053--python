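"""Per-mode dispersion relation of the coupled bulk-surface system.

On the unit ball (or disk) the linearized perturbation separates into surface
harmonics Y_lm (resp. cos/sin of m*theta) times radial profiles psi(rho).  Each
mode yields a 4x4 matrix M whose block lower-triangular structure factors the
quartic dispersion relation into a bulk and a surface quadratic,

    lam^2 + Tr(M)_O lam + Det(M)_O = 0,   lam^2 + Tr(M)_G lam + Det(M)_G = 0,

so the growth rates of bulk and surface perturbations decouple: the radial
trace psi'(1) couples bulk into surface but never shifts the eigenvalues.

On the ball the surface Laplace-Beltrami eigenvalue is L = l(l+1) and, for unit
radius, the bulk radial eigenvalue is taken as k^2 = L (k^2 = m^2 on the disk,
whose boundary circle has eigenvalues m^2).  A free k^2 override is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import special

from .kinetics import kinetics_jacobian
from .params import ModelSpec
from .stability import steady_state


class Geometry(str, Enum):
    BALL = "ball"
    DISK = "disk"


@dataclass(frozen=True)
class Mode:
    """One spatial mode: harmonic index l (azimuthal m on the disk), degeneracy
    index m (irrelevant for growth rates), surface eigenvalue and bulk k^2."""

    l: int
    geometry: Geometry = Geometry.BALL
    m: int = 0
    k_squared: float | None = None

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("harmonic index l must be nonnegative")
        if abs(self.m) > self.l:
            raise ValueError("degeneracy index must satisfy |m| <= l")

    @property
    def surface_eigenvalue(self) -> float:
        if self.geometry is Geometry.BALL:
            return float(self.l * (self.l + 1))
        return float(self.l * self.l)

    @property
    def bulk_eigenvalue(self) -> float:
        """k^2; defaults to the surface eigenvalue (unit-radius convention)."""
        return self.surface_eigenvalue if self.k_squared is None else self.k_squared


@dataclass(frozen=True)
class RadialEigenfunction:
    """Radial factor psi of a bulk eigenmode, normalized so psi(1) = 1."""

    psi_at_1: float
    dpsi_at_1: float
    geometry: Geometry
    k: float

    def __call__(self, rho):
        """Evaluate psi on radii rho in [0, 1]."""
        rho = np.asarray(rho, dtype=float)
        if self.k == 0.0:
            return np.ones_like(rho)
        if self.geometry is Geometry.BALL:
            l = _index_from_k(self.k, self.geometry)
            return special.spherical_jn(l, self.k * rho) / special.spherical_jn(l, self.k)
        m = _index_from_k(self.k, self.geometry)
        return special.jv(m, self.k * rho) / special.jv(m, self.k)


def _index_from_k(k: float, geometry: Geometry) -> int:
    if geometry is Geometry.BALL:
        # k = sqrt(l(l+1))  =>  l = (-1 + sqrt(1 + 4k^2)) / 2
        return round((-1.0 + math.sqrt(1.0 + 4.0 * k * k)) / 2.0)
    return round(k)


def radial_trace(l: int, geometry: Geometry | str = Geometry.BALL) -> RadialEigenfunction:
    """Radial eigenfunction trace data at the boundary for harmonic index l.

    Ball: psi(rho) = j_l(k rho)/j_l(k) with k = sqrt(l(l+1)); disk:
    psi(rho) = J_m(k rho)/J_m(k) with k = m.  Raises when the normalizing
    Bessel value is (near) zero.
    """
    geometry = Geometry(geometry)
    if l < 0:
        raise ValueError("l must be nonnegative")
    if l == 0:
        return RadialEigenfunction(psi_at_1=1.0, dpsi_at_1=0.0, geometry=geometry, k=0.0)
    if geometry is Geometry.BALL:
        k = math.sqrt(l * (l + 1.0))
        val = special.spherical_jn(l, k)
        der = special.spherical_jn(l, k, derivative=True)
    else:
        k = float(l)
        val = special.jv(l, k)
        der = special.jvp(l, k)
    if abs(val) < 1e-12:
        raise ValueError(f"degenerate normalization: radial eigenfunction vanishes at "
                         f"the boundary for l={l} ({geometry.value})")
    return RadialEigenfunction(psi_at_1=1.0, dpsi_at_1=k * der / val,
                               geometry=geometry, k=k)


@dataclass(frozen=True)
class DispersionMatrix:
    """The per-mode 4x4 matrix M; eigenvalue problem (lam I + M) xi = 0."""

    M: np.ndarray
    mode: Mode


class GrowthSource(str, Enum):
    BULK_FACTOR = "bulk_factor"
    SURFACE_FACTOR = "surface_factor"
    BOTH = "both"


@dataclass(frozen=True)
class ModeGrowth:
    """Growth data of one mode: the four roots of the factored dispersion relation."""

    mode: Mode
    bulk_roots: tuple[complex, complex]
    surface_roots: tuple[complex, complex]
    tr_bulk: float
    det_bulk: float
    tr_surface: float
    det_surface: float

    @property
    def roots(self) -> tuple[complex, complex, complex, complex]:
        return self.bulk_roots + self.surface_roots

    @property
    def max_re(self) -> float:
        return max(z.real for z in self.roots)

    @property
    def max_re_bulk(self) -> float:
        return max(z.real for z in self.bulk_roots)

    @property
    def max_re_surface(self) -> float:
        return max(z.real for z in self.surface_roots)

    @property
    def unstable(self) -> bool:
        return self.max_re > 0.0

    @property
    def source(self) -> GrowthSource:
        if math.isclose(self.max_re_bulk, self.max_re_surface,
                        rel_tol=1e-12, abs_tol=1e-12):
            return GrowthSource.BOTH
        if self.max_re_bulk > self.max_re_surface:
            return GrowthSource.BULK_FACTOR
        return GrowthSource.SURFACE_FACTOR


def build_mode_matrix(spec: ModelSpec, mode: Mode) -> DispersionMatrix:
    """Assemble the per-mode matrix M with pure reaction partials at the steady state."""
    st = steady_state(spec.kinetics, spec.coupling)
    (fu, fv), (gu, gv) = kinetics_jacobian(st.u, st.v)
    (fr, fs), (gr, gs) = kinetics_jacobian(st.r, st.s)
    go, gg = spec.transport.gamma_omega, spec.transport.gamma_gamma
    do, dg = spec.transport.d_omega, spec.transport.d_gamma
    k2 = mode.bulk_eigenvalue
    L = mode.surface_eigenvalue
    dpsi = radial_trace(mode.l, mode.geometry).dpsi_at_1
    M = np.array([
        [k2 - go * fu, -go * fv, 0.0, 0.0],
        [-go * gu, do * k2 - go * gv, 0.0, 0.0],
        [dpsi, 0.0, L - gg * fr, -gg * fs],
        [0.0, do * dpsi, -gg * gr, dg * L - gg * gs],
    ])
    return DispersionMatrix(M=M, mode=mode)


def _quadratic_roots(tr: float, det: float) -> tuple[complex, complex]:
    """Roots of lam^2 + tr*lam + det = 0."""
    disc = complex(tr * tr - 4.0 * det) ** 0.5
    return ((-tr + disc) / 2.0, (-tr - disc) / 2.0)


def mode_growth(spec: ModelSpec, mode: Mode) -> ModeGrowth:
    """Growth rates of one mode from the factored dispersion relation.

    The roots coincide with the eigenvalues of -M: the psi'(1) coupling enters
    only the lower-left block of M and cannot shift eigenvalues.
    """
    st = steady_state(spec.kinetics, spec.coupling)
    (fu, fv), (gu, gv) = kinetics_jacobian(st.u, st.v)
    (fr, fs), (gr, gs) = kinetics_jacobian(st.r, st.s)
    go, gg = spec.transport.gamma_omega, spec.transport.gamma_gamma
    do, dg = spec.transport.d_omega, spec.transport.d_gamma
    k2 = mode.bulk_eigenvalue
    L = mode.surface_eigenvalue
    tr_b = (do + 1.0) * k2 - go * (fu + gv)
    det_b = do * k2 * k2 - go * (do * fu + gv) * k2 + go * go * (fu * gv - fv * gu)
    tr_s = (dg + 1.0) * L - gg * (fr + gs)
    det_s = dg * L * L - gg * (dg * fr + gs) * L + gg * gg * (fr * gs - fs * gr)
    return ModeGrowth(mode=mode,
                      bulk_roots=_quadratic_roots(tr_b, det_b),
                      surface_roots=_quadratic_roots(tr_s, det_s),
                      tr_bulk=tr_b, det_bulk=det_b,
                      tr_surface=tr_s, det_surface=det_s)


@dataclass(frozen=True)
class ModeScan:
    """Growth data for l = 0..l_max with unstable-index summaries."""

    growths: tuple[ModeGrowth, ...]

    @property
    def bulk_unstable(self) -> tuple[int, ...]:
        return tuple(g.mode.l for g in self.growths if g.max_re_bulk > 0.0)

    @property
    def surface_unstable(self) -> tuple[int, ...]:
        return tuple(g.mode.l for g in self.growths if g.max_re_surface > 0.0)

    @property
    def unstable(self) -> tuple[int, ...]:
        return tuple(g.mode.l for g in self.growths if g.unstable)

    def __iter__(self):
        return iter(self.growths)


def mode_scan(spec: ModelSpec, l_max: int = 100,
              geometry: Geometry | str = Geometry.BALL) -> ModeScan:
    """Scan harmonic indices 0..l_max for unstable bulk/surface modes."""
    geometry = Geometry(geometry)
    if l_max < 0:
        raise ValueError("l_max must be nonnegative")
    growths = tuple(mode_growth(spec, Mode(l=l, geometry=geometry))
                    for l in range(l_max + 1))
    return ModeScan(growths=growths)
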