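"""Parameter containers for the coupled bulk-surface reaction-diffusion model.

The model couples an activator-depleted (Brusselator/Schnakenberg-type)
reaction-diffusion system in a volume ("bulk", fields u, v) to a second copy
of the same kinetics on the enclosing closed surface (fields r, s), through
linear Robin-type flux boundary conditions

    du/dnu = gamma_Gamma * h1,    d_Omega * dv/dnu = gamma_Gamma * h2,

with h1 = alpha1*r - beta1*u - kappa1*v and h2 = alpha2*s - beta2*u - kappa2*v.
All parameters are dimensionless.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path


@dataclass(frozen=True)
class KineticParams:
    """Rates of the activator-depleted kinetics f = a - u + u^2 v, g = b - u^2 v."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"kinetic rates must be positive, got a={self.a}, b={self.b}")
        if not (math.isfinite(self.a) and math.isfinite(self.b)):
            raise ValueError("kinetic rates must be finite")


@dataclass(frozen=True)
class CouplingParams:
    """Coefficients of the linear Robin coupling fluxes h1, h2."""

    alpha1: float = 0.0
    alpha2: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    kappa1: float = 0.0
    kappa2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "beta1", "beta2", "kappa1", "kappa2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"coupling coefficient {name} must be finite")


@dataclass(frozen=True)
class TransportParams:
    """Diffusion ratios (d) and length-scale parameters (gamma) in bulk and on surface."""

    d_omega: float = 1.0
    d_gamma: float = 1.0
    gamma_omega: float = 1.0
    gamma_gamma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("d_omega", "d_gamma", "gamma_omega", "gamma_gamma"):
            val = getattr(self, name)
            if not (math.isfinite(val) and val > 0):
                raise ValueError(f"transport parameter {name} must be positive, got {val}")


@dataclass(frozen=True)
class ModelSpec:
    """Complete scalar parameter set of the coupled bulk-surface system."""

    kinetics: KineticParams
    coupling: CouplingParams
    transport: TransportParams


@dataclass(frozen=True)
class StateVector:
    """Spatially uniform state (u, v, r, s) of the four species."""

    u: float
    v: float
    r: float
    s: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.u, self.v, self.r, self.s)


_FLAT_KEYS = (
    "a", "b", "gamma_omega", "gamma_gamma", "d_omega", "d_gamma",
    "alpha1", "alpha2", "beta1", "beta2", "kappa1", "kappa2",
)


def spec_from_flat(table: dict) -> ModelSpec:
    """Build a :class:`ModelSpec` from a flat key-value mapping."""
    unknown = set(table) - set(_FLAT_KEYS)
    if unknown:
        raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
    missing = {"a", "b"} - set(table)
    if missing:
        raise KeyError(f"missing required parameter keys: {sorted(missing)}")
    kin = KineticParams(a=float(table["a"]), b=float(table["b"]))
    cpl = CouplingParams(
        alpha1=float(table.get("alpha1", 0.0)),
        alpha2=float(table.get("alpha2", 0.0)),
        beta1=float(table.get("beta1", 0.0)),
        beta2=float(table.get("beta2", 0.0)),
        kappa1=float(table.get("kappa1", 0.0)),
        kappa2=float(table.get("kappa2", 0.0)),
    )
    trn = TransportParams(
        d_omega=float(table.get("d_omega", 1.0)),
        d_gamma=float(table.get("d_gamma", 1.0)),
        gamma_omega=float(table.get("gamma_omega", 1.0)),
        gamma_gamma=float(table.get("gamma_gamma", 1.0)),
    )
    return ModelSpec(kinetics=kin, coupling=cpl, transport=trn)


def spec_to_flat(spec: ModelSpec) -> dict:
    """Inverse of :func:`spec_from_flat`."""
    return {
        "a": spec.kinetics.a,
        "b": spec.kinetics.b,
        "gamma_omega": spec.transport.gamma_omega,
        "gamma_gamma": spec.transport.gamma_gamma,
        "d_omega": spec.transport.d_omega,
        "d_gamma": spec.transport.d_gamma,
        "alpha1": spec.coupling.alpha1,
        "alpha2": spec.coupling.alpha2,
        "beta1": spec.coupling.beta1,
        "beta2": spec.coupling.beta2,
        "kappa1": spec.coupling.kappa1,
        "kappa2": spec.coupling.kappa2,
    }


def load_config(path: str | Path) -> ModelSpec:
    """Read a flat TOML parameter file into a :class:`ModelSpec`."""
    with open(path, "rb") as fh:
        table = tomllib.load(fh)
    return spec_from_flat(table)


def reference_spec(d_omega: float = 1.0, d_gamma: float = 1.0) -> ModelSpec:
    """The packaged reference parameter set (a=0.1, b=0.9, gamma=500, compatible
    coupling alpha1=beta1=5/12, alpha2=kappa2=5, kappa1=beta2=0), with the two
    diffusion ratios free: they select the patterning regime."""
    with resources.files("bsrd.configs").joinpath("reference.toml").open("rb") as fh:
        table = tomllib.load(fh)
    table["d_omega"] = d_omega
    table["d_gamma"] = d_gamma
    return spec_from_flat(table)
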