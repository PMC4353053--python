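"""Shared fixtures: reference parameter sets, session-scoped meshes and the
four-regime simulation runs reused by the FEM, postprocess and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from bsrd import (SimulationConfig, assemble_operators, generate_disk_mesh,
                  generate_ball_mesh, reference_spec, run_simulation, spec_from_flat)

#: diffusion pairs of the four patterning regimes
REGIME_PAIRS = {
    "no_patterns": (1.0, 1.0),
    "surface_only_with_boundary_layer": (1.0, 20.0),
    "bulk_dominant": (20.0, 1.0),
    "bulk_and_surface": (20.0, 20.0),
}

#: seeds per regime; the cheap decaying regime is exercised on more seeds
REGIME_SEEDS = {
    "no_patterns": (11, 12, 13, 14, 15),
    "surface_only_with_boundary_layer": (11, 12, 13),
    "bulk_dominant": (11, 12, 13),
    "bulk_and_surface": (11, 12, 13),
}


@pytest.fixture(scope="session")
def disk_coarse():
    return generate_disk_mesh(0.1)


@pytest.fixture(scope="session")
def disk_fine():
    return generate_disk_mesh(0.05)


@pytest.fixture(scope="session")
def disk_growth():
    """Finer disk used for linear-regime growth-rate measurements."""
    mesh = generate_disk_mesh(0.03)
    return mesh, assemble_operators(mesh)


@pytest.fixture(scope="session")
def ball_mesh():
    return generate_ball_mesh(1)


def uncoupled_spec(d_omega: float, d_gamma: float):
    """Reference kinetics and length scales with zero Robin coupling (the
    compatible configuration in which the factored dispersion relation is
    exact for the continuum problem)."""
    return spec_from_flat(dict(a=0.1, b=0.9, gamma_omega=500.0, gamma_gamma=500.0,
                               d_omega=d_omega, d_gamma=d_gamma))


@pytest.fixture(scope="session")
def theta_order_result():
    """Observed temporal orders of the fractional-theta cycle from a
    dt-refinement study against a fine-dt reference trajectory."""
    import math

    from bsrd import (CoupledSystem, SimulationConfig, ThetaStepper,
                      initial_condition, steady_state)

    spec = reference_spec(1.0, 20.0)
    mesh = generate_disk_mesh(0.35)
    ops = assemble_operators(mesh)
    st = steady_state(spec.kinetics, spec.coupling)
    cfg = SimulationConfig(dt=1e-3, seed=3, ic_amplitude=0.2, newton_tol=1e-12)
    x0 = initial_condition(st, cfg, ops.n_bulk, ops.n_surf).pack()
    system = CoupledSystem(ops, spec)
    T = 0.02

    def integrate(dt):
        stepper = ThetaStepper(system, dt, cfg)
        x = x0.copy()
        for _ in range(int(round(T / dt))):
            x = stepper.step(x)
        return x

    ref = integrate(T / 256)
    errs = [float(np.linalg.norm(integrate(T / n) - ref)) for n in (8, 16, 32)]
    return [math.log2(errs[i] / errs[i + 1]) for i in range(2)]


@pytest.fixture(scope="session")
def regime_runs(disk_fine):
    """Disk simulations of the four regimes: {regime: [summary per seed]}.

    h = 0.05, dt = 1e-4, 1% random initial perturbations; decaying runs stop
    early at the steady detector, patterned runs integrate to saturation.
    """
    runs = {}
    for regime, (do, dg) in REGIME_PAIRS.items():
        spec = reference_spec(do, dg)
        t_end = 0.4 if regime == "no_patterns" else 0.5
        summaries = []
        for seed in REGIME_SEEDS[regime]:
            cfg = SimulationConfig(dt=1e-4, t_end=t_end, seed=seed,
                                   ic_amplitude=0.01, steady_detect_tol=1e-6)
            summaries.append(run_simulation(spec, cfg, disk_fine))
        runs[regime] = summaries
    return runs
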