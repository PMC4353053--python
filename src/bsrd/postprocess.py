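"""Pattern diagnostics and regime verdicts for simulation output.

Quantifies what a run produced — per-field amplitudes, deviation profiles
binned by distance to the surface, the boundary-layer width of surface-driven
bulk patterning, and the phase relation between the two bulk species — and
maps the diagnostics onto the four patterning regimes for comparison with the
linear-theory prediction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dispersion import Geometry, mode_scan
from .fem import Fields, TrajectorySummary
from .mesh import BulkMesh, read_mesh
from .params import ModelSpec, StateVector, spec_from_flat
from .stability import RegimePrediction, classify_regime, steady_state

#: amplitude (max - min) above which a field counts as patterned
PATTERN_THRESHOLD = 0.05
#: distance-to-surface bin width of the radial deviation profile
PROFILE_BIN = 0.05
#: bulk nodes farther than this from the surface count as "interior"
INTERIOR_DEPTH = 0.5


@dataclass
class PatternMetrics:
    """Diagnostics of one final state."""

    amplitude: dict[str, float]          # max - min per field
    l2_deviation: dict[str, float]       # relative L2 deviation from steady state
    pattern_flag: dict[str, bool]
    interior_amplitude: float            # amplitude of u at depth > INTERIOR_DEPTH
    profile_depths: np.ndarray           # bin centres, distance to surface
    profile_values: np.ndarray           # RMS deviation of u per bin
    boundary_layer_width: float
    uv_phase_correlation: float
    threshold: float = PATTERN_THRESHOLD

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "l2_deviation": self.l2_deviation,
            "pattern_flag": self.pattern_flag,
            "interior_amplitude": self.interior_amplitude,
            "boundary_layer_width": self.boundary_layer_width,
            "uv_phase_correlation": self.uv_phase_correlation,
            "threshold": self.threshold,
            "profile_depths": self.profile_depths.tolist(),
            "profile_values": self.profile_values.tolist(),
        }


def _radial_profile(depth: np.ndarray, dev: np.ndarray):
    edges = np.arange(0.0, 1.0 + PROFILE_BIN, PROFILE_BIN)
    centres, values = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (depth >= lo) & (depth < hi)
        if mask.any():
            centres.append(0.5 * (lo + hi))
            values.append(float(np.sqrt(np.mean(dev[mask] ** 2))))
    return np.asarray(centres), np.asarray(values)


def _boundary_layer_width(centres: np.ndarray, values: np.ndarray) -> float:
    """Depth (from the near-surface bin) at which the profile first falls below
    10% of its near-surface value; linear interpolation between bin centres."""
    if len(values) == 0 or values[0] <= 0.0:
        return 0.0
    target = 0.1 * values[0]
    for i in range(1, len(values)):
        if values[i] < target:
            lo_d, hi_d = centres[i - 1], centres[i]
            lo_v, hi_v = values[i - 1], values[i]
            frac = (lo_v - target) / (lo_v - hi_v)
            return float(lo_d + frac * (hi_d - lo_d) - centres[0])
    return 1.0


def compute_metrics(fields: Fields, steady: StateVector, mesh: BulkMesh,
                    threshold: float = PATTERN_THRESHOLD) -> PatternMetrics:
    """Pattern diagnostics of a nodal state relative to the uniform steady state."""
    amps, l2s, flags = {}, {}, {}
    for name, arr, ref in (("u", fields.u, steady.u), ("v", fields.v, steady.v),
                           ("r", fields.r, steady.r), ("s", fields.s, steady.s)):
        amps[name] = float(arr.max() - arr.min())
        l2s[name] = float(np.sqrt(np.mean((arr - ref) ** 2)) / abs(ref))
        flags[name] = amps[name] > threshold
    depth = 1.0 - np.linalg.norm(mesh.points, axis=1)
    dev_u = fields.u - steady.u
    centres, values = _radial_profile(depth, dev_u)
    interior = depth > INTERIOR_DEPTH
    if interior.any():
        interior_amp = float(fields.u[interior].max() - fields.u[interior].min())
    else:
        interior_amp = 0.0
    corr = 0.0
    dv = fields.v - steady.v
    if np.std(dev_u) > 0 and np.std(dv) > 0:
        corr = float(np.corrcoef(dev_u, dv)[0, 1])
    return PatternMetrics(
        amplitude=amps, l2_deviation=l2s, pattern_flag=flags,
        interior_amplitude=interior_amp,
        profile_depths=centres, profile_values=values,
        boundary_layer_width=_boundary_layer_width(centres, values),
        uv_phase_correlation=corr, threshold=threshold)


def regime_verdict(metrics: PatternMetrics,
                   threshold: float | None = None) -> RegimePrediction:
    """Classify a simulated state into the four patterning regimes.

    Surface patterning requires the surface fields themselves to exceed the
    amplitude threshold; bulk patterning requires amplitude in the *interior*
    (depth > 0.5), which separates genuine bulk patterns from the
    boundary layer that surface-driven patterning induces near the surface.
    """
    thr = metrics.threshold if threshold is None else threshold
    surface_on = max(metrics.amplitude["r"], metrics.amplitude["s"]) > thr
    bulk_on = metrics.interior_amplitude > thr
    if bulk_on and surface_on:
        return RegimePrediction.BULK_AND_SURFACE
    if bulk_on:
        return RegimePrediction.BULK_DOMINANT
    if surface_on:
        return RegimePrediction.SURFACE_ONLY_WITH_BOUNDARY_LAYER
    return RegimePrediction.NO_PATTERNS


def summary_verdict(summary: TrajectorySummary, mesh: BulkMesh,
                    threshold: float = PATTERN_THRESHOLD) -> RegimePrediction:
    """Convenience: verdict of a completed run."""
    return regime_verdict(compute_metrics(summary.final, summary.steady, mesh, threshold))


def report(run_dir: str | Path, plots: bool = False) -> dict:
    """Build a machine-readable verdict for a run directory.

    Expects ``run.json``, ``mesh.msh``, ``final_fields.npz`` and
    ``timeseries.csv`` as written by :func:`bsrd.fem.run_simulation`; writes
    ``verdict.json`` (and PNG plots when requested) into the directory and
    returns the verdict dictionary.
    """
    run_dir = Path(run_dir)
    missing = [name for name in ("run.json", "mesh.msh", "final_fields.npz",
                                 "timeseries.csv") if not (run_dir / name).exists()]
    if missing:
        raise FileNotFoundError(f"run directory {run_dir} is missing {missing}")
    with open(run_dir / "run.json") as fh:
        run_meta = json.load(fh)
    spec = spec_from_flat(run_meta["spec"])
    mesh = read_mesh(run_dir / "mesh.msh")
    data = np.load(run_dir / "final_fields.npz")
    fields = Fields(u=data["u"], v=data["v"], r=data["r"], s=data["s"],
                    t=float(data["t"]))
    st = steady_state(spec.kinetics, spec.coupling)
    metrics = compute_metrics(fields, st, mesh)
    predicted = classify_regime(spec)
    simulated = regime_verdict(metrics)
    geometry = Geometry.DISK if mesh.dim == 2 else Geometry.BALL
    scan = mode_scan(spec, l_max=30, geometry=geometry)
    verdict = {
        "predicted_regime": predicted.value,
        "simulated_regime": simulated.value,
        "agreement": predicted == simulated,
        "metrics": metrics.to_dict(),
        "dispersion": {
            "bulk_unstable": list(scan.bulk_unstable),
            "surface_unstable": list(scan.surface_unstable),
            "max_growth_rate": max(g.max_re for g in scan),
        },
        "spec": run_meta["spec"],
        "t_final": fields.t,
    }
    with open(run_dir / "verdict.json", "w") as fh:
        json.dump(verdict, fh, indent=1)
    if plots:
        _write_plots(run_dir, metrics, scan)
    return verdict


def _write_plots(run_dir: Path, metrics: PatternMetrics, scan) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    ls = [g.mode.l for g in scan]
    axes[0].plot(ls, [g.max_re_bulk for g in scan], "o-", label="bulk factor", ms=3)
    axes[0].plot(ls, [g.max_re_surface for g in scan], "s-", label="surface factor", ms=3)
    axes[0].axhline(0.0, color="k", lw=0.6)
    axes[0].set_xlabel("harmonic index l")
    axes[0].set_ylabel("max Re $\\lambda$")
    axes[0].legend()
    ts = pd.read_csv(run_dir / "timeseries.csv")
    for name in ("u", "r"):
        axes[1].semilogy(ts["t"], ts[f"amp_{name}"].clip(lower=1e-16), label=name)
    axes[1].set_xlabel("t")
    axes[1].set_ylabel("amplitude (max - min)")
    axes[1].legend()
    axes[2].plot(metrics.profile_depths, metrics.profile_values, "o-", ms=3)
    axes[2].set_xlabel("distance to surface")
    axes[2].set_ylabel("RMS deviation of u")
    fig.tight_layout()
    fig.savefig(run_dir / "report.png", dpi=120)
    plt.close(fig)
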