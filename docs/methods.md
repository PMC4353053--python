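# Methods

This note records the model, the analysis it admits, and the numerical and
design choices behind `bsrd`, in enough detail that a user can judge what the
package's tests do and do not establish.

## Model and assumptions

Two activator-depleted systems — f(u,v) = a − u + u²v, g(u,v) = b − u²v with
a, b > 0 — are posed on a stationary bulk Ω and on its closed C² boundary
surface Γ, and coupled only through linear Robin-type flux conditions
∂u/∂ν = γ_Γ h₁ and d_Ω ∂v/∂ν = γ_Γ h₂ with h₁ = α₁r − β₁u − κ₁v,
h₂ = α₂s − β₂u − κ₂v.  The same fluxes are subtracted from the surface
kinetics, so the coupling conserves the exchanged mass.  There is no
cross-diffusion and the domain does not evolve.  The geometry is restricted to
the unit disk/ball wherever modes are enumerated, because separation of
variables in polar/spherical coordinates underlies the mode analysis.

Two printed-source ambiguities are resolved as follows: the flux condition on
v carries d_Ω (the linearized restatement that swaps it for d_Γ is treated as
a typo), and the reference coupling value α₁ = β₁ is read as the fraction
5/12.

## Steady state and compatibility

The candidate uniform state is (a+b, b/(a+b)², a+b, b/(a+b)²) in both
compartments.  It exists iff both coupling fluxes vanish at it.  Eliminating
the state from the two flux balances gives the product condition
(β₁−α₁)(κ₂−α₂) − κ₁β₂ = 0, which is necessary but *not* sufficient: when κ₁
or β₂ mix species across the flux balance, the individual balances tie the
coupling coefficients to (a, b).  `steady_state` therefore checks the product
condition *and* numerically verifies that all four augmented kinetics vanish
at the candidate, raising a documented error otherwise.

## Linear stability

The 4×4 Jacobian of the augmented kinetics is block lower-triangular (the bulk
kinetics do not see r, s), so the characteristic quartic factors into the two
block quadratics.  `routh_hurwitz_report` evaluates six sign conditions on the
block traces/determinants — positivity of the four polynomial coefficients
plus the two Hurwitz determinant conditions 2(a₁a₂−a₃) > 0 and
a₃(a₁a₂−a₃) − a₁²a₄ > 0, expanded in block invariants as

    −(Tr_Γ·Tr + 2 Det_Ω)·Tr_Ω − (Tr_Ω·Tr + 2 Det_Γ)·Tr_Γ > 0,
    [(Det_Ω − Det_Γ)² + (Det_Ω Tr_Γ + Det_Γ Tr_Ω)·Tr]·Tr_Ω·Tr_Γ > 0.

These forms were re-derived symbolically because a direct transcription of the
commonly quoted block expansion fails the eigenvalue cross-check; the suite
verifies equivalence with "all eigenvalues have negative real part" on 1000+
random block-triangular matrices with no tolerance games (a₄ = 0 is rejected
as degenerate: a zero root makes the quartic test meaningless).

Two Jacobian variants are exposed.  The *full* variant linearizes the
augmented surface kinetics literally (its surface block carries −α₁, −α₂ on
the diagonal); the *pure-kinetics* variant keeps only reaction partials there.
The Turing analysis and the per-mode matrix use pure kinetics — with the
reference coupling the full variant's surface block has negative determinant,
so the two variants genuinely disagree and reports name the variant used.
Sign decisions use a relative tolerance of 1e-12; values inside the band are
flagged "marginal" and never count as satisfied.

## Modes, dispersion and critical diffusion

On the unit ball the surface eigenvalue is L = l(l+1) and the bulk radial
eigenvalue is taken equal to it (k² = m² on the disk), the natural convention
at unit radius; `Mode` accepts a free k² override since no radial boundary
condition pins k.  Each mode yields the block lower-triangular matrix M whose
quadratic factors

    Tr(M)_Ω = (d_Ω+1)k² − γ_Ω(f_u+g_v),
    Det(M)_Ω = d_Ω k⁴ − γ_Ω(d_Ω f_u+g_v)k² + γ_Ω²(f_u g_v − f_v g_u)

(and the Γ analogues in L) give the four growth-rate roots; they equal the
eigenvalues of −M exactly because the radial-trace coupling ψ′(1) sits in the
lower-left block only.  The critical diffusion ratio d₊ is the larger root of
(d f_u + g_v)² = 4 d Det, +∞ when f_u ≤ 0; for the reference kinetics
(f_u, f_v, g_u, g_v) = (0.8, 1, −1.8, −1) it is the larger root of
0.64 d² − 5.6 d + 1 = 0 ≈ 8.568.  `classify_regime` compares (d_Ω, d_Γ)
against the two critical values and returns one of four regimes.

### Limits of the factored dispersion relation

The factorization substitutes the flux conditions into the surface rows only;
the bulk's response to surface forcing (and its feedback through h₁, h₂) is
not part of the per-mode eigenvalue.  With the reference two-way coupling
(γ_Γ = 500, β₁ = 5/12, κ₂ = 5) this feedback is not negligible: the measured
growth rates of single harmonics on the disk converge, under mesh and
time-step refinement, to the eigenvalues of the exact linearized coupled
operator, which sit 10–30% below the factored roots (verified in the suite by
an independent shift-invert eigensolve).  The shift never changed a regime
outcome in any tested configuration, but quantitative rate predictions under
strong coupling should use the linearized operator, not the factored relation.
For coupling-free (yet compatible) configurations the factorization is exact
and measured rates agree with it to ~1%, which is how the growth-rate
recovery test is posed.

## Meshes

Disk: vertices on concentric rings spaced h apart with arc spacing ≈ h,
alternate rings staggered by half a step; the annuli are triangulated by a
deterministic two-pointer merge of the ring angle sequences.  Minimum angles
are ≈30° and boundary vertices lie on the unit circle to machine precision.
Ball: a twice-refined octahedral seed (512 tetrahedra) undergoes uniform red
(Bey) refinement, boundary vertices projected to the unit sphere after every
refinement; level 2 reaches the sphere volume to 0.6%.  The surface mesh is
always induced — its facets are the boundary facets of the bulk mesh, its
vertices the bulk boundary vertices — so bulk and surface fields share
boundary nodes exactly.  Mesh I/O covers Gmsh MSH 2.2 ASCII, legacy VTK and
OFF (ASCII, 17 significant digits, hence bit-exact round trips); the readers
are small line-oriented parsers that report the offending line on malformed
input.  Simplicial P1 elements are used throughout; the analysis is
element-agnostic and simplicial assembly keeps the package self-contained.

## Discretization

P1 mass and stiffness matrices are assembled from the Gram matrices of the
cell edge vectors, which yields tangential gradients on embedded surface
cells with the same code path (segments on the boundary circle, triangles on
the sphere).  The semi-discrete system is M_blk dx/dt = −A x + b(x) where A
contains diffusion plus *all* coupling (the fluxes are linear, so they are
kept fully implicit via the boundary mass matrix and the trace selector) and
b(x) holds the mass-weighted nodal kinetics (group-FEM treatment of u²v).

Two integrators:

- **IMEX backward Euler** — diffusion and coupling implicit, kinetics
  explicit; one sparse LU reused for the whole run.  Implemented in increment
  form, (M + dt A)δ = dt(−Ax + b(x)), which keeps exact steady states fixed
  to roundoff (drift < 1e-12 over 1000 steps).  First order; the default for
  production runs because a pattern run costs a few seconds.
- **Fractional-step θ** — three substeps θ·dt, (1−2θ)·dt, θ·dt with
  θ = 1 − √2/2 and the right-hand side split F = αF + βF,
  α = (1−2θ)/(1−θ), alternating implicit/explicit weights; each substep is
  solved by Newton on the quadratic kinetics (Jacobian reassembled and
  refactorized per iteration; tolerance 1e-10, relative).  The θ choice makes
  the composed stability function second order, and a dt-refinement study
  against a fine-dt reference trajectory of the full nonlinear system shows
  observed order ≈ 1.97.

Default run parameters: dt = 1e-4 (γ = 500 makes the kinetics stiff; the
explicit kinetics eigenvalues satisfy |λ| dt ≲ 0.2), ε = 0.01 relative
uniform random initial perturbations (seeded, reproducible), steady detector
‖x_{n+1}−x_n‖ / (dt·‖x_steady‖) < 1e-6.  Growth-rate measurement seeds a
single harmonic times the dominant eigenvector of the matching 2×2 factor at
ε = 1e-6, projects onto the harmonic through the surface mass matrix every
step, and fits the slope of log|coefficient| by least squares; it aborts if
the deviation leaves the linear regime.

## Pattern metrics and verdicts

Amplitude is max − min per field; the radial profile is the RMS deviation of
u in bins of width 0.05 in distance-to-surface; the boundary-layer width is
the interpolated depth at which the profile first falls below 10% of its
near-surface value (an exp(−depth/0.1) profile gives 0.1·ln 10 ≈ 0.23).  A
field is "patterned" above amplitude 0.05 — well above decayed-perturbation
noise (≤1e-4 in the no-pattern regime) and well below observed pattern
amplitudes (≳0.5).  The verdict calls the bulk patterned only if the
*interior* (depth > 0.5) exceeds the threshold, which cleanly separates the
surface-driven boundary layer from genuine bulk patterning; in the
bulk-dominant regime the surface amplitude stays an order of magnitude below
threshold, so no amplitude-ratio tie-break is needed.  The u–v phase
opposition (negative Pearson correlation of the deviations) is asserted only
for the reference regimes; with strong Robin coupling it need not hold in
general.

## Problem sizes used by the test suite

Regime simulations run on the disk at h = 0.05 (≈1300 vertices), dt = 1e-4,
to t = 0.5 (patterned regimes saturate by t ≈ 0.2) with 3–5 seeds per regime;
3D checks use ball level 1 (4096 tetrahedra), which resolves the low end of
the unstable band (l ≈ 6–10) and reproduces the surface-only verdict.
Growth-rate fits use h = 0.03 and dt = 2e-5 over windows of ≈0.03 time units.
These sizes were chosen as the coarsest at which the measured quantities are
mesh-converged to within the asserted tolerances; the original study's full
3D resolutions are intentionally not reproduced.

## Known limitations

- The mode analysis covers disks/balls only; the simulator takes any valid
  simplicial mesh but verdict heuristics assume a unit-radius domain.
- The factored dispersion relation underestimates decay/growth under strong
  two-way coupling (see above).
- No adaptive time stepping; Newton failure suggests reducing dt rather than
  retrying adaptively.
- Boundary elements are straight (no isoparametric curvature); measure errors
  are O(h²) and enter the reported amplitudes only through quadrature.
- The steady-pattern detector measures the rate of change, so it can stop
  early in shallow saddle transients; the patterned-regime tests integrate to
  a fixed horizon instead of relying on it.
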