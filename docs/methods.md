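# Methods

## The model

`pinpattern` simulates auxin patterning on a static network of cells.
Each cell `i` carries three concentrations: auxin `A_i`, total PIN1
`P_i^tot` (cytosol plus all membrane sections), and a polarizing signal
`X_i`. Cells exchange auxin across shared walls, passively and through
membrane-bound PIN1:

    dA_i/dt = c_A - d_A A_i
              + (1/V_i) [ D Σ_j a_ij (A_j - A_i)
                        + T Σ_j a_ij (P_ji A_j - P_ij A_i) ]

    dP_i^tot/dt = c_P - d_P P_i^tot

    dX_i/dt = V_X · H⁺(A_i; K_XA, n_XA) · H⁻(R_i; K_XR, n_XR)
                  · H⁻(K_i; K_XK, n_XK) - d_X X_i

where `V_i` is the cell volume, `a_ij = a_ji` the wall area between
neighbors `i` and `j`, the sums run over wall-neighbors `N_i`, and
`H⁺(x; K, n) = xⁿ/(Kⁿ + xⁿ)`, `H⁻ = 1 - H⁺` are activating and
repressing Hill functions.

Membrane PIN1 is not integrated. PIN1 cycling between cytosol and
membrane sections is assumed fast relative to auxin dynamics
(quasi-equilibrium), so the membrane amount facing neighbor `j` is the
algebraic steady state of the exchange system
`dP_ij/dt = k_x[(1-k_p) + k_p X_j] P_i - k_n P_ij`:

    P_ij = P_i^tot (1 - k_p + k_p X_j) / (f_p + Σ_k (1 - k_p + k_p X_k))

with `f_p = k_n/k_x` and `k_p ∈ [0, 1]` weighting polarized against
symmetric exocytosis. `P_ij` is recomputed inside every derivative
evaluation; the explicit exchange ODE exists only as a test oracle.
Because a cell's X recruits PIN1 in its *neighbors* onto the shared
wall, auxin is pumped up its own gradient: the homogeneous state is
unstable for sufficiently strong coupling and isolated auxin maxima
emerge — the standard up-the-gradient mechanism of phyllotaxis models.
X is deliberately abstract; it has been read as either a molecular or a
mechanical-stress signal, and nothing here depends on the choice.

The KANADI (`K_i`) and REVOLUTA (`R_i`) fields enter only through the
two repressive Hill factors in X production. With `K = R = 0`
everywhere the factors are identically 1 and the classical unrepressed
model is recovered exactly.

## Prepattern

KAN and REV are set before the transport dynamics run and stay fixed.
Both follow Hill kinetics in the radial coordinate `r_i` (distance of
the cell centroid from the volume-weighted tissue center) and are
evaluated at equilibrium, which is closed-form because production is
constant per cell. Defaults: `V_K = V_R = d_K = d_R = 1`, `K_K = 30`,
`K_R = 25`, `n_K = n_R = 20`. KAN is then sharpened to a binary field:
`K_i = 0` if the equilibrium is ≤ 0.5, else 1. REV stays graded.

`rev_orientation` selects the direction of the REV profile. The
increasing form `rⁿ/(K_Rⁿ + rⁿ)` makes REV peripheral and produces no
boundary gap when `K_K > K_R`; the decreasing form
`K_Rⁿ/(K_Rⁿ + rⁿ)` makes REV central and leaves an annulus
`r ∈ (≈25, ≈30)` where KAN is absent and REV is low. Only the central
orientation matches the intended geometry (central REV domain,
peripheral KAN ring, low-expression boundary between them), so it is
the default; both forms are implemented because both appear in
descriptions of this prepattern, and the flag makes the choice
explicit rather than silent. The boundary mask is `K = 0 and
R < rev_threshold`, with `rev_threshold = 0.5` mirroring the KAN
threshold (no principled value exists for "low" REV; the mask is an
artifact definition, exposed as a parameter).

A numerical integration path (`integrate_prepattern`) exists purely to
cross-check the closed form; they agree to 1e-6 by test.

## Tissue templates

The dynamics consume only `(V_i, a_ij, N_i, centroids)`, so any
connected polygonal tiling is a valid template. Two generators:

- **Disc** (`generate_disc_tissue`): seeded uniform points in a disc,
  optional Lloyd relaxation (each step moves points to the centroid of
  their disc-clipped Voronoi cell), then a Voronoi tessellation
  bounded by radially mirrored helper points and clipped to the disc.
  Volumes are polygon areas, wall areas shared-edge lengths. The
  default study template is 400 cells, radius 60, 10 relaxation steps:
  the radius puts the Hill thresholds 25 and 30 strictly inside the
  tissue, 400 cells give ≈30 cells in the boundary annulus, and 10
  relaxation steps leave realistic irregularity (mean interior degree
  ≈ 6) while avoiding slivers.
- **Ring** (`generate_ring_tissue`): a cycle of identical cells with
  uniform `V` and `a` (defaults 1), the minimal geometry for oracle,
  conservation and stability tests.

Real meristem templates grow, divide and deform mechanically; these
generators reproduce none of that. What passing tests show is that the
*transport model* behaves as specified on static irregular geometry —
not that the geometry itself is realistic.

## Initial conditions and symmetry breaking

All concentrations start at exactly zero. On an irregular disc the
geometry itself seeds the instability. On a perfectly regular ring the
homogeneous solution is exact to machine precision and would persist
forever, so a seeded multiplicative perturbation of auxin production
(`c_A,i = c_A exp(σ z_i)`, `z_i` standard normal, default σ = 0.05,
off unless requested) provides the missing heterogeneity. It is used
for ring runs only.

## Default dynamics parameters

No canonical value set exists for this model family in the text this
package works from, so defaults were calibrated once with
`scripts/calibrate.py` and frozen. The kinetic scales are normalized
first — `c_A = d_A = c_P = d_P = V_X = d_X = 1` puts the uniform state
at `A* = P* = 1`, `X* = 0.5`; `K_XA = 1` centers X activation on `A*`
where its gain is maximal, with `n_XA = 4`; `f_p = 1` splits PIN1
between cytosol and membranes. The scan then varies `T`, `k_p`, `V_X`
and scores (a) spontaneous patterning on ring and disc and (b) ≥ 90%
of peaks inside the boundary annulus with the prepattern on. The
chosen point `T = 20, k_p = 1, V_X = 1, D = 0.3` lies in the interior
of the region passing both, not on its edge (neighboring grid points
pass too). Repression half-maxes `K_XR = 0.5 (n = 4)` and
`K_XK = 0.25 (n = 2)` sit well below the REV/KAN plateau level 1, so
expressing cells lose ≳ 90% of X production while boundary cells
(R ≲ 0.2) keep most of theirs.

## Numerics

- Integrator: adaptive embedded Dormand–Prince 4(5) Runge–Kutta
  (`scipy.integrate.solve_ivp`, RK45), `rtol = 1e-6`, `atol = 1e-9`.
  States are sampled from the dense interpolant at requested output
  times; accepted-step and function-evaluation counts are reported, a
  step below `min_step = 1e-12` raises an integration failure.
- The V-weighted auxin mass `Σ V_i A_i` is a linear invariant of the
  closed (`c_A = d_A = 0`) system; Runge–Kutta steps preserve linear
  invariants exactly, so measured drift is at machine precision — the
  conservation test is therefore a check on the antisymmetry of the
  implemented flux terms, not on solver tolerance.
- Positivity is not enforced; it holds structurally (every loss term
  is proportional to its own state) and the sampled minimum state
  value is reported in the solver statistics.
- Hill functions are evaluated as `(x/K)ⁿ/(1 + (x/K)ⁿ)` to avoid
  overflow at large `x` with `n = 20`.
- No-flux tissue boundary: walls exist only between cells, so the
  tissue edge is impermeable by construction.
- Steady state is declared when the max relative change of any cell's
  auxin over the trailing 5 output samples is below tolerance
  (default 1e-4), relative to the largest final auxin level.
- Peak detection uses strict inequality against every wall-neighbor
  and a relative height floor (default 0.5 of the global max); ties
  disqualify both cells, so homogeneous fields yield zero peaks
  deterministically and no two peaks are ever adjacent. Peaks are
  single cells; plateau merging is not implemented (fields from this
  model are generically non-degenerate).

## Problem sizes

The packaged experiments use a 100-cell ring and a 400-cell disc, with
simulations to t = 150 and t = 300 respectively — long enough that the
steady-state criterion above is met with margin. These sizes resolve
roughly one cell layer across the boundary annulus and a clear
multi-peak pattern while keeping a full paired experiment in the
seconds range.

## Known limitations

- Static tissue: no growth, division or mechanics, hence no divergence
  angle sequences over successive initiations.
- The KAN/REV fields do not feed back on auxin, and auxin does not
  re-pattern KAN/REV; the coupling is one-way repression of X.
- 2D polygonal geometry only; no 3D meshes or import of external
  template formats.
- Peak statistics (thresholds, the REV cutoff in the boundary mask)
  are operational definitions of qualitative behavior, exposed as
  parameters rather than fixed truths.
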