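# Methods

This note records the models `ellipore` implements, the numerical choices
behind them, what the synthetic generators do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate frame and radii

All geometry is in Å. Structures are rigid single frames. The pipeline
first moves the center of mass to the origin and rotates the
largest-eigenvalue eigenvector of the mass-weighted gyration tensor onto
+z. The axis sign follows the atom-index trend along the axis (falling back
to the +z hemisphere), and the in-plane eigenvectors are sign-fixed by
their largest component, so alignment is deterministic. Caveat: for
structures whose longest principal axis is *not* the pore axis (short, wide
pores; aspect ratio near 1), this heuristic picks the wrong axis — supply
`--no-align` or pre-orient the input, as with any principal-axis aligner.

Van der Waals radii come from a HOLE-style table (C 1.85, O 1.65, N 1.75,
S 2.00, P 2.10, H 1.00, default 2.00 Å), user-overridable via YAML. The
default is a convention, not a fit; all geometric ground-truth statements
in the tests are expressed relative to the table in use. Waters and free
ions are excluded by default (the wall is the protein/nanotube); hydrogens
are kept because the nanotube fixtures are hydrogen-capped.

## Spherical pathway

Per slice at height z, the probe radius is the clearance
`min_i(|p − x_i| − r_i)` over *all* atoms (a single vectorized reduction —
no spatial indexing, which at these problem sizes is not the bottleneck and
keeps results trivially identical to the naive definition). The center is
optimized in-plane by simulated annealing — 500 Gaussian proposals, step
0.5 Å decaying by 0.99 per proposal, Metropolis temperature falling
geometrically 0.5 → 0.005 Å — followed by a Nelder–Mead polish run in
seed-relative coordinates (which makes results exactly translation
equivariant). Defaults: dz = 0.25 Å, stop radius 15 Å, seed 42.

Two containment rules matter and are deliberate:

* **Per-slice search box.** Each slice's search is restricted to a box
  around its seed (±1 Å during a pathway walk, ±2 Å standalone). Clearance
  grows without bound outside any enclosing wall, and atomistic walls are
  not potential barriers of infinite height — for graphene the clearance at
  a hexagon center is only −0.43 Å, which the annealer crosses readily at
  its initial temperature. The box encodes the physical prior that the
  pathway is continuous; an optimum pinned at the box edge is flagged.
* **Blocked or unbounded slices.** Slices whose radius exceeds the stop
  radius (mouths), is non-positive (blocked), or whose plane reaches no
  atoms (sentinel ∞) are carried through flagged and excluded from volume
  and resistance integration.

## Ellipse inflation

In the slice plane, an atom at height offset |dz| < r reduces exactly to a
disc of radius ρ = √(r² − dz²); the non-overlap constraint is a signed
point-to-ellipse distance per disc (negative when the disc center is inside
the ellipse). Distances are computed by safeguarded bisection on the
monotone rational root function of the closest-point parameter, with the
substitution u = t + b² to avoid cancellation; brackets are guaranteed, and
the only special case (points on the major axis inside the evolute) is
closed-form. Precision is ~1e-9 Å at slice scales (60 bisection steps in
the public routine, 36 inside optimizers). A numba kernel provides the same
computation scalar-per-disc with a triangle-inequality prune and early
exit, used in the optimization hot path.

Expansion per slice fixes b at the spherical radius and maximizes a over
[x, y, a, θ]:

1. a coarse orientation scan (18 angles) picks the most promising θ at the
   sphere center, using the exact "largest feasible a" bisection (clearance
   is monotone in a because ellipses with fixed b are nested);
2. two Nelder–Mead stages on the penalized objective
   a + 0.05·clearance − 10⁴·max(0, −clearance)², with center bounds
   ±0.5·b then ±2·b and a capped at min(8b, stop radius). The small
   clearance reward breaks the plateau the objective otherwise has in the
   center coordinates at fixed a — without it the simplex collapses before
   recentring;
3. a feasibility restore after each stage: bisect to the *largest* feasible
   a at the stage's center/orientation (growing as well as shrinking — the
   restored value is the true constrained optimum there, not the simplex's
   last iterate);
4. a refinement pass over (x, y, θ) only, with a eliminated through the
   feasibility bisection, run from both the staged result and the θ-scan
   seed; the best of all candidates wins.

The non-overlap tolerance is −1e-3 Å throughout. Results are canonicalized
to a ≥ b, θ ∈ [0, π). Slices are independent, so profile expansion is
order-free.

**What a ≥ b means on rigid walls.** The maximal-area ellipse inscribed in
an elliptical wall with b pinned to the inscribed-circle radius is *longer*
than the wall's aspect ratio suggests: offsetting a wall of semi-axes
(A, B) inward by the atom radius leaves room for a probe with a/b well
above A/B (the offset region flattens near the major ends). On rigid
atomistic tubes the picture is further textured by the lattice: slices near
atom layers see few large discs with wide angular gaps (the spherical
radius inflates into a gap and elongation is blocked), while slices between
layers elongate to the continuum limit. Both effects are real geometry, not
optimizer artifacts — the test suite checks the optimizer against an
independent dense boundary-sampling oracle — and they mean the median axis
ratio of a rigid, ideally deformed tube is *not* the imposed deformation
ratio. Thermally fluctuating walls, whose effective surface is smoother and
tighter, are the regime where recovered ratios track imposed ones; rigid
generators probe the algorithm, not that regime.

## Volumes and summaries

V = Σ π·a_i·b_i·dz over finite, unflagged slices (slab rule, matching the
resistance discretization). The default integration range is the maximal
contiguous run of unflagged slices containing the global minimum of b —
"the pore proper" — and is reported in the output metadata. Spherical and
ellipsoidal volumes are always compared over a common range (the
ellipsoidal pore proper): the spherical walk keeps producing valid slices
past the last atom-cutting plane, so per-profile ranges are not comparable.
The capsule effective radius √(r² + 2·L·r/π) (area equivalence for a
spherocylinder cross-section) is provided for comparisons with legacy
anisotropy probes.

## Conductance

Bulk conductivity of KCl follows the Nernst–Einstein form
κ = q_e²·n·(D_K + D_Cl)/(k_B·T) with CODATA constants (via
`scipy.constants`), n the number density of c mol/L. Defaults: c = 0.15 M,
T = 300 K, D_K = 1.96e-9, D_Cl = 2.03e-9 m²/s — standard literature
diffusivities, overridable.

Channel resistance is the series slab sum R = Σ dz/(κ_i·π·a_i·b_i) with
Å→m conversion centralized; g is reported in pS. κ_i is either κ_bulk or
the double-sigmoid confinement model
κ(a, b) = σ(a·c1 − c2)·σ(b·c1 − c2)·κ_bulk, which is strictly below bulk
and increasing in both radii for c1 > 0. Exact limits used as tests: a
uniform stack reproduces the single-cylinder R = ρL/A to machine
precision; R is invariant under slab subdivision and z reversal; the model
variant always predicts less conductance than the bulk variant; the
model→bulk gap decays like e^(−(c1·b − c2)) for wide pores.

No default (c1, c2) ships: these are system- and force-field-dependent
fitting parameters, and presenting invented constants as calibrated values
would be worse than requiring a fit. The fitter minimizes squared error on
κ (per-record κ_obs = g·L/(π·a·b); fitting on κ rather than g weights
records by geometry, which is the natural scale for a conductivity model)
with Nelder–Mead from a fixed 3×3 multistart grid (c1 ∈ {0.5, 1, 2},
c2 ∈ {2, 4, 8}); it reports the SSE and the R² between predicted and
observed conductances. With two distinct records the two-parameter model
interpolates exactly; recovery from a noise-free 18-system design grid is
exact to <1e-3, and the acceptance script measures the median error under
5 % multiplicative conductance noise.

Uncertainty of a single-structure estimate is not a model property; the
`ensemble` command propagates it empirically as the standard deviation of
g (and volume) across user-supplied frames.

## Synthetic generators

Armchair (n, n) tubes are rolled rectangular graphene cells (4n carbons
per √3·c_cc period; c_cc = 1.421 Å), axis on z, optional axial terminal
hydrogens at 1.09 Å. Ellipticity is imposed as the exact area-preserving
map x → x/√s, y → y·√s, so the wall semi-axes (r/√s, r·√s) and every
derived ground-truth quantity are closed-form — the point of the generator
is exactness for testing, not physical realism: there is no thermal
disorder, no relaxation of the deformed lattice, and no solvent. Bead-wall
pores place rings of beads on a prescribed wall profile; the inscribed
sphere radius is wall minus bead radius, with the ring-discretization bias
bounded by the chord sagitta and reported in the ground-truth sidecar.
Consequently, passing tests certify the probe algorithms against exact
geometry; they do not certify behavior on thermally fluctuating walls or
real protein surfaces beyond what the geometry shares.

## Problem sizes and determinism

Default test and acceptance runs use (8,8) tubes of length 50 Å at
dz = 0.25 Å (≈160 interior slices), bead pores of 16–30 Å, 100-replicate
fit studies, and oracle comparisons on 20 spherical + 12 ellipse slices —
sizes chosen so the full suite exercises every pathway on a single CPU in
a few minutes. All stochastic components (annealing, noise studies) are
seeded; identical configuration and seed give byte-identical CSV/JSON
outputs, and every output embeds its configuration hash.

## Known limitations

* Planes are always normal to z; curved or tilted pore axes and branched
  pathways are out of scope.
* The ellipse is the most general cross-section shape considered; no
  superellipses or out-of-plane probe tilt.
* Access (mouth) resistance is deliberately absent from the conductance
  stack; the model covers pore resistance only.
* Principal-axis alignment assumes the pore runs along the longest axis.
* Conductance estimates are Ohmic/continuum heuristics: no explicit ions,
  no potential-of-mean-force barriers, no rectification.
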