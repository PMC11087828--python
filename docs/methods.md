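# Methods

## The model

A CT acquisition is modelled as a linear inverse problem

    y = Φx + w,

where `x ≥ 0` is the unknown attenuation image on an `N`-pixel grid,
`Φ` is a parallel-beam Radon transform with `Ma` equispaced angles over
`[0, π)` and `D` unit-spaced detector bins centred on the image centre, and
`w` is i.i.d. zero-mean Gaussian noise with standard deviation `σ` in
sinogram units.  `Φ` is assembled as a sparse matrix by pixel-driven
splatting (each pixel centre projects onto the detector axis and
distributes its value over the two nearest bins with linear weights), so the
adjoint is the exact matrix transpose and the adjoint test holds to machine
precision.  This matters: the primal-dual solvers below assume a consistent
forward/adjoint pair.

The reconstruction is the constrained MAP estimate

    x† = argmin ‖Ψx‖₁   s.t.   ‖Φx − y‖₂ ≤ ε,  x ≥ 0,

with `Ψ` either the anisotropic-TV analysis operator (2-channel forward
differences, replicate boundary) or an orthogonal wavelet decomposition
(periodised, `db4`, 3 levels by default).  Nonnegativity is part of the
problem — it makes `x†` a member of the credible region below by
construction.  The noise-energy radius defaults to the chi-square quantile
bound `ε = σ·sqrt(χ²_q(MaD))` with `q = 0.99`, which makes the data ball
feasible with 99% probability.

## The hypothesis test

For a candidate structure marked by a binary mask `M` (NS pixels), the null
hypothesis H0 states the structure is absent from the true image.  Two
convex sets are compared:

* the conservative credible region
  `Cα = {x ≥ 0 : ‖Φx − y‖₂ ≤ ε, ‖Ψx‖₁ ≤ ηα}` with
  `ηα = ‖Ψx†‖₁ + N + sqrt(16·N·log(3/α))` (α = 0.01 by default);
* the structure-absent set `S = I ∩ E ∩ S`: nonnegativity, an energy ball
  keeping the masked intensities near the neighbourhood median `μpix`, and
  a smoothness ball keeping the masked gradient components near the
  neighbourhood's median gradient magnitude `μ∇`.

The ball parameters are chosen automatically from the MAP estimate over a
dilation annulus around the mask (width 3 pixels): `μ` is the median of the
sampled histogram and `r` the larger of (P60 − median) and (median − P40),
with linear-interpolation percentiles.  The per-pixel tolerances act as RMS
tolerances: the energy ball is `‖Mx − μpix·1‖₂ ≤ r_pix·sqrt(NS)` and the
smoothness ball `‖M∇x − μ∇·1‖₂ ≤ (r_∇ + μ∇)·sqrt(2NS)`.  Including `μ∇` in
the smoothness radius guarantees the set contains a flat patch (whose
signed gradient components sit at zero, at distance `μ∇·sqrt(2NS)` from the
centre), so `S` is never empty.  Strict inequalities are implemented as
closed balls — projections onto open sets are ill-defined and the closure
changes nothing measurable.

The test itself runs in two stages.  Stage 1 projects `x†` onto `S` (a
primal-dual solve involving only the mask operators, no `Φ`); if
`Proj_S(x†) ∈ Cα` an element of `S ∩ Cα` has been exhibited and H0 cannot
be rejected at zero cost in forward-operator evaluations.  Stage 2 otherwise
minimises `½‖x_C − x_S‖²` over `x_S ∈ S, x_C ∈ Cα` on the product space.
After stage 2 an intersection certificate is checked: if the feasible
`x̂_S` also lies in `Cα` (within tolerance), the distance is zero regardless
of the residual iterate gap — this guards against the slow tail of
first-order methods reporting a spurious positive distance when the sets in
fact intersect.

The structure confidence is

    ρα = ‖x̂_C − x̂_S‖₂ / ‖x† − Proj_S(x†)‖₂ ∈ [0, 1],

the fraction of the structure's energy confirmed by the data; H0 is
rejected when `ρα > δ` (δ = 1e-3 by default; the boundary goes to the
null).  When the achieved distance falls below the solver's resolution
(`tol_feas·‖x†‖₂`) or the denominator is zero, ρα is reported as 0 —
conservative toward the null.

## The solver

Both optimisation problems are solved by a Condat–Vũ primal-dual iteration
for `f(x) + g(x) + Σᵢ hᵢ(Lᵢx)`: `f` smooth (zero for the MAP problem, the
coupling `½‖x_C − x_S‖²` for the distance problem, `½‖·−x‖²` for the
projection onto S), `g` the nonnegativity projection, and every `hᵢ` — ball
indicators and the ℓ₁ norm — dualised through the Moreau identity, so only
projections and operator applications are ever needed.

Step sizes use per-term dual steps `σᵢ = θ/‖Lᵢ‖` with
`τ = s/(L_f/2 + θ·Σᵢ wᵢ‖Lᵢ‖)` (safety factor `s = 0.99`, balance `θ = 1`),
which satisfies the Condat–Vũ inequality and keeps every constraint's dual
equally strong regardless of operator scale.  The optional per-term weight
`wᵢ` (0.1 on the credible-region terms in the distance stage, whose
constraints start loosely active at the warm start `(Proj_S(x†), x†)`)
frees a larger primal step.  These are scalar per-block step choices, not
diagonal preconditioning.

Convergence is declared when every constraint's distance-to-set, relative
to the constraint's scale `max(radius, ‖centre‖)`, is below
`tol_feas = 1e-4`, and the estimate is stable: for the MAP problem the
per-iteration relative change of the iterate (window change divided by the
window length, checked every 25 iterations) is below `tol_primal = 1e-5`;
for the distance problem stability is tracked on the distance statistic
itself, relative to `‖x† − Proj_S(x†)‖`.  Feasibility is measured against
the constraint scale rather than against ε because an ε-relative residual
at high data quality would demand absolute accuracy beyond any first-order
method; the resulting slight enlargement of `Cα` is conservative toward the
null.  Non-convergence within `max_iters = 20000` is flagged and a flagged
run yields no decision.

Forward and adjoint applications of every operator are counted exactly; the
cost of the test is reported as the ratio of its `Φ` applications to the
reconstruction's, the hardware-independent unit used throughout.  The ratio
is strongly bimodal: near zero when stage 1 exits early or the certificate
finds an intersection (the projection onto S costs no `Φ` applications at
all), and of order one when the sets are disjoint and stage 2 must run, so
the median over a quality sweep depends on the mix of accepting and
rejecting cells.

## The synthetic data

The phantom generator emulates a contrast-enhanced axial chest slice: a
soft-tissue body ellipse (0.30), two darker lung fields (0.10), 4 bright
vessels (≈0.9, radii 5.5–8.5% of the image side) placed inside the lungs by
a seeded RNG, and optional PE-like inserts — discs of radius ≥ 2 px inside
a vessel at value `vessel·(1 − contrast)`, contrast 0.6 by default.  All
generators are pure functions of their seeds.

Noise levels are specified as a fraction of the noiseless sinogram's
maximum absolute value, so the acquisition-quality regimes (0.007–0.175)
transfer across phantom scales; geometry defaults are D equal to the image
side for desk-scale work with a 450-detector preset for the reference
acquisition grid.

Structure-present scenarios probe a true insert.  Structure-absent
scenarios reconstruct an insert-free phantom at low quality (50 angles,
noise 0.175) under the wavelet prior and auto-detect a probe mask as a
black-top-hat intensity dip inside a vessel that is locally dark (mean at
least 0.02 below its annulus in the reconstruction) and absent from the
ground truth (mean truth-minus-reconstruction deficit above 0.1).  The
wavelet prior is used here because it genuinely hallucinates compact dark
blobs at this quality, while anisotropic TV at these image sizes
over-smooths them away; the scenario caches its prior and reconstruction so
the test probes the same image the artifact was found in.

What the generator does not emulate: real anatomy and texture, beam
hardening, scatter, motion, or any physics-based artifact mechanism, and
polychromatic or fan/cone-beam acquisition.  Passing tests therefore show
that the decision logic behaves correctly for piecewise-constant scenes
under the stated noise model — not that the method is clinically validated.

## Problem sizes and defaults

Unit tests run on 32–48 pixel grids.  The end-to-end suites use side-64
phantoms with D = 64 for the (Ma, σ) sweeps — Ma ∈ {50, 100, 200} × σ ∈
{0.0175, 0.0875, 0.175} with 3 seeds for the cost accounting, and
Ma ∈ {50, 200, 450} at σ = 0.0175 / σ ∈ {0.007, 0.035, 0.175} at Ma = 200
with 5 seeds for the quality trends — and the default side-128 phantoms for
artifact scenarios.  Key defaults: α = 0.01, δ = 1e-3, quantile 0.99,
annulus width 3, `tol_feas = 1e-4`, `tol_primal = 1e-5`,
`max_iters = 20000`.

## Known limitations

* The smoothness constraint is unreliable for masks touching the image or
  body boundary (the gradient stencil then mixes in boundary pixels).
* In regimes where `S` and `Cα` are nearly tangent, the reported distance
  carries the slow tail of the primal-dual iteration and ρα can
  overestimate the true (smaller) value; the intersection certificate
  bounds this from the feasible side only.
* `ηα`'s printed form is implemented in its `sqrt(16·N·log(3/α))`
  concentration reading; the dimensionally heavier verbatim reading
  (`16·N·log(3/α)`) is available behind `reading="verbatim"` and only
  loosens the ℓ₁ budget.
* ρα is not a calibrated p-value; thresholding it (δ) is an
  application-specific choice.
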