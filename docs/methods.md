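# Methods

## Model and assumptions

The package models a closed cardiovascular-style distribution network as a
strictly bifurcating tree of rigid cylinders. Its scope is the idealized
self-similar regime:

1. scale factors are constant across and within generations (one branching
   rule per flow regime, no mixing of asymmetry types);
2. the network is a space-filling fractal: sibling lengths satisfy
   l³_parent = l³_μ + l³_ν, so the cube-law exponent equals the Euclidean
   dimension of the serviced volume;
3. energy loss is minimized — by impedance matching of pressure waves in the
   pulsatile regime (area preservation r²_parent = r²_μ + r²_ν), and by a
   constrained minimization of viscous dissipation in the laminar regime
   (asymmetric Murray's law);
4. terminal units (capillaries) are invariant across body sizes and
   truncation effects are neglected for the analytic results, so the tip
   count is N_C = 2^N.

Under these assumptions total network volume is dominated by the proximal
generations: each generation's combined volume is S = β_μ²γ_μ + β_ν²γ_ν
times the next one's, with S ≤ 1, giving V_TOT = N_C V_C S^{−N}
(1 − S^{N+1})/(1 − S) and the exponent θ = ln2/(ln2 − ln S). We define
θ = 0 at S = 0 and θ = 1 at S = 1 by continuity, so the two degenerate limit
networks (see `asymvasc.fixtures`) evaluate without exceptions.

Note on the geometric bracket: the sub-leading factor
(1 − S^{N+1})/(1 − S) tends to 1/(1 − S), not to 1; the leading-order form
N_C V_C S^{−N} is therefore offset from the exact sum by a constant factor
at large N. Both forms are exposed (`total_volume_closedform` modes) since
the offset cancels in the scaling exponent but not in absolute volumes.

## Parameters

All scale factors are dimensionless ratios in [0, 1]. The difference
factors Δβ, Δγ are capped at 0.5: beyond that the solved average would be
smaller than the difference and a child dimension would go negative. The
physically meaningful constants are:

* β̃_WBE = (1/2)^{1/2} ≈ 0.70711 (pulsatile radii), (1/2)^{1/3} ≈ 0.79370
  (laminar radii), γ̃_WBE = (1/2)^{1/3} (lengths, both regimes);
* fluid constants (viscosity, flow rate) enter only the impedance/power
  oracles, default 1.0 in model units, and provably rescale the objective
  without moving the argmin — they cancel from every scale-factor
  constraint.

## Numerical choices

* Cube-law root: the depressed cubic 2g³ + 6d²g = 1 is monotone on the
  bracket [d, 1]; we bisect 80 steps and polish with 4 Newton iterations,
  rejecting any residual above 1e-12. The boundary solutions g(0) =
  (1/2)^{1/3} and g(0.5) = 0.5 are reproduced exactly by the polish.
* "Constraint satisfied" means |residual| < 1e-9 absolute; all constrained
  quantities are O(1) and dimensionless.
* Inputs are validated to [0, 1] with 1e-12 absolute slack to absorb float
  noise; μ/ν labels are notational, so pairs arriving with β_μ < β_ν are
  relabeled silently (radius ties break by length; the label follows the
  radius, which resolves the pairing ambiguity for negative asymmetry).
* Contour tracing parameterizes by Δγ, scans 401 Δβ points per row for sign
  changes and refines each bracket with Brent's method (xtol 1e-13). Rows
  where the exponent is identically equal to the target (the Δγ = 0 row of
  the 3/4 pulsatile contour) contribute their smallest on-curve point;
  surplus roots are counted on the polyline object rather than returned, so
  each row maps to at most one point.
* Grids mark unsolvable cells with NaN, never silent zeros; quadrants II/IV
  (negative asymmetry) are evaluated with the same solvers since the
  constraints are even in the differences, with the signed differences
  fixing the μ/ν pairing.
* θ treats S within 1e-9 of 1 as the isometric boundary; S > 1 + 1e-9 is an
  error (volume growing per generation is outside the model).

## The energy-minimization oracle

The laminar predictions (β = γ, Δβ = Δγ, cube laws, positive asymmetry) are
verified numerically rather than re-deriving the Lagrange system: SLSQP
minimizes the capillary-anchored dissipated power Q̇₀² Z_TOT over the
per-generation factors (β_μ, β_ν, γ_μ), with γ_ν eliminated through the
space-filling equality and total volume held at (N+1)·N_C·V_C — the value
every cube-law configuration attains, so the constraint set contains the
predicted manifold. The mass constraint is folded into the volume
constraint (mass ∝ volume in this framework). A reduced-problem argument
shows the exact minimizer is β_i = γ_i per child with per-generation volume
factors 1, degenerate along the asymmetry level; the optimizer is therefore
judged by constraint residuals (< 1e-3 at the default settings), not by a
unique argmin. Runs are multi-start (5 seeded feasible inits by default),
deterministic given the seed, with non-convergence reported explicitly.
Box bounds [1e-3, 1] exclude the degenerate corners where impedance
diverges.

## Finite-tree simulations and the empirical exponent

`empirical_theta` regresses ln N_C on ln V_TOT across a family of enumerated
trees of growing depth, rescaled so all networks share one capillary volume
(the WBE size construction). Default problem sizes in the tests and
examples are depths 8–14 (at most 2^15 − 1 branches per tree), which keeps
full enumeration cheap while leaving the finite-size bias well resolved.
That bias is real, not numerical: the exact volume carries the sub-leading
generations, so the symmetric pulsatile family fits 0.7367 against the
asymptotic 3/4, and the laminar family — where S = 1 makes
V_TOT = (N+1) N_C V_C exactly — fits 0.8910 against the asymptotic 1, with
an ln(N+1) bias term that decays only like 1/N. The laminar fit reaches
1.00 ± 0.02 only for depths of order 100, far beyond biological generation
counts; the tests pin the exact finite-size value instead of the asymptote.

## What the simulations do and do not show

The generated trees realize exactly the model's assumptions (constant
rules, no asymmetry-type mixing, optional truncation at a capillary
radius). Agreement between enumeration and closed forms validates the
algebra, not the biology: real networks have non-constant, mixed, noisy
branching, side branching, and finite capillary-size effects that the
closed forms ignore. The impedance closed form is claimed (and tested)
only for unmixed constant rules; for mixed trees the recursive reduction is
the sole result. Pulsatile impedance on finite trees is out of scope — the
model uses impedance matching only as a nodal constraint.

## Design decisions taken where the design was open

* The single source of truth for θ is the physical-factor formula; the
  average/difference, constrained symmetric-difference, and laminar forms
  are implemented as rearrangements and unit-tested as identities, with the
  symmetric limits (3/4 and 1) fixing the sign conventions.
* Of the four possible child-substitution variants of the constrained
  symmetric-difference form, only the μ-child variant is implemented; the
  others differ only in sign conventions and add no coverage.
* Branch volume pairs each branch's radius with its *own* length
  (V = π r² l); the per-generation factorization into S requires this
  pairing.
* `contour_extrema` reports extrema of the exact traced polyline (including
  the Δγ = 0.5 endpoint where the short child's length vanishes), not
  values re-rounded through a coarser grid.
* The laminar θ-grid evaluates the two cube laws independently off the
  Δβ = Δγ equality so the whole difference plane is mapped; on the equality
  the full constraint set holds and θ = 1 exactly.

## Known limitations

* No branch angles or 3-D embedding: trees are topology + dimensions only.
* Degenerate limit rules (zero child dimensions) require an explicit flag
  and exclude impedance evaluation.
* The minimizer certifies local optimality from multiple starts, not global
  optimality.
* Biological classifications beyond the positive/negative taxonomy
  (distributing vs delivering vessels, lung branching modes) are not
  modeled.
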