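# asymvasc

Metabolic scaling in asymmetric self-similar vascular networks.

Kleiber's law states that metabolic rate scales with body mass as
B = B₀ M^θ with θ clustering near 3/4. The West–Brown–Enquist (WBE)
framework derives θ from the geometry of optimal, space-filling vascular
trees — but classically assumes every bifurcation is *symmetric*: both
children share one radius and one length. Real vasculature rarely is.
`asymvasc` implements a generalized WBE model in which the two children of a
bifurcation may differ in both radius and length, and asks how branching
asymmetry reshapes the predicted scaling exponent.

It is a library for researchers in biological scaling / vascular network
theory, with a thin `asymvasc` command-line wrapper for quick calculations.

## The model

A sibling pair at generation j is described by physical scale factors
β_μ = r_μ/r_parent, β_ν = r_ν/r_parent (μ = wider child) and γ_μ, γ_ν for
lengths, or equivalently by averages and differences

    β = (β_μ + β_ν)/2,  Δβ = (β_μ − β_ν)/2,   and likewise γ, Δγ.

Pairs with Δβ·Δγ > 0 are *positively* asymmetric (wider child also longer),
Δβ·Δγ < 0 *negatively* asymmetric (wider but shorter).

Energy minimization and space filling constrain the factors at every node:

* **pulsatile flow** (impedance matching): 1 = (β+Δβ)² + (β−Δβ)², and
  space filling 1 = (γ+Δγ)³ + (γ−Δγ)³ — either asymmetry type allowed;
* **constant laminar flow** (Lagrange minimization of viscous dissipation):
  β = γ, Δβ = Δγ, with both pairs on the cube law — an asymmetric Murray's
  law; negative asymmetry is selected against.

For constant scale factors, capillary number N_C = 2^N and body mass
M ∝ V_TOT give the metabolic scaling exponent

    θ = ln 2 / (ln 2 − ln S),     S = β_μ²γ_μ + β_ν²γ_ν,

which is 3/4 at the symmetric pulsatile point (β = 2^{−1/2}, γ = 2^{−1/3}),
exactly 1 everywhere on the laminar manifold, and spans [0, 1] across the
asymmetry plane. A network transitioning from pulsatile to laminar flow at
generation ratio c = M/N interpolates:
θ = ln2 / [ln2 + (c−1) ln S_lam − c ln S_pul].

The package provides, as importable modules mirrored by `examples/`:

| module | contents |
|---|---|
| `asymvasc.scale_factors` | the three coordinate systems + asymmetry classification |
| `asymvasc.constraints`   | square/cube-law solvers, laminar admissibility, Murray area factor |
| `asymvasc.scaling`       | θ in all published forms, (Δβ, Δγ) grids, iso-θ contour tracing |
| `asymvasc.network`       | explicit finite trees, enumeration oracles for volume/impedance, empirical log-log exponent |
| `asymvasc.optimize`      | numerical power-dissipation minimizer verifying the laminar predictions |
| `asymvasc.cli`, `asymvasc.fixtures` | command-line surface and the canonical A–D reference networks |

## Worked example

```python
from asymvasc import (FIXTURES, AvgDiffScaleFactors, beta_pulsatile,
                      gamma_spacefill, theta_avgdiff, theta_physical)

print(theta_physical(FIXTURES["A"].physical).theta)   # 0.7500000000000003
a = AvgDiffScaleFactors(beta_pulsatile(0.3), 0.3, gamma_spacefill(0.0), 0.0)
print(theta_avgdiff(a).theta)                          # 0.7500000000000002
```

Radial asymmetry alone (Δβ = 0.3, Δγ = 0) leaves θ at 3/4: under the
pulsatile constraints, the exponent only responds to *length* asymmetry.
Tracing where in the asymmetry plane 3/4 survives:

```
$ asymvasc contour pulsatile 0.75 --out contour.csv
dbeta_max = 0.218348
dgamma_max = 0.5
beta_mu_max = 0.890899
beta_nu_min = 0.454202
```

The 3/4 contour tolerates the full range of length asymmetry
(Δγ up to 0.5) but only radial differences up to Δβ ≈ 0.218, i.e. physical
radial factors within ≈ [0.45, 0.89]. And the finite-size check
(`python examples/05_finite_trees.py`):

```
empirical slope over N=8..14: 0.7367 (analytic theta = 0.7500; the small
gap is the finite-size bias of the volume sum)
```

a log-log regression of tip count against enumerated tree volume across
depths 8–14 recovers the analytic exponent up to a computable finite-size
bias.

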