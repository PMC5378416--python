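"""Nodal energy-minimization and space-filling constraints.

Optimal transport in a bifurcating network couples the average and
difference scale factors at every node.  Two flow regimes give two
constraint sets:

*Pulsatile flow* (impedance matching of pressure waves + space-filling):

    area preservation:  1 = (beta + dbeta)^2 + (beta - dbeta)^2
    space filling:      1 = (gamma + dgamma)^3 + (gamma - dgamma)^3

The two relations are independent: radii and lengths may be asymmetric to
different degrees, and either asymmetry type (positive or negative) is
allowed.

*Constant laminar flow* (Lagrange minimization of viscous dissipation +
space-filling) additionally forces ``beta = gamma`` and ``dbeta = dgamma``,
with both pairs on the cube law — an asymmetric form of Murray's law.  Only
positive (or symmetric) asymmetry survives energy minimization in this
regime.

Both solved averages decrease from their symmetric WBE values
((1/2)^{1/2} for the square law, (1/2)^{1/3} for the cube law) to exactly
1/2 as the difference grows from 0 to 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .scale_factors import (
    AvgDiffScaleFactors,
    FlowRegime,
    classify_asymmetry,
)

__all__ = [
    "ConstraintResidual",
    "beta_pulsatile",
    "gamma_spacefill",
    "laminar_scale",
    "check_laminar_admissible",
    "murray_child_area_sum",
    "constraint_residuals",
    "CONSTRAINT_TOL",
]

#: Absolute residual below which a constraint counts as satisfied
#: (all constrained quantities are O(1) and dimensionless).
CONSTRAINT_TOL = 1e-9

#: Maximum admissible difference factor: beyond 0.5 the solved average would
#: fall below the difference, i.e. one child dimension would go negative.
_D_MAX = 0.5


@dataclass(frozen=True)
class ConstraintResidual:
    """Signed residuals of the nodal constraint relations.

    ``area_preserving``: (beta+dbeta)^2 + (beta-dbeta)^2 - 1 (pulsatile).
    ``space_filling``:   (gamma+dgamma)^3 + (gamma-dgamma)^3 - 1.
    ``murray``:          (beta+dbeta)^3 + (beta-dbeta)^3 - 1 (laminar).
    ``equality_beta_gamma``: max(|beta-gamma|, |dbeta-dgamma|) (laminar).
    """

    area_preserving: float
    space_filling: float
    murray: float
    equality_beta_gamma: float

    def satisfies(self, which: str, tol: float = CONSTRAINT_TOL) -> bool:
        return abs(getattr(self, which)) < tol


def constraint_residuals(a: AvgDiffScaleFactors) -> ConstraintResidual:
    """Evaluate all nodal constraint residuals for one configuration."""
    bm, bn = a.beta + a.dbeta, a.beta - a.dbeta
    gm, gn = a.gamma + a.dgamma, a.gamma - a.dgamma
    return ConstraintResidual(
        area_preserving=bm**2 + bn**2 - 1.0,
        space_filling=gm**3 + gn**3 - 1.0,
        murray=bm**3 + bn**3 - 1.0,
        equality_beta_gamma=max(abs(a.beta - a.gamma), abs(a.dbeta - a.dgamma)),
    )


def beta_pulsatile(dbeta: float, strict: bool = True) -> float:
    """Average radial factor under area-preserving (pulsatile) branching.

    Solves ``1 = (beta+dbeta)^2 + (beta-dbeta)^2``, i.e.
    ``beta = sqrt(1/2 - dbeta^2)``, the unique non-negative root; strictly
    decreasing in ``|dbeta|``, from (1/2)^{1/2} at 0 to exactly 1/2 at 1/2.

    For ``|dbeta|`` in (1/2, 1/sqrt(2)] a real root exists but falls below
    ``|dbeta|`` (a negative child radius); with ``strict`` (default) that is
    an error, otherwise the root is returned as-is.
    """
    d = abs(float(dbeta))
    if d > 1.0 / math.sqrt(2.0) + 1e-15:
        raise ValueError(
            f"no real solution: |dbeta| = {d!r} exceeds 1/sqrt(2)"
        )
    beta = math.sqrt(max(0.5 - d * d, 0.0))
    if strict and d > _D_MAX + 1e-12:
        raise ValueError(
            f"|dbeta| = {d!r} > 0.5: solved beta = {beta!r} < |dbeta| "
            "(negative child radius); pass strict=False to get the root anyway"
        )
    return beta


def gamma_spacefill(dgamma: float) -> float:
    """Average length factor under space-filling (cube-law) branching.

    Solves ``1 = (gamma+dgamma)^3 + (gamma-dgamma)^3``, equivalently
    ``2 gamma^3 + 6 gamma dgamma^2 = 1``, for the unique real root with
    ``gamma >= |dgamma|``; strictly decreasing in ``|dgamma|``, from
    (1/2)^{1/3} at 0 to exactly 1/2 at 1/2.

    The same cube law governs the laminar-regime radii (Murray's law), so
    this solver serves both.
    """
    d = abs(float(dgamma))
    if d > _D_MAX + 1e-12:
        raise ValueError(f"|dgamma| = {d!r} > 0.5: no admissible solution")
    d = min(d, _D_MAX)
    # Depressed cubic 2g^3 + 6d^2 g - 1 = 0: monotone increasing in g, so a
    # single root brackets in [d, 1]. Bisection then Newton polish.
    f = lambda g: 2.0 * g**3 + 6.0 * d * d * g - 1.0
    lo, hi = d, 1.0
    if f(lo) > 0.0:  # only at d = 0.5 where the root is exactly 0.5
        return 0.5
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    g = 0.5 * (lo + hi)
    for _ in range(4):
        fg = f(g)
        g -= fg / (6.0 * g * g + 6.0 * d * d)
    if abs(f(g)) > 1e-12:  # pragma: no cover - defensive
        raise ArithmeticError("cube-law root polish failed to converge")
    return g


def laminar_scale(d: float) -> AvgDiffScaleFactors:
    """Full constant-laminar-flow configuration at difference level ``d``.

    Energy minimization forces ``beta = gamma`` and ``dbeta = dgamma = d``
    with the shared average on the cube law, so a single number parameterizes
    the whole admissible manifold.
    """
    d = float(d)
    if not (0.0 <= d <= _D_MAX + 1e-12):
        raise ValueError(f"d must lie in [0, 0.5]; got {d!r}")
    g = gamma_spacefill(d)
    return AvgDiffScaleFactors(beta=g, dbeta=d, gamma=g, dgamma=d)


def check_laminar_admissible(
    a: AvgDiffScaleFactors, tol: float = 1e-9
) -> tuple[bool, str]:
    """Verdict on whether a configuration can occur under laminar flow.

    Admissible iff the asymmetry is symmetric or positive (negative
    asymmetry is selected against in this regime) and the full laminar
    constraint set (equalities + both cube laws) is satisfied within ``tol``.

    Returns ``(verdict, reason)``; ``reason`` is empty when admissible.
    """
    label = classify_asymmetry(a).label
    if label == "negative":
        return False, "negative asymmetry (suppressed under laminar flow)"
    res = constraint_residuals(a)
    if abs(res.equality_beta_gamma) >= tol:
        return False, (
            "average/difference equalities violated: "
            f"max(|beta-gamma|, |dbeta-dgamma|) = {res.equality_beta_gamma:.3g}"
        )
    if abs(res.murray) >= tol:
        return False, f"Murray cube law violated: residual {res.murray:.3g}"
    if abs(res.space_filling) >= tol:
        return False, f"space-filling cube law violated: residual {res.space_filling:.3g}"
    return True, ""


def murray_child_area_sum(
    parent_area: float, beta: float, dbeta: float, tol: float = CONSTRAINT_TOL
) -> float:
    """Total child cross-sectional area under asymmetric Murray branching.

    On the Murray manifold (radial cube law) the sum of the two child areas
    can be written in terms of the parent area alone:

        A_mu + A_nu = A_parent * (1/beta - 4 dbeta^2)

    which interpolates between area-increasing branching (factor 2^{1/3} at
    the symmetric point) and area-preserving branching (factor 1 at
    beta = dbeta = 1/2) — asymmetry acts as a throttle on flow speed.
    Off-manifold inputs are rejected.
    """
    if parent_area < 0:
        raise ValueError("parent_area must be non-negative")
    bm, bn = beta + dbeta, beta - dbeta
    residual = bm**3 + bn**3 - 1.0
    if abs(residual) >= tol:
        raise ValueError(
            f"(beta, dbeta) = ({beta!r}, {dbeta!r}) is off the Murray "
            f"manifold (cube-law residual {residual:.3g})"
        )
    return parent_area * (1.0 / beta - 4.0 * dbeta**2)
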