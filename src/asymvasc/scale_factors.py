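"""Algebra of asymmetric branching scale factors.

A bifurcating vascular network is described generation by generation through
the ratios of child to parent dimensions.  For a sibling pair, the *physical*
scale factors are the four ratios

    beta_mu = r_child_mu / r_parent,   beta_nu = r_child_nu / r_parent,
    gamma_mu = l_child_mu / l_parent,  gamma_nu = l_child_nu / l_parent,

where ``mu`` labels the child with the larger radius.  The same pair can be
written in *average/difference* coordinates

    beta  = (beta_mu + beta_nu) / 2,   dbeta  = (beta_mu - beta_nu) / 2,
    gamma = (gamma_mu + gamma_nu) / 2, dgamma = (gamma_mu - gamma_nu) / 2,

which cleanly separate the symmetric (average) and asymmetric (difference)
content of a branching event, or as *symmetric-difference* deviations from
the symmetric WBE constants ((1/2)^{1/2} or (1/2)^{1/3} for radii depending on
flow regime, (1/2)^{1/3} for lengths).

Sign conventions: a pair with ``dbeta`` and ``dgamma`` of equal sign is
*positively* asymmetric (the wider child is also the longer one); opposite
signs are *negative* asymmetry (wider but shorter).  Negating both
differences relabels the two children and describes the same node.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Literal

__all__ = [
    "PhysicalScaleFactors",
    "AvgDiffScaleFactors",
    "SymDiffScaleFactors",
    "AsymmetryClass",
    "FlowRegime",
    "BETA_WBE_PULSATILE",
    "BETA_WBE_LAMINAR",
    "GAMMA_WBE",
    "avgdiff_from_physical",
    "physical_from_avgdiff",
    "symdiff_from_physical",
    "physical_from_symdiff",
    "classify_asymmetry",
]

#: Absolute tolerance used to absorb float noise at interval boundaries.
_ATOL = 1e-12

#: Symmetric WBE radial scale factor under pulsatile flow (area-preserving).
BETA_WBE_PULSATILE = (1.0 / 2.0) ** (1.0 / 2.0)
#: Symmetric WBE radial scale factor under constant laminar flow (Murray).
BETA_WBE_LAMINAR = (1.0 / 2.0) ** (1.0 / 3.0)
#: Symmetric WBE length scale factor (space-filling; both regimes).
GAMMA_WBE = (1.0 / 2.0) ** (1.0 / 3.0)


class FlowRegime(str, Enum):
    """Fluid-flow regime of a network section.

    Pulsatile flow (large vessels, wave propagation) selects area-preserving
    branching; constant laminar flow (small vessels, Hagen-Poiseuille)
    selects Murray's cube law.
    """

    PULSATILE = "pulsatile"
    LAMINAR = "laminar"

    def beta_wbe(self) -> float:
        """Symmetric WBE radial constant for this regime."""
        if self is FlowRegime.PULSATILE:
            return BETA_WBE_PULSATILE
        return BETA_WBE_LAMINAR


def _check_unit_interval(name: str, value: float) -> float:
    if not (-_ATOL <= value <= 1.0 + _ATOL):
        raise ValueError(f"{name} must lie in [0, 1]; got {value!r}")
    return min(max(value, 0.0), 1.0)


@dataclass(frozen=True)
class PhysicalScaleFactors:
    """The four child/parent dimension ratios at a branching node.

    ``mu`` labels the child with the larger radius; inputs with
    ``beta_mu < beta_nu`` are silently relabeled on construction (the labels
    are notational, not physical).  Radius ties assign ``mu`` to the longer
    child.
    """

    beta_mu: float
    beta_nu: float
    gamma_mu: float
    gamma_nu: float

    def __post_init__(self) -> None:
        bm = _check_unit_interval("beta_mu", self.beta_mu)
        bn = _check_unit_interval("beta_nu", self.beta_nu)
        gm = _check_unit_interval("gamma_mu", self.gamma_mu)
        gn = _check_unit_interval("gamma_nu", self.gamma_nu)
        # labels follow the radius; on a radius tie, the length
        if bm < bn or (bm == bn and gm < gn):
            bm, bn = bn, bm
            gm, gn = gn, gm
        object.__setattr__(self, "beta_mu", bm)
        object.__setattr__(self, "beta_nu", bn)
        object.__setattr__(self, "gamma_mu", gm)
        object.__setattr__(self, "gamma_nu", gn)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.beta_mu, self.beta_nu, self.gamma_mu, self.gamma_nu)


@dataclass(frozen=True)
class AvgDiffScaleFactors:
    """Average/difference coordinates of a sibling pair.

    Invariants: ``|dbeta| <= beta`` and ``|dgamma| <= gamma`` (both physical
    factors non-negative) and averages in (0, 1].
    """

    beta: float
    dbeta: float
    gamma: float
    dgamma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.beta <= 1.0 + _ATOL):
            raise ValueError(f"beta must lie in (0, 1]; got {self.beta!r}")
        if not (0.0 < self.gamma <= 1.0 + _ATOL):
            raise ValueError(f"gamma must lie in (0, 1]; got {self.gamma!r}")
        if abs(self.dbeta) > self.beta + _ATOL:
            raise ValueError(
                f"|dbeta| = {abs(self.dbeta)!r} exceeds beta = {self.beta!r}"
            )
        if abs(self.dgamma) > self.gamma + _ATOL:
            raise ValueError(
                f"|dgamma| = {abs(self.dgamma)!r} exceeds gamma = {self.gamma!r}"
            )

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.beta, self.dbeta, self.gamma, self.dgamma)


@dataclass(frozen=True)
class SymDiffScaleFactors:
    """Deviations from the symmetric WBE constants.

    The reconstruction is ``beta_mu = beta_WBE + dbeta_mu`` and
    ``beta_nu = beta_WBE - dbeta_nu`` (note the sign convention on the nu
    deviations), and analogously for lengths; ``regime`` fixes which radial
    WBE constant applies.
    """

    dbeta_mu: float
    dbeta_nu: float
    dgamma_mu: float
    dgamma_nu: float
    regime: FlowRegime = FlowRegime.PULSATILE

    def __post_init__(self) -> None:
        object.__setattr__(self, "regime", FlowRegime(self.regime))
        b_wbe = self.regime.beta_wbe()
        pairs = (
            ("beta_mu", b_wbe + self.dbeta_mu),
            ("beta_nu", b_wbe - self.dbeta_nu),
            ("gamma_mu", GAMMA_WBE + self.dgamma_mu),
            ("gamma_nu", GAMMA_WBE - self.dgamma_nu),
        )
        for name, value in pairs:
            if not (-_ATOL <= value <= 1.0 + _ATOL):
                raise ValueError(
                    f"reconstructed {name} = {value!r} lies outside [0, 1]"
                )


@dataclass(frozen=True)
class AsymmetryClass:
    """Branching-type classification of a sibling pair."""

    label: Literal["symmetric", "positive", "negative", "degenerate"]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def avgdiff_from_physical(p: PhysicalScaleFactors) -> AvgDiffScaleFactors:
    """Convert physical scale factors to average/difference coordinates."""
    return AvgDiffScaleFactors(
        beta=(p.beta_mu + p.beta_nu) / 2.0,
        dbeta=(p.beta_mu - p.beta_nu) / 2.0,
        gamma=(p.gamma_mu + p.gamma_nu) / 2.0,
        dgamma=(p.gamma_mu - p.gamma_nu) / 2.0,
    )


def physical_from_avgdiff(a: AvgDiffScaleFactors) -> PhysicalScaleFactors:
    """Convert average/difference coordinates back to physical factors.

    Exact inverse of :func:`avgdiff_from_physical` (up to the mu/nu
    relabeling convention, which orients ``dbeta >= 0``).
    """
    return PhysicalScaleFactors(
        beta_mu=a.beta + a.dbeta,
        beta_nu=a.beta - a.dbeta,
        gamma_mu=a.gamma + a.dgamma,
        gamma_nu=a.gamma - a.dgamma,
    )


def symdiff_from_physical(
    p: PhysicalScaleFactors, regime: FlowRegime | str = FlowRegime.PULSATILE
) -> SymDiffScaleFactors:
    """Express physical factors as deviations from the WBE constants."""
    regime = FlowRegime(regime)
    b_wbe = regime.beta_wbe()
    return SymDiffScaleFactors(
        dbeta_mu=p.beta_mu - b_wbe,
        dbeta_nu=b_wbe - p.beta_nu,
        dgamma_mu=p.gamma_mu - GAMMA_WBE,
        dgamma_nu=GAMMA_WBE - p.gamma_nu,
        regime=regime,
    )


def physical_from_symdiff(s: SymDiffScaleFactors) -> PhysicalScaleFactors:
    """Reconstruct physical factors from symmetric-difference deviations."""
    b_wbe = s.regime.beta_wbe()
    return PhysicalScaleFactors(
        beta_mu=b_wbe + s.dbeta_mu,
        beta_nu=b_wbe - s.dbeta_nu,
        gamma_mu=GAMMA_WBE + s.dgamma_mu,
        gamma_nu=GAMMA_WBE - s.dgamma_nu,
    )


def classify_asymmetry(a: AvgDiffScaleFactors, atol: float = _ATOL) -> AsymmetryClass:
    """Classify a sibling pair as symmetric, positive, negative or degenerate.

    Positive asymmetry: the wider child is also the longer one
    (``dbeta * dgamma > 0``; simultaneous negation of both differences is the
    same physical node, so both sign pairs count).  Negative asymmetry: wider
    but shorter (``dbeta * dgamma < 0``).  Exactly one vanishing difference is
    ``degenerate``; both vanishing is ``symmetric``.
    """
    db_zero = abs(a.dbeta) <= atol
    dg_zero = abs(a.dgamma) <= atol
    if db_zero and dg_zero:
        return AsymmetryClass("symmetric")
    if db_zero or dg_zero:
        return AsymmetryClass("degenerate")
    if a.dbeta * a.dgamma > 0:
        return AsymmetryClass("positive")
    return AsymmetryClass("negative")
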