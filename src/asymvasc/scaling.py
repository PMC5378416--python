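"""Metabolic scaling exponents of asymmetric branching networks.

For a self-similar bifurcating network whose sibling scale factors are
constant across generations, metabolic rate is proxied by the number of
terminal capillaries (N_C = 2^N) and body mass by the total network volume.
Total volume is dominated by the proximal generations and scales with the
per-generation *branch volume factor*

    S = beta_mu^2 gamma_mu + beta_nu^2 gamma_nu,

giving the metabolic scaling exponent

    theta = ln 2 / (ln 2 - ln S),            0 <= S <= 1.

This single formula is the canonical definition here; the average/difference
and symmetric-difference forms are algebraic rearrangements of it and are
tested as identities.  Limits are taken by continuity: theta -> 0 as S -> 0
(maximally sub-linear scaling) and theta = 1 at S = 1 (isometric scaling; the
whole constant-laminar-flow manifold sits there).

A network that transitions from pulsatile flow (generations 0..M-1, factors
constrained by area preservation + space filling) to constant laminar flow
(generations M..N, cube laws) interpolates between the two pure-regime
exponents through the generation ratio c = M/N:

    theta = ln 2 / [ln 2 + (c - 1) ln S_lam - c ln S_pul].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .constraints import beta_pulsatile, gamma_spacefill, laminar_scale
from .scale_factors import (
    AvgDiffScaleFactors,
    FlowRegime,
    GAMMA_WBE,
    PhysicalScaleFactors,
    SymDiffScaleFactors,
    physical_from_avgdiff,
)

__all__ = [
    "ThetaResult",
    "ThetaGrid",
    "TransitionSpec",
    "ContourPolyline",
    "branch_volume_factor",
    "theta_from_volume_factor",
    "theta_physical",
    "theta_avgdiff",
    "theta_symdiff",
    "theta_laminar",
    "theta_transition",
    "theta_grid",
    "contour_trace",
    "contour_extrema",
]

_LN2 = math.log(2.0)
#: Slack for treating S as the isometric boundary value 1.
_S_BOUND_TOL = 1e-9

RegimeOrC = Union[FlowRegime, str, float]


@dataclass(frozen=True)
class ThetaResult:
    """A metabolic scaling exponent together with its volume factor S."""

    theta: float
    branch_volume_factor: float


@dataclass(frozen=True)
class TransitionSpec:
    """A pulsatile-to-laminar flow transition at generation ratio c = M/N.

    ``pre`` are the scale factors of the pulsatile (proximal) generations,
    ``post`` those of the laminar (distal) generations.  ``c = 1`` is a pure
    pulsatile network, ``c = 0`` pure laminar.  With ``validate`` set, ``pre``
    must satisfy the pulsatile constraint pair and ``post`` the laminar cube
    laws (the average/difference equalities are not required, so that the
    full difference plane can be explored).
    """

    pre: PhysicalScaleFactors
    post: PhysicalScaleFactors
    c: float
    validate: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.c <= 1.0):
            raise ValueError(f"generation ratio c must lie in [0, 1]; got {self.c!r}")
        if self.validate:
            tol = 1e-9
            p = self.pre
            area = p.beta_mu**2 + p.beta_nu**2 - 1.0
            fill = p.gamma_mu**3 + p.gamma_nu**3 - 1.0
            if abs(area) >= tol or abs(fill) >= tol:
                raise ValueError(
                    "pre factors violate the pulsatile constraints "
                    f"(area residual {area:.3g}, space-filling residual {fill:.3g})"
                )
            q = self.post
            murray = q.beta_mu**3 + q.beta_nu**3 - 1.0
            fill = q.gamma_mu**3 + q.gamma_nu**3 - 1.0
            if abs(murray) >= tol or abs(fill) >= tol:
                raise ValueError(
                    "post factors violate the laminar cube laws "
                    f"(Murray residual {murray:.3g}, space-filling residual {fill:.3g})"
                )


def branch_volume_factor(p: PhysicalScaleFactors) -> float:
    """Per-generation total-volume ratio S = beta_mu^2 gamma_mu + beta_nu^2 gamma_nu."""
    return p.beta_mu**2 * p.gamma_mu + p.beta_nu**2 * p.gamma_nu


def theta_from_volume_factor(s: float) -> ThetaResult:
    """Exponent from the volume factor, with continuous boundary conventions."""
    if s > 1.0 + _S_BOUND_TOL:
        raise ValueError(
            f"branch volume factor S = {s!r} exceeds 1: total volume would "
            "grow per generation, outside the model's assumptions"
        )
    if s < 0.0:
        raise ValueError(f"branch volume factor must be non-negative; got {s!r}")
    if s >= 1.0 - _S_BOUND_TOL:
        return ThetaResult(theta=1.0, branch_volume_factor=min(s, 1.0))
    if s == 0.0:
        return ThetaResult(theta=0.0, branch_volume_factor=0.0)
    return ThetaResult(theta=_LN2 / (_LN2 - math.log(s)), branch_volume_factor=s)


def theta_physical(p: PhysicalScaleFactors) -> ThetaResult:
    """Metabolic scaling exponent from physical scale factors."""
    return theta_from_volume_factor(branch_volume_factor(p))


def theta_avgdiff(a: AvgDiffScaleFactors) -> ThetaResult:
    """Exponent in average/difference coordinates.

    Uses the expansion S = 2 beta^2 gamma (1 + 2 dbeta dgamma / (beta gamma)
    + dbeta^2 / beta^2), which separates the symmetric contribution
    (2 beta^2 gamma) from the asymmetric corrections; identical to
    :func:`theta_physical` on the converted factors.
    """
    s = (
        2.0
        * a.beta**2
        * a.gamma
        * (
            1.0
            + 2.0 * a.dbeta * a.dgamma / (a.beta * a.gamma)
            + a.dbeta**2 / a.beta**2
        )
    )
    return theta_from_volume_factor(s)


def theta_symdiff(s: SymDiffScaleFactors) -> ThetaResult:
    """Exponent with the pulsatile constraints substituted in.

    Only the mu-child deviations are free: the nu-child factors are
    eliminated through area preservation (beta_nu^2 = 1 - beta_mu^2) and
    space filling (gamma_nu = (1 - gamma_mu^3)^{1/3}).  In this form the
    exponent's dependence on radial asymmetry disappears whenever the length
    deviation is zero: with gamma_mu at the WBE constant the exponent is
    exactly 3/4 for every admissible beta_mu.
    """
    if s.regime is not FlowRegime.PULSATILE:
        raise ValueError("the constrained symmetric-difference form is pulsatile-only")
    beta_mu = s.regime.beta_wbe() + s.dbeta_mu
    gamma_mu = GAMMA_WBE + s.dgamma_mu
    if not (0.0 <= beta_mu <= 1.0):
        raise ValueError(f"reconstructed beta_mu = {beta_mu!r} outside [0, 1]")
    if not (0.0 <= gamma_mu <= 1.0):
        raise ValueError(f"reconstructed gamma_mu = {gamma_mu!r} outside [0, 1]")
    beta_nu_sq = 1.0 - beta_mu**2
    gamma_nu = (1.0 - gamma_mu**3) ** (1.0 / 3.0)
    return theta_from_volume_factor(
        beta_mu**2 * gamma_mu + beta_nu_sq * gamma_nu
    )


def theta_laminar(d: float) -> ThetaResult:
    """Exponent of the constant-laminar-flow configuration at difference d.

    Identically 1 across the whole admissible manifold: the cube law
    2 gamma^3 + 6 gamma dgamma^2 = 1 makes the volume factor exactly 1.
    """
    return theta_avgdiff(laminar_scale(d))


def theta_transition(t: TransitionSpec) -> ThetaResult:
    """Exponent of a network with a pulsatile-to-laminar flow transition.

    Reduces to the pure pulsatile exponent at c = 1 and to the pure laminar
    exponent at c = 0; the reported volume factor is the effective
    per-generation factor S_eff with theta = ln2/(ln2 - ln S_eff).
    """
    s_pre = branch_volume_factor(t.pre)
    s_post = branch_volume_factor(t.post)
    if s_pre > 1.0 + _S_BOUND_TOL and t.c > 0.0:
        raise ValueError(
            f"pulsatile (pre) volume factor S = {s_pre!r} exceeds 1"
        )
    if s_post > 1.0 + _S_BOUND_TOL:
        raise ValueError(f"laminar (post) volume factor S = {s_post!r} exceeds 1")
    return _theta_transition_from_factors(s_pre, s_post, t.c)


def _theta_transition_from_factors(s_pre: float, s_post: float, c: float) -> ThetaResult:
    """Transition exponent from the two volume factors, by continuity at 0."""
    # weighted log-volume growth per generation; S = 0 on either active side
    # collapses total volume growth and drives theta to 0 continuously
    if (s_pre <= 0.0 and c > 0.0) or (s_post <= 0.0 and c < 1.0):
        return ThetaResult(theta=0.0, branch_volume_factor=0.0)
    log_post = 0.0 if c >= 1.0 else math.log(min(s_post, 1.0))
    log_pre = 0.0 if c <= 0.0 else math.log(min(s_pre, 1.0))
    log_s_eff = (1.0 - c) * log_post + c * log_pre
    denom = _LN2 - log_s_eff
    theta = 1.0 if abs(log_s_eff) < 1e-15 else _LN2 / denom
    return ThetaResult(theta=theta, branch_volume_factor=math.exp(log_s_eff))


def _solved_volume_factor(regime_or_c: RegimeOrC, dbeta: float, dgamma: float) -> float:
    """Volume factor at (dbeta, dgamma) with averages solved per regime.

    The constraint relations are even in the differences, so the solvers see
    |dbeta|, |dgamma| while the signed values fix the mu/nu pairing (sign
    quadrants II/IV are negative asymmetry).  For a generation-ratio c the
    pre (pulsatile) and post (laminar) averages are solved independently at
    the same differences and blended on the log scale.
    """
    if isinstance(regime_or_c, (FlowRegime, str)):
        regime = FlowRegime(regime_or_c)
        if regime is FlowRegime.PULSATILE:
            beta = beta_pulsatile(abs(dbeta))
            gamma = gamma_spacefill(abs(dgamma))
            return _signed_factor(beta, dbeta, gamma, dgamma)
        # laminar: both pairs on the cube law, evaluated off the
        # dbeta = dgamma equality as well to cover the full plane
        beta = gamma_spacefill(abs(dbeta))
        gamma = gamma_spacefill(abs(dgamma))
        return _signed_factor(beta, dbeta, gamma, dgamma)
    c = float(regime_or_c)
    s_pre = _solved_volume_factor(FlowRegime.PULSATILE, dbeta, dgamma)
    s_post = _solved_volume_factor(FlowRegime.LAMINAR, dbeta, dgamma)
    return _theta_transition_from_factors(s_pre, s_post, c).branch_volume_factor


def _signed_factor(beta: float, dbeta: float, gamma: float, dgamma: float) -> float:
    bm, bn = beta + dbeta, beta - dbeta
    gm, gn = gamma + dgamma, gamma - dgamma
    return bm * bm * gm + bn * bn * gn


def _theta_at(regime_or_c: RegimeOrC, dbeta: float, dgamma: float) -> float:
    s = _solved_volume_factor(regime_or_c, dbeta, dgamma)
    return theta_from_volume_factor(min(s, 1.0)).theta


@dataclass
class ThetaGrid:
    """The exponent evaluated over a (dbeta, dgamma) lattice.

    ``theta_values[i, j]`` is theta at ``dgamma_axis[i]``, ``dbeta_axis[j]``
    (rows sweep the length difference, columns the radial difference).
    Cells where the constraints are unsolvable hold NaN.
    """

    dbeta_axis: np.ndarray
    dgamma_axis: np.ndarray
    theta_values: np.ndarray
    regime_or_c: RegimeOrC

    def to_frame(self) -> pd.DataFrame:
        """Wide matrix form: index dgamma, columns dbeta."""
        return pd.DataFrame(
            self.theta_values, index=self.dgamma_axis, columns=self.dbeta_axis
        )

    def to_csv(self, path: str | Path) -> None:
        """Axes + matrix as CSV (index column = dgamma, header = dbeta)."""
        frame = self.to_frame()
        frame.index.name = "dgamma"
        frame.to_csv(path)

    def to_long(self) -> pd.DataFrame:
        """Long form with one (dbeta, dgamma, theta) row per cell."""
        frame = self.to_frame()
        frame.index.name = "dgamma"
        frame.columns.name = "dbeta"
        long = frame.stack(future_stack=True).rename("theta").reset_index()
        return long[["dbeta", "dgamma", "theta"]]

    def to_long_tsv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    def value_at(self, dbeta: float, dgamma: float) -> float:
        """Theta at the lattice point nearest to (dbeta, dgamma)."""
        j = int(np.argmin(np.abs(self.dbeta_axis - dbeta)))
        i = int(np.argmin(np.abs(self.dgamma_axis - dgamma)))
        return float(self.theta_values[i, j])


def theta_grid(
    regime_or_c: RegimeOrC,
    resolution: int = 201,
    span: float = 0.5,
) -> ThetaGrid:
    """Evaluate theta over the full (dbeta, dgamma) in [-span, span]^2 lattice.

    At every lattice point the averages are solved from the regime's
    constraints (or, for a generation ratio c, from both regimes' constraints
    and blended); all four sign quadrants are populated, quadrants II/IV
    being negative asymmetry.
    """
    if resolution < 2:
        raise ValueError("resolution must be at least 2")
    if not (0.0 < span <= 0.5):
        raise ValueError("span must lie in (0, 0.5]")
    axis = np.linspace(-span, span, resolution)
    values = np.full((resolution, resolution), np.nan)
    for i, dg in enumerate(axis):
        for j, db in enumerate(axis):
            try:
                values[i, j] = _theta_at(regime_or_c, float(db), float(dg))
            except (ValueError, ArithmeticError):
                pass  # unsolvable cell stays NaN
    return ThetaGrid(
        dbeta_axis=axis, dgamma_axis=axis, theta_values=values, regime_or_c=regime_or_c
    )


@dataclass
class ContourPolyline:
    """An iso-theta contour traced in the positive (dbeta, dgamma) quadrant."""

    theta_target: float
    regime_or_c: RegimeOrC
    points: np.ndarray  # shape (n, 2): columns (dbeta, dgamma), ordered by dgamma
    multiplicity_dropped: int = 0  # extra roots beyond the smallest, if any

    def __len__(self) -> int:
        return len(self.points)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["dbeta", "dgamma"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def contour_trace(
    regime_or_c: RegimeOrC,
    theta_target: float,
    dgamma_samples: int | Sequence[float] = 201,
    scan_resolution: int = 401,
) -> ContourPolyline:
    """Trace the iso-exponent contour theta = theta_target.

    For each sampled dgamma in [0, 0.5], root-solves theta(dbeta; dgamma) =
    theta_target for dbeta in [0, 0.5] by bracket scanning + Brent's method;
    where multiple roots exist the smallest is kept (and the surplus
    counted).  dgamma values with no root are simply absent from the
    polyline, which may legitimately be empty.
    """
    if not (0.0 < theta_target < 1.0):
        raise ValueError("theta_target must lie strictly between 0 and 1")
    if isinstance(dgamma_samples, int):
        dgammas = np.linspace(0.0, 0.5, dgamma_samples)
    else:
        dgammas = np.sort(np.asarray(dgamma_samples, dtype=float))
        if dgammas.size and (dgammas[0] < 0.0 or dgammas[-1] > 0.5):
            raise ValueError("dgamma samples must lie in [0, 0.5]")
    from scipy.optimize import brentq

    db_scan = np.linspace(0.0, 0.5, scan_resolution)
    points: list[tuple[float, float]] = []
    dropped = 0
    for dg in dgammas:
        vals = np.array([_theta_at(regime_or_c, db, dg) for db in db_scan])
        g = vals - theta_target
        roots: list[float] = []
        on_curve = np.abs(g) < 1e-12
        for k in range(len(db_scan) - 1):
            if on_curve[k]:
                roots.append(float(db_scan[k]))
                continue
            if g[k] * g[k + 1] < 0.0:
                r = brentq(
                    lambda db: _theta_at(regime_or_c, db, float(dg)) - theta_target,
                    db_scan[k],
                    db_scan[k + 1],
                    xtol=1e-13,
                )
                roots.append(float(r))
        if on_curve[-1]:
            roots.append(float(db_scan[-1]))
        if roots:
            # collapse near-duplicates from flat stretches
            uniq = [roots[0]]
            for r in roots[1:]:
                if r - uniq[-1] > 1e-9:
                    uniq.append(r)
            points.append((uniq[0], float(dg)))
            dropped += len(uniq) - 1
    return ContourPolyline(
        theta_target=theta_target,
        regime_or_c=regime_or_c,
        points=np.array(points).reshape(-1, 2),
        multiplicity_dropped=dropped,
    )


def contour_extrema(polyline: ContourPolyline) -> dict[str, float]:
    """Extrema of the difference and implied physical radial factors.

    Returns ``dbeta_max``, ``dgamma_max``, ``beta_mu_max`` (max of
    beta + dbeta along the contour) and ``beta_nu_min`` (min of
    beta - dbeta), with the average solved from the contour's regime at each
    point.  For a generation ratio c the pulsatile average is used (the
    radial constraint of the proximal, pulsatile section).
    """
    if len(polyline) == 0:
        raise ValueError("cannot take extrema of an empty contour")
    roc = polyline.regime_or_c
    if isinstance(roc, (FlowRegime, str)) and FlowRegime(roc) is FlowRegime.LAMINAR:
        solve_beta = gamma_spacefill
    else:
        solve_beta = beta_pulsatile
    dbetas = polyline.points[:, 0]
    dgammas = polyline.points[:, 1]
    betas = np.array([solve_beta(db) for db in dbetas])
    return {
        "dbeta_max": float(dbetas.max()),
        "dgamma_max": float(dgammas.max()),
        "beta_mu_max": float((betas + dbetas).max()),
        "beta_nu_min": float((betas - dbetas).min()),
    }
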