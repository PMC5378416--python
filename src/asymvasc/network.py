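"""Explicit finite bifurcating trees: volumes, impedances, empirical scaling.

This module materializes the self-similar model as an actual tree of
cylindrical branches so that the closed-form results can be checked against
brute-force enumeration:

* total network volume — enumerated sum of pi r^2 l over all branches vs the
  geometric-sum closed form N_C V_C S^{-N} (1 - S^{N+1})/(1 - S) with
  S = beta_mu^2 gamma_mu + beta_nu^2 gamma_nu (the aorta-dominated form; the
  per-generation totals shrink distally when S < 1);
* Hagen-Poiseuille network impedance — recursive series/parallel reduction
  vs the generation-blocks-in-series closed form, which coincide exactly for
  unmixed constant rules because every subtree is a scaled copy of the whole;
* the empirical scaling exponent — an OLS fit of ln(tip count) against
  ln(total volume) across a family of networks of growing depth sharing an
  invariant terminal (capillary) unit, which converges to the analytic
  exponent of the rule as the network deepens.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .scale_factors import AvgDiffScaleFactors, PhysicalScaleFactors, physical_from_avgdiff

__all__ = [
    "Branch",
    "NetworkSpec",
    "TreeSummary",
    "ScalingFit",
    "build_tree",
    "iter_branches",
    "tree_summary",
    "total_volume_exact",
    "total_volume_closedform",
    "total_volume_transition",
    "total_impedance_laminar",
    "total_impedance_closedform",
    "empirical_theta",
    "export_tree",
    "import_tree_json",
    "import_tree_newick",
]

#: Hard cap on tree depth (2^22 branches ~ GiB scale).
_MAX_GENERATIONS = 22

TREE_SCHEMA_VERSION = 1


@dataclass
class Branch:
    """One cylindrical vessel segment; 0 or 2 children."""

    generation: int
    radius: float
    length: float
    children: list["Branch"] = field(default_factory=list)

    @property
    def volume(self) -> float:
        return math.pi * self.radius**2 * self.length

    def is_tip(self) -> bool:
        return not self.children


@dataclass
class NetworkSpec:
    """Recipe for a finite self-similar network.

    ``rule`` may be a single :class:`PhysicalScaleFactors` (constant rule) or
    one per generation.  With ``transition_generation`` M and ``post_rule``
    set, generations before M branch by ``rule`` and generations at or after
    M by ``post_rule`` (a pulsatile-to-laminar flow transition).
    ``mixing_policy`` orients which child takes the mu role: ``none`` keeps
    mu first everywhere, ``alternate`` swaps by generation parity, ``random``
    swaps per node with a seeded generator.  Descent stops early at any
    branch whose radius has reached ``capillary_radius``.
    """

    root_radius: float
    root_length: float
    n_generations: int
    rule: PhysicalScaleFactors | Sequence[PhysicalScaleFactors]
    transition_generation: int | None = None
    post_rule: PhysicalScaleFactors | None = None
    mixing_policy: Literal["none", "alternate", "random"] = "none"
    seed: int | None = None
    capillary_radius: float | None = None
    allow_degenerate: bool = False

    def rule_at(self, generation: int) -> PhysicalScaleFactors:
        if self.transition_generation is not None and self.post_rule is not None:
            if generation >= self.transition_generation:
                return self.post_rule
        if isinstance(self.rule, PhysicalScaleFactors):
            return self.rule
        return self.rule[generation]


def build_tree(spec: NetworkSpec) -> Branch:
    """Materialize the tree described by ``spec``; deterministic given seed."""
    n = spec.n_generations
    if n < 0:
        raise ValueError("n_generations must be non-negative")
    if n > _MAX_GENERATIONS:
        raise ValueError(f"n_generations = {n} exceeds the guard ({_MAX_GENERATIONS})")
    if spec.root_radius <= 0 or spec.root_length <= 0:
        raise ValueError("root dimensions must be positive")
    if spec.transition_generation is not None and not (
        0 <= spec.transition_generation <= n
    ):
        raise ValueError("transition_generation must lie in [0, n_generations]")
    rng = np.random.default_rng(spec.seed) if spec.mixing_policy == "random" else None

    root = Branch(generation=0, radius=spec.root_radius, length=spec.root_length)
    frontier = [root]
    for gen in range(n):
        rule = spec.rule_at(gen)
        if not spec.allow_degenerate and (
            min(rule.beta_mu, rule.beta_nu) == 0.0
            or min(rule.gamma_mu, rule.gamma_nu) == 0.0
        ):
            raise ValueError(
                "rule produces zero child dimensions; pass allow_degenerate=True "
                "to build this limit network"
            )
        next_frontier: list[Branch] = []
        for branch in frontier:
            if (
                spec.capillary_radius is not None
                and branch.radius <= spec.capillary_radius
            ):
                continue  # reached terminal size early: stays a tip
            if spec.mixing_policy == "alternate":
                mu_first = gen % 2 == 0
            elif spec.mixing_policy == "random":
                mu_first = bool(rng.integers(0, 2))
            else:
                mu_first = True
            mu = Branch(
                generation=gen + 1,
                radius=branch.radius * rule.beta_mu,
                length=branch.length * rule.gamma_mu,
            )
            nu = Branch(
                generation=gen + 1,
                radius=branch.radius * rule.beta_nu,
                length=branch.length * rule.gamma_nu,
            )
            branch.children = [mu, nu] if mu_first else [nu, mu]
            next_frontier.extend(branch.children)
        frontier = next_frontier
    return root


def iter_branches(root: Branch) -> Iterable[Branch]:
    """Depth-first (preorder) traversal."""
    stack = [root]
    while stack:
        b = stack.pop()
        yield b
        stack.extend(reversed(b.children))


@dataclass
class TreeSummary:
    """Per-generation table plus network totals."""

    per_generation: pd.DataFrame
    total_volume: float
    tip_count: int

    def to_csv(self, path: str | Path) -> None:
        self.per_generation.to_csv(path, index=False)


def tree_summary(root: Branch) -> TreeSummary:
    rows: dict[int, dict[str, float]] = {}
    tips = 0
    for b in iter_branches(root):
        row = rows.setdefault(
            b.generation,
            {
                "generation": b.generation,
                "count": 0,
                "volume": 0.0,
                "area": 0.0,
                "radius_min": math.inf,
                "radius_max": -math.inf,
                "length_min": math.inf,
                "length_max": -math.inf,
            },
        )
        row["count"] += 1
        row["volume"] += b.volume
        row["area"] += math.pi * b.radius**2
        row["radius_min"] = min(row["radius_min"], b.radius)
        row["radius_max"] = max(row["radius_max"], b.radius)
        row["length_min"] = min(row["length_min"], b.length)
        row["length_max"] = max(row["length_max"], b.length)
        if b.is_tip():
            tips += 1
    frame = pd.DataFrame(sorted(rows.values(), key=lambda r: r["generation"]))
    return TreeSummary(
        per_generation=frame,
        total_volume=float(frame["volume"].sum()),
        tip_count=tips,
    )


def total_volume_exact(root: Branch) -> float:
    """Brute-force total volume: sum of pi r^2 l over every branch."""
    return sum(b.volume for b in iter_branches(root))


def _volume_factor(rule: PhysicalScaleFactors) -> float:
    return rule.beta_mu**2 * rule.gamma_mu + rule.beta_nu**2 * rule.gamma_nu


def total_volume_closedform(
    a: AvgDiffScaleFactors | PhysicalScaleFactors,
    n_generations: int,
    capillary_volume: float,
    mode: Literal["exact_sum", "leading_order"] = "exact_sum",
) -> float:
    """Closed-form total volume of a constant-rule network.

    With N_C = 2^N capillaries of volume V_C and per-generation factor S:

    ``exact_sum``      N_C V_C S^{-N} (1 - S^{N+1}) / (1 - S)
                       (the full geometric sum over generations; evaluated by
                       its limit N_C V_C (N+1) at the S = 1 boundary),
    ``leading_order``  N_C V_C S^{-N}   (aorta-generation term only).

    S > 1 is rejected: the model assumes total volume shrinks distally.
    """
    rule = a if isinstance(a, PhysicalScaleFactors) else physical_from_avgdiff(a)
    s = _volume_factor(rule)
    if s > 1.0 + 1e-12:
        raise ValueError(f"volume factor S = {s!r} exceeds 1")
    s = min(s, 1.0)
    n = n_generations
    n_c = 2.0**n
    if mode == "leading_order":
        return n_c * capillary_volume * s ** (-n)
    if mode != "exact_sum":
        raise ValueError(f"unknown mode {mode!r}")
    if s == 0.0:
        raise ValueError("volume factor S = 0: capillary-anchored sum undefined")
    if abs(1.0 - s) < 1e-12:
        return n_c * capillary_volume * (n + 1)
    return n_c * capillary_volume * s ** (-n) * (1.0 - s ** (n + 1)) / (1.0 - s)


def total_volume_transition(
    pre: PhysicalScaleFactors,
    post: PhysicalScaleFactors,
    n_generations: int,
    transition_generation: int,
    capillary_volume: float,
) -> float:
    """Leading-order volume of a network with a flow transition at M.

    Generations 0..M-1 carry the pulsatile factor S_pre, generations M..N the
    laminar factor S_post: V_TOT ~ N_C V_C S_pre^{-M} S_post^{-(N-M)}.  At
    M = N this reduces to the pure pulsatile leading-order form.
    """
    n, m = n_generations, transition_generation
    if not 0 <= m <= n:
        raise ValueError("transition_generation must lie in [0, n_generations]")
    s_pre, s_post = _volume_factor(pre), _volume_factor(post)
    if min(s_pre, s_post) <= 0.0:
        raise ValueError("volume factors must be positive")
    return 2.0**n * capillary_volume * s_pre ** (-m) * s_post ** (-(n - m))


def total_impedance_laminar(root: Branch, viscosity: float = 1.0) -> float:
    """Hagen-Poiseuille impedance of the whole tree by nodal reduction.

    Each branch contributes Z = 8 mu l / (pi r^4) in series with the parallel
    combination of its child subtrees.
    """

    def z(b: Branch) -> float:
        if b.radius <= 0.0:
            raise ValueError("zero-radius branch has infinite impedance")
        own = 8.0 * viscosity * b.length / (math.pi * b.radius**4)
        if not b.children:
            return own
        inv = sum(1.0 / z(c) for c in b.children)
        return own + 1.0 / inv

    return z(root)


def total_impedance_closedform(
    rule: PhysicalScaleFactors,
    n_generations: int,
    root_radius: float,
    root_length: float,
    viscosity: float = 1.0,
) -> float:
    """Generation-blocks-in-series impedance for an unmixed constant rule.

    Generation k, taken as one parallel block, has impedance Z_0 t^k with
    t = (beta_mu^4/gamma_mu + beta_nu^4/gamma_nu)^{-1}; blocks add in series:
    Z_TOT = Z_0 sum_{k=0}^{N} t^k.  Equal to the recursive nodal reduction
    for self-similar constant rules.
    """
    if min(rule.beta_mu, rule.beta_nu) <= 0.0 or min(rule.gamma_mu, rule.gamma_nu) <= 0.0:
        raise ValueError("closed-form impedance requires strictly positive factors")
    z0 = 8.0 * viscosity * root_length / (math.pi * root_radius**4)
    t = 1.0 / (rule.beta_mu**4 / rule.gamma_mu + rule.beta_nu**4 / rule.gamma_nu)
    return z0 * sum(t**k for k in range(n_generations + 1))


@dataclass
class ScalingFit:
    """OLS fit of ln(tip count) against ln(total volume)."""

    slope: float
    intercept: float
    r_squared: float
    n_sizes: int
    sizes: list[int]
    log_tip_counts: list[float]
    log_volumes: list[float]


def empirical_theta(
    spec_family: Sequence[NetworkSpec],
    capillary_volume: float = math.pi,
) -> ScalingFit:
    """Empirical scaling exponent across a family of growing networks.

    Builds each tree, counts tips and enumerates its exact volume, rescaled
    so that every network shares the same terminal (capillary) unit volume —
    the WBE construction in which larger bodies mean deeper networks over
    invariant capillaries.  Returns the OLS slope of ln N_C on ln V_TOT.

    The slope carries a finite-size bias from the sub-leading generations of
    the volume sum; it converges to the analytic exponent of the rule as the
    networks deepen.
    """
    if len(spec_family) < 3:
        raise ValueError("need at least three network sizes for a meaningful fit")
    sizes: list[int] = []
    log_nc: list[float] = []
    log_v: list[float] = []
    for spec in spec_family:
        root = build_tree(spec)
        summary = tree_summary(root)
        tip_volume = sum(b.volume for b in iter_branches(root) if b.is_tip())
        if tip_volume <= 0.0:
            raise ValueError("tip volume vanishes; cannot anchor capillary units")
        # rescale so each network's combined tip volume is N_C * V_C
        v_scaled = summary.total_volume * (
            summary.tip_count * capillary_volume / tip_volume
        )
        sizes.append(spec.n_generations)
        log_nc.append(math.log(summary.tip_count))
        log_v.append(math.log(v_scaled))
    if len(set(sizes)) < 3:
        raise ValueError("need at least three distinct sizes")
    x = np.asarray(log_v)
    y = np.asarray(log_nc)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else float("nan")
    return ScalingFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_sizes=len(sizes),
        sizes=sizes,
        log_tip_counts=list(map(float, y)),
        log_volumes=list(map(float, x)),
    )


# ---------------------------------------------------------------------------
# serialization

def _tree_records(root: Branch) -> list[dict]:
    records = []
    counter = [0]

    def visit(b: Branch, parent_id: int | None) -> None:
        bid = counter[0]
        counter[0] += 1
        records.append(
            {
                "id": bid,
                "parent_id": parent_id,
                "generation": b.generation,
                "radius": b.radius,
                "length": b.length,
            }
        )
        for c in b.children:
            visit(c, bid)

    visit(root, None)
    return records


def export_tree(root: Branch, format: Literal["json", "newick"] = "json") -> str:
    """Serialize a tree as a JSON cylinder list or an annotated Newick string.

    JSON round-trips byte-identically through :func:`import_tree_json`.
    The Newick form stores each branch's length as the edge length and its
    radius as the node label; :func:`import_tree_newick` restores the tree.
    """
    if format == "json":
        payload = {"schema_version": TREE_SCHEMA_VERSION, "branches": _tree_records(root)}
        return json.dumps(payload, indent=1)
    if format == "newick":
        def nwk(b: Branch) -> str:
            label = f"{b.radius!r}:{b.length!r}"
            if not b.children:
                return label
            return "(" + ",".join(nwk(c) for c in b.children) + ")" + label

        return nwk(root) + ";"
    raise ValueError(f"unknown format {format!r}")


def import_tree_json(text: str) -> Branch:
    payload = json.loads(text)
    if payload.get("schema_version") != TREE_SCHEMA_VERSION:
        raise ValueError("unsupported tree schema version")
    by_id: dict[int, Branch] = {}
    root: Branch | None = None
    for rec in payload["branches"]:
        b = Branch(
            generation=rec["generation"], radius=rec["radius"], length=rec["length"]
        )
        by_id[rec["id"]] = b
        if rec["parent_id"] is None:
            root = b
        else:
            by_id[rec["parent_id"]].children.append(b)
    if root is None:
        raise ValueError("no root branch in record list")
    return root


def import_tree_newick(text: str) -> Branch:
    """Parse the annotated Newick form produced by :func:`export_tree`."""
    import skbio

    tree = skbio.TreeNode.read(io.StringIO(text), format="newick")

    def convert(node, generation: int) -> Branch:
        b = Branch(
            generation=generation,
            radius=float(node.name),
            length=float(node.length),
        )
        b.children = [convert(c, generation + 1) for c in node.children]
        return b

    return convert(tree, 0)
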