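"""Named reference networks spanning the model's limits.

Four canonical parameter sets:

* ``A`` — symmetric pulsatile network (area-preserving + space-filling at
  zero asymmetry); the classic 3/4-exponent configuration.
* ``B`` — symmetric constant-laminar network (Murray + space-filling at zero
  asymmetry); exponent 1.
* ``C`` — extreme asymmetric limit with the wide child of zero length and
  the long child of zero radius; exponent 0 (maximally sub-linear).
* ``D`` — extreme asymmetric limit collapsing to one continuing cylinder;
  exponent 1 (isometric).

A and B satisfy their regime's nodal constraints exactly; C and D are
degenerate limit networks (zero child dimensions) and are flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass

from .scale_factors import (
    BETA_WBE_LAMINAR,
    BETA_WBE_PULSATILE,
    FlowRegime,
    GAMMA_WBE,
    PhysicalScaleFactors,
)

__all__ = ["NetworkFixture", "FixtureCatalog", "FIXTURES"]


@dataclass(frozen=True)
class NetworkFixture:
    name: str
    description: str
    physical: PhysicalScaleFactors
    regime: FlowRegime | None
    degenerate: bool


@dataclass(frozen=True)
class FixtureCatalog:
    """The named fixtures, keyed by letter."""

    entries: dict[str, NetworkFixture]

    def __getitem__(self, name: str) -> NetworkFixture:
        return self.entries[name.upper()]

    def names(self) -> list[str]:
        return sorted(self.entries)


FIXTURES = FixtureCatalog(
    entries={
        "A": NetworkFixture(
            name="A",
            description="symmetric pulsatile limit (theta = 3/4)",
            physical=PhysicalScaleFactors(
                BETA_WBE_PULSATILE, BETA_WBE_PULSATILE, GAMMA_WBE, GAMMA_WBE
            ),
            regime=FlowRegime.PULSATILE,
            degenerate=False,
        ),
        "B": NetworkFixture(
            name="B",
            description="symmetric constant-laminar limit (theta = 1)",
            physical=PhysicalScaleFactors(
                BETA_WBE_LAMINAR, BETA_WBE_LAMINAR, GAMMA_WBE, GAMMA_WBE
            ),
            regime=FlowRegime.LAMINAR,
            degenerate=False,
        ),
        "C": NetworkFixture(
            name="C",
            description="extreme asymmetric limit, theta = 0 "
            "(wide child of zero length, long child of zero radius)",
            physical=PhysicalScaleFactors(1.0, 0.0, 0.0, 1.0),
            regime=None,
            degenerate=True,
        ),
        "D": NetworkFixture(
            name="D",
            description="extreme asymmetric limit, theta = 1 (single cylinder)",
            physical=PhysicalScaleFactors(1.0, 0.0, 1.0, 0.0),
            regime=None,
            degenerate=True,
        ),
    }
)
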