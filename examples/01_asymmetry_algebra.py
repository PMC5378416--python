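"""Sibling scale factors in three coordinate systems.

Builds one asymmetric branching node from physical child/parent ratios,
rewrites it in average/difference and symmetric-difference coordinates, and
classifies its asymmetry type.
"""

from asymvasc import (
    PhysicalScaleFactors,
    avgdiff_from_physical,
    classify_asymmetry,
    symdiff_from_physical,
)

# wider child (radius ratio 0.8) is also longer (length ratio 0.9)
node = PhysicalScaleFactors(beta_mu=0.8, beta_nu=0.6, gamma_mu=0.9, gamma_nu=0.5)
a = avgdiff_from_physical(node)
s = symdiff_from_physical(node, "pulsatile")

print(f"physical factors      : {node.as_tuple()}")
print(f"average/difference    : beta={a.beta:.3f} dbeta={a.dbeta:.3f} "
      f"gamma={a.gamma:.3f} dgamma={a.dgamma:.3f}")
print(f"WBE deviations (radii): +{s.dbeta_mu:.4f} / -{s.dbeta_nu:.4f}")
print(f"asymmetry class       : {classify_asymmetry(a)}")
# dbeta and dgamma share a sign, so the wider child is the longer one:
# positive asymmetry.  Opposite signs (wider but shorter) would be negative.
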