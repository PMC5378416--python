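"""Energy-minimization constraints at a branching node.

Solves the average scale factors from the difference factors in both flow
regimes and shows the Murray area factor interpolating between
area-increasing and area-preserving branching.
"""

from asymvasc import (
    beta_pulsatile,
    check_laminar_admissible,
    gamma_spacefill,
    laminar_scale,
    murray_child_area_sum,
    AvgDiffScaleFactors,
)

# pulsatile flow: area-preserving square law for radii, cube law for lengths
for d in (0.0, 0.25, 0.5):
    print(f"pulsatile d={d:.2f}: beta={beta_pulsatile(d):.5f} "
          f"gamma={gamma_spacefill(d):.5f}")
# both averages fall from the symmetric WBE constants (0.70711, 0.79370)
# to exactly 0.5 at maximal asymmetry.

# laminar flow: one shared cube law plus beta=gamma, dbeta=dgamma
cfg = laminar_scale(0.2)
print(f"laminar  d=0.20: beta=gamma={cfg.beta:.5f}")

# asymmetry throttles the child/parent area ratio (hence flow speed)
for d, beta in ((0.0, laminar_scale(0.0).beta), (0.5, 0.5)):
    factor = murray_child_area_sum(1.0, beta, d)
    print(f"Murray area factor at dbeta={d:.1f}: {factor:.4f}")
# 1.2599 = 2^(1/3): area grows each generation (blood slows);
# 1.0000: area preserved (speed maintained).

bad = AvgDiffScaleFactors(beta=0.7, dbeta=0.1, gamma=0.7, dgamma=-0.1)
ok, reason = check_laminar_admissible(bad)
print(f"wider-but-shorter pair admissible under laminar flow? {ok} ({reason})")
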