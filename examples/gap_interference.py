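"""Standing-wave interference in the thin sample gap.

Sweeps the slide-to-coverslip distance L and prints how the peak pressure
in the sample is amplified or reduced by interference, its lambda/2
periodicity, and why glass walls make the chamber more L-sensitive than
polystyrene ones.
"""

import numpy as np

import sonochamber as sc

reg = sc.MaterialRegistry()
for m in sc.default_materials():
    reg.add(m.with_(alpha0_db_per_cm=0.0))   # lossless: pure interference

lam = reg["water"].c_long / 1e6


def stack(wall):
    return sc.LayerStack.from_sequence([
        (reg["water"], sc.HALF_SPACE), (reg[wall], 1.2e-3),
        (reg["water"], 15e-6), (reg[wall], 0.17e-3),
        (reg["air"], sc.HALF_SPACE)])


gaps = np.linspace(1e-6, lam, 240)
for wall in ("glass", "polystyrene"):
    sweep = sc.sample_amplitude_vs_gap(stack(wall), gaps, 1e6)
    amp = sweep["amplitude_ratio"]
    print(f"{wall:12s}: sample amplitude ranges {amp.min():.3f} .. {amp.max():.3f}"
          f"  (excursion {amp.max()-amp.min():.3f}) over one wavelength of L")

print(f"\nperiod check: lambda/2 = {lam/2*1e6:.1f} um; amplitude at"
      f" L = 0.2*lambda and L = 0.2*lambda + lambda/2 agree:")
for L in (0.2 * lam, 0.2 * lam + lam / 2):
    a = sc.sample_amplitude_vs_gap(stack("glass"), [L], 1e6, n_z=1001)
    print(f"  L = {L*1e6:7.2f} um -> {a['amplitude_ratio'][0]:.6f}")
print("the high-contrast glass cavity resonates sharply (large excursion),"
      " while polystyrene walls leave the sample field much flatter in L")
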