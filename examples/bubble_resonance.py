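"""Microbubble resonance and mechanical index for the exposure settings.

Prints the resonance frequency of a lipid-shelled contrast-agent bubble,
its bare (Minnaert) limit, the radius resonant at the 1 MHz drive, and
the mechanical index at the pressure transmitted into the sample.
"""

import sonochamber as sc

shelled = sc.BubbleParameters(R0=1.5e-6)       # default lipid-shell constants
bare = sc.BubbleParameters(R0=1.5e-6, gamma=1.4, sigma=0.0, chi=0.0)

print(f"R0 = 1.5 um shelled bubble : f0 = {sc.resonance_frequency(shelled)/1e6:.2f} MHz")
print(f"same radius, bare (Minnaert): f0 = {sc.resonance_frequency(bare)/1e6:.2f} MHz")
print("  the shell stiffens the oscillator and raises the resonance")

R_res = sc.resonant_radius(1e6, shelled)
print(f"radius resonant at the 1 MHz drive: {R_res*1e6:.2f} um")

for pnp in (380.0, 500.0):
    mi = sc.mechanical_index(sc.ExposureSetting(pnp_kpa=pnp, f_hz=1e6))
    print(f"MI at {pnp:.0f} kPa, 1 MHz: {mi:.2f}")
print("  MI = PNP(kPa)/sqrt(f(Hz)), numerically equal to the usual"
      " MPa/sqrt(MHz) convention; values near 0.4 drive inertial cavitation"
      " of the contrast bubbles")
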