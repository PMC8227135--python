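"""Single-interface behaviour on the chamber's acoustic path.

Prints the specific impedances of the default materials, the
normal-incidence intensity transmission at the water/glass and water/air
interfaces, and the oblique-incidence landmarks (critical and intromission
angles) that constrain where the transducer can point.
"""

import sonochamber as sc

reg = sc.default_materials()
water, glass, ps, adiprene, air = (reg[n] for n in
                                   ("water", "glass", "polystyrene",
                                    "adiprene", "air"))

print("specific acoustic impedances r = rho*c (MPa.s/m):")
for m in (water, glass, ps, adiprene, air):
    print(f"  {m.name:12s} {sc.impedance(m)/1e6:10.4f}")

for other in (glass, air):
    Ti = sc.normal_coeffs(sc.impedance(water), sc.impedance(other)).Ti
    print(f"normal incidence water -> {other.name}: Ti = {Ti:.4g}")
print("  (Ti = 1 only for matched impedances; the water/air interface is"
      " nearly opaque, which is why the chamber is backed by a near-total"
      " reflector)")

ca = sc.critical_angles(water, glass)
print(f"water -> glass critical angles: longitudinal {ca.longitudinal:.2f} deg,"
      f" shear {ca.shear:.2f} deg")
print("  beyond the first angle only shear waves enter the slide; beyond"
      " both, transmission is evanescent tunneling")

theta = sc.intromission_angle(water, adiprene)
print(f"water/adiprene intromission angle: {theta:.2f} deg "
      f"(T = {sc.oblique_power_transmission(theta, water, adiprene):.6f})")
print("  at this angle the interface is acoustically transparent;"
      " water/polystyrene has no such angle:",
      sc.intromission_angle(water, ps))
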