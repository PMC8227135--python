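# Default exposure-chamber configuration: 1 MHz flat immersion transducer,
# water bath, 26.5 degree design incidence, 1.2 mm glass slide, 10-20 um
# sample gap under a 0.17 mm glass coverslip, air backing.
transducer:
  frequency_hz: 1.0e6
  element_radius_m: 9.43e-3
  external_radius_m: 12.5e-3
  focal_distance_m: 60.0e-3
chamber:
  incidence_angle_deg: 26.5
  bath_material: water
  slide_material: glass
  slide_thickness_m: 1.2e-3
  sample_material: water
  gap_m: 15.0e-6
  gap_range_m: [10.0e-6, 20.0e-6]
  coverslip_material: glass
  coverslip_thickness_m: 0.17e-3
  backing_material: air
calibration:
  focal_pressure_pa: 500.0e3
bubble:
  radius_m: 1.5e-6
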