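name,density,c_long,c_shear,alpha0_db_per_cm,f_ref_hz,alpha_exponent,K,G,E
water,1000,1480,0,0.0022,1000000,2,2.1904e9,0,
glass,2500,5600,3400,0.2,1000000,1,3.98667e10,2.89e10,6.98271e10
polystyrene,1050,2350,1120,0.35,1000000,1,,,
adiprene,870,1680,0,1.2,1000000,1,,,
polyethylene,950,1950,540,1.0,1000000,1,,,
air,1.204,343,0,1.6,1000000,2,,,
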