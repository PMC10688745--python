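species,trait,y0,a,b,c,d,e,se_y0,se_a,se_b,se_c,se_d,se_e,r_squared
purple_basil,branch_no,-2.80E1,1.46,,,,,8.00,0.272,,,,,0.658
purple_basil,branch_no,5.58,,8.51E-1,,,,3.72,,3.31E-1,,,,0.174
purple_basil,height_cm,-1.82E2,1.24E1,4.08,-1.94E-1,-9.40E-2,-3.52E-2,1.47E1,9.89E-1,5.89E-1,1.74E-2,1.53E-2,1.81E-2,0.646
purple_basil,fvfm,4.46E-1,2.11E-2,6.1E-3,-3.E-4,,-3.E-4,8.59E-2,5.9E-3,3.2E-3,1.E-4,,1.E-4,0.371
purple_basil,leaf_area_cm2,-6.46E2,5.21E1,1.11E1,-9.06E-1,,-3.38E-1,7.61E1,5.22,2.83,9.11E-2,,9.56E-2,0.540
purple_basil,dmc_g_per_kg,8.26E1,-4.6E-1,,,,,8.61,2.93E-1,,,,,0.087
purple_basil,dmc_g_per_kg,4.85E1,,2.99,,-8.22E-2,,4.92,,8.72E-1,,3.57E-2,,0.419
purple_basil,leaf_mass_fraction,2.75,-1.18E-1,-4.7E-2,1.8E-3,7.E-4,9.E-4,1.30E-1,8.7E-3,5.2E-3,2.E-4,1.E-4,2.E-4,0.615
purple_basil,fresh_mass_g,-3.58E2,2.35E1,,-3.15E-1,,,3.71E2,2.58E1,,4.42E-1,,,0.459
purple_basil,fresh_mass_g,-5.83,,5.52,,,,1.23E1,,1.09,,,,0.420
purple_basil,hue_transformed_deg,-9.94E2,8.23E1,-3.88E1,-1.47,,1.19,9.85E1,6.77,3.67,1.18E-1,,1.24E-1,0.718
purple_basil,chroma,-3.09E1,1.379,,,,,4.33,1.47E-1,,,,,0.601
purple_basil,L_star,5.33E1,-1.71,-6.99E-1,3.98E-2,,1.49E-2,7.98,5.47E-1,2.97E-1,9.6E-3,,1.00E-2,0.687
purple_basil,a_star,2.32E1,-9.19E-1,,,,,2.82,9.60E-2,,,,,0.641
purple_basil,b_star,-3.07E1,1.32,,,,,3.35,1.14E-1,,,,,0.654
sage,branch_no,1.92E1,-8.45E-1,1.103,1.45E-2,,-2.87E-2,6.90,4.73E-1,2.65E-1,8.0E-3,,9.0E-3,0.376
sage,height_cm,-2.02E2,1.55E1,4.06,-2.67E-1,-1.31E-1,-4.82E-2,2.40E1,1.61,9.87E-1,2.84E-2,2.59E-2,3.05E-2,0.367
sage,fvfm,9.04E-1,-2.9E-3,,,,,1.99E-2,7.E-4,,,,,0.251
sage,leaf_area_cm2,3.42E2,-8.33,,,,,2.65E1,9.00E-1,,,,,0.557
sage,dmc_g_per_kg,8.70E1,2.44,,,,,4.29E1,1.46,,,,,0.140
sage,dmc_g_per_kg,1.25E2,,4.20,,,,1.32E1,,1.20,,,,0.461
sage,leaf_mass_fraction,2.37,-1.05E-1,-3.69E-2,1.6E-3,5.E-4,1.0E-3,1.72E-1,1.16E-2,7.1E-3,2.E-4,2.E-4,2.E-4,0.356
sage,fresh_mass_g,-2.55E2,1.70E1,1.26E1,-2.87E-1,-2.21E-1,-1.93E-1,4.99E1,3.35,2.05,5.91E-2,5.68E-2,6.35E-2,0.400
spearmint,branch_no,-3.79E1,2.83,1.12,-4.25E-2,-2.25E-2,-8.0E-3,6.96,4.68E-1,2.61E-1,8.2E-3,6.7E-3,8.1E-3,0.523
spearmint,height_cm,-2.32E2,1.56E1,5.37,-2.46E-1,-9.45E-2,-7.73E-2,2.15E1,1.45,8.07E-1,2.54E-2,2.08E-2,2.50E-2,0.479
spearmint,fvfm,5.40E-1,1.66E-2,8.5E-3,-2.E-4,,-3.E-4,9.09E-2,6.2E-3,3.2E-3,1.E-4,,1.E-4,0.179
spearmint,leaf_area_cm2,-5.49E2,4.18E1,2.18E1,-7.41E-1,-4.61E-1,-3.07E-1,9.45E1,6.35,3.54,1.11E-1,9.12E-2,1.10E-1,0.486
spearmint,dmc_g_per_kg,2.69E2,-1.10E1,-3.38,1.71E-1,,1.23E-1,5.00E1,3.43,1.75,5.97E-2,,5.89E-2,0.063
spearmint,leaf_mass_fraction,2.15,-9.27E-2,-3.33E-2,1.5E-3,9.E-4,2.E-4,1.55E-1,1.04E-2,5.8E-3,2.E-4,1.E-4,2.E-4,0.409
spearmint,fresh_mass_g,-4.18E2,2.52E1,1.33E1,-3.96E-1,-1.86E-1,-1.75E-1,4.91E1,3.30,1.84,5.79E-2,4.74E-2,5.70E-2,0.601
sweet_basil,branch_no,-1.01E1,1.49E-1,4.46E-2,,-7.45E-2,7.01E-2,6.04,1.42E-1,8.51E-1,,3.00E-2,1.41E-2,0.743
sweet_basil,node_no,-1.54,3.01E-1,2.74E-2,-3.8E-3,-1.42E-2,1.05E-2,2.35,1.30E-1,2.12E-1,2.1E-3,7.5E-3,3.5E-3,0.661
sweet_basil,height_cm,-9.47E1,6.81,1.61,-1.11E-1,-1.17E-1,3.95E-2,1.58E1,8.72E-1,1.42,1.38E-2,5.03E-2,2.36E-2,0.478
sweet_basil,leaf_area_cm2,-1.05E3,4.89E1,1.76E2,-6.45E-1,-5.09,-2.32,2.91E2,1.61E1,2.62E1,2.55E-1,9.28E-1,4.36E-1,0.485
sweet_basil,dmc_g_per_kg,6.67E1,,7.16E-1,,,,2.71,,2.75E-1,,,,0.102
sweet_basil,fresh_mass_g,-2.23E2,1.15E1,1.11E1,-1.96E-1,-6.92E-1,2.22E-1,4.35E1,2.41,3.92,3.81E-2,1.39E-1,6.52E-2,0.632
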