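mode,nutrient,weight_class,day_lo,day_hi,recommended
EN,energy_kcal_per_kg,le_2500g,1,3,60
EN,energy_kcal_per_kg,le_2500g,4,7,90
EN,energy_kcal_per_kg,le_2500g,8,,115
EN,energy_kcal_per_kg,gt_2500g,1,3,55
EN,energy_kcal_per_kg,gt_2500g,4,7,85
EN,energy_kcal_per_kg,gt_2500g,8,,110
PN,energy_kcal_per_kg,le_2500g,1,3,45
PN,energy_kcal_per_kg,le_2500g,4,7,75
PN,energy_kcal_per_kg,le_2500g,8,,95
PN,energy_kcal_per_kg,gt_2500g,1,3,40
PN,energy_kcal_per_kg,gt_2500g,4,7,70
PN,energy_kcal_per_kg,gt_2500g,8,,90
EN,protein_g_per_kg,le_2500g,1,3,1.5
EN,protein_g_per_kg,le_2500g,4,7,2.5
EN,protein_g_per_kg,le_2500g,8,,3.5
EN,protein_g_per_kg,gt_2500g,1,3,1.0
EN,protein_g_per_kg,gt_2500g,4,7,2.0
EN,protein_g_per_kg,gt_2500g,8,,3.0
PN,protein_g_per_kg,le_2500g,1,3,2.0
PN,protein_g_per_kg,le_2500g,4,7,3.0
PN,protein_g_per_kg,le_2500g,8,,3.8
PN,protein_g_per_kg,gt_2500g,1,3,1.5
PN,protein_g_per_kg,gt_2500g,4,7,2.5
PN,protein_g_per_kg,gt_2500g,8,,3.0
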