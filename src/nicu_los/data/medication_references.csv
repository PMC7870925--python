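drug,dose_per_kg,dose_unit,frequency_per_day,is_supplement
amikacin,15,mg/kg/dose,1,false
gentamicin,4,mg/kg/dose,1,false
ampicillin,50,mg/kg/dose,2,false
cefotaxime,50,mg/kg/dose,2,false
vancomycin,10,mg/kg/dose,2,false
caffeine_citrate,5,mg/kg/dose,1,false
fluconazole,6,mg/kg/dose,1,false
phenobarbital,4,mg/kg/dose,1,false
vitamin_d,400,IU/dose,1,true
iron,2,mg/kg/dose,1,true
multivitamin,1,ml/dose,1,true
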