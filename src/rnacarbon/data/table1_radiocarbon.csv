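sample_id,medium,sample_kind,surfactant,phenol_ph,tube_size,licl,cscl,fraction_modern,fm_sigma,delta14c,delta14c_sigma,age_reported,age_sigma_reported,modern_class,a260_280,a260_230,pct_dna,pct_dna_censored,rna_ug,year_measured,cams_id
etoh_100,100% EtOH,reagent,none,,none,,,1.0491,0.0037,40.8,3.7,,,greater-than-Modern,,,,,,2015,173559
etoh_depc,100% EtOH & DEPC,reagent,none,,none,,,1.0504,0.0037,42.0,3.7,,,greater-than-Modern,,,,,,2015,173560
ctab_in_water,CTAB in water,reagent,none,,none,,,0.0048,0.0001,-995.2,0.1,42900,170,numeric-age,,,,,,2015,174198
lb_medium,LB,medium,none,,none,,,1.0675,0.0039,59.9,3.7,,,greater-than-Modern,,,,,,2015,143162
acetate_medium,acetate,medium,none,,none,,,0.1414,0.0008,-860.0,1.0,15715,45,numeric-age,,,,,,2015,149428
dextrose_medium,dextrose,medium,none,,none,,,1.0633,0.0035,55.6,3.5,,,greater-than-Modern,,,,,,2015,149098
ecoli_cells,LB,cells,none,,none,,,1.0302,0.0039,24.8,3.9,,,greater-than-Modern,,,,,,2015,174199
ecoli_cells_washed,LB,cells,none,,none,,,1.0321,0.0043,26.6,4.3,,,greater-than-Modern,,,,,,2015,174200
rna_sds_01,LB,extracted-RNA,SDS,7.9,small,no,no,1.0094,0.0070,1.6,7.0,,,greater-than-Modern,,,,,,2015,167573
rna_sds_02,LB,extracted-RNA,SDS,7.9,small,yes,no,1.0021,0.0067,-5.7,6.7,,,Modern,,,,,,2015,167574
rna_sds_03,LB,extracted-RNA,SDS,7.9,small,yes,yes,0.9687,0.0132,-38.7,13.2,260,110,numeric-age,,,,,,2015,167575
rna_sds_04,LB,extracted-RNA,SDS,7.9,small,yes,yes,0.9639,0.0255,-43.5,25.5,300,220,numeric-age,,,,,,2015,167676
rna_ctab66_01,LB,extracted-RNA,CTAB,6.6,small,no,no,0.9711,0.0038,-36.7,3.8,235,35,numeric-age,2.08,2.10,10.6,no,197,2015,176279
rna_ctab66_02,LB,extracted-RNA,CTAB,6.6,small,no,yes,0.9259,0.0061,-81.3,6.1,620,60,numeric-age,1.99,1.99,1.0,yes,,2015,172417
rna_ctab66_03,LB,extracted-RNA,CTAB,6.6,small,no,yes,0.9351,0.0044,-72.2,4.4,540,40,numeric-age,2.06,2.18,1.3,yes,,2015,172418
rna_ctab66_04,LB,extracted-RNA,CTAB,6.6,small,no,yes,0.8836,0.0041,-123.5,4.1,995,40,numeric-age,1.88,2.17,5.0,no,,2015,173313
rna_ctab66_05,LB,extracted-RNA,CTAB,6.6,small,no,yes,0.9297,0.0040,-77.7,4.0,585,35,numeric-age,1.92,2.23,1.0,yes,,2015,173315
rna_ctab66_06,LB,extracted-RNA,CTAB,6.6,small,no,yes,0.9189,0.0089,-88.4,8.9,680,80,numeric-age,1.98,2.34,2.7,no,60,2015,175675
rna_ctab66_07,LB,extracted-RNA,CTAB,6.6,large,no,no,0.9862,0.0038,-21.7,3.8,110,35,numeric-age,2.12,2.07,10.0,no,283,2015,176278
rna_ctab79_lg1,LB,extracted-RNA,CTAB,7.9,large,no,no,0.9854,0.0047,-22.6,4.7,120,40,numeric-age,2.05,1.95,6.8,no,164,2015,176274
rna_ctab79_lg2,LB,extracted-RNA,CTAB,7.9,large,yes,no,1.0000,0.0043,-8.0,4.3,,,Modern,2.07,2.05,0.7,no,127,2015,176277
rna_ctab79_lg3,LB,extracted-RNA,CTAB,7.9,large,yes,no,1.0056,0.0060,-2.5,6.0,,,Modern,2.07,2.00,0.0,no,62,2015,176275
rna_ctab79_sm1,LB,extracted-RNA,CTAB,7.9,small,no,no,1.0236,0.0069,15.7,6.9,,,greater-than-Modern,2.03,2.24,,,83,2015,167569
rna_ctab79_sm2,LB,extracted-RNA,CTAB,7.9,small,yes,no,1.0277,0.0054,19.8,5.4,,,greater-than-Modern,2.05,2.28,4.7,no,143,2015,167570
rna_ctab79_sm3,LB,extracted-RNA,CTAB,7.9,small,yes,no,1.0032,0.0070,-4.7,7.0,,,Modern,2.01,1.72,0.5,no,,2015,169942
rna_ctab79_sm4,LB,extracted-RNA,CTAB,7.9,small,yes,no,1.0125,0.0164,4.3,16.4,,,greater-than-Modern,2.03,2.28,1.6,no,21,2015,176276
rna_ctab79_sm5,LB,extracted-RNA,CTAB,7.9,small,yes,no,1.0145,0.0044,6.3,4.4,,,greater-than-Modern,,,,,340,2015,176271
rna_ctab79_sm6,LB,extracted-RNA,CTAB,7.9,small,yes,yes,1.0120,0.0111,4.2,11.1,,,greater-than-Modern,2.00,2.40,3.8,no,49,2015,167571
rna_ctab79_sm7,LB,extracted-RNA,CTAB,7.9,small,yes,yes,1.0235,0.0043,15.6,4.3,,,greater-than-Modern,2.09,2.10,,,203,2015,167572
rna_acetate,acetate,extracted-RNA,CTAB,7.9,small,yes,no,0.1629,0.0053,-838.4,5.3,14580,270,numeric-age,2.03,2.17,0.6,no,,2015,169940
rna_dextrose,dextrose,extracted-RNA,CTAB,7.9,small,yes,no,1.0460,0.0042,37.8,4.2,,,greater-than-Modern,2.10,2.26,1.1,no,,2015,169941
rna_lq107,groundwater,extracted-RNA,CTAB,7.9,small,yes,no,0.8129,0.0056,-193.4,5.6,1660,60,numeric-age,1.95,2.13,,,,2015,169943
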