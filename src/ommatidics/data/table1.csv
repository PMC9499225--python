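subfamily,genus,species,brightness_mean,brightness_se,brightness_n,foraging_raw,activity_class,eye_area_mean,eye_area_se,eye_area_emm,eye_area_emm_se,facet_count_mean,facet_count_se,facet_count_emm,facet_count_emm_se,facet_diameter_D_mean,facet_diameter_D_se,facet_diameter_D_emm,facet_diameter_D_emm_se,mesosoma_mean,mesosoma_se,emm_covariate_eval_point
Formicinae,Myrmecocystus,christineae,75.2,2.4,4,nocturnal,nocturnal,0.0763,0.0049,0.1196,0.0077,277.5,9.3,384.1,14.2,19.68,0.26,20.81,0.49,1.14,0.04,1.7434
Formicinae,Myrmecocystus,ewarti,72.7,1.7,3,nocturnal,nocturnal,,,,,,,,,,,,,,,
Formicinae,Myrmecocystus,kennedyi,55.9,0.2,3,diurnal,diurnal,0.0463,0.0025,0.0685,0.0058,322.8,11.3,377.6,10.7,13.71,0.22,14.29,0.37,1.43,0.04,1.7434
Formicinae,Myrmecocystus,mendax-03,58.7,4.5,3,diurnal,diurnal,0.0817,0.0048,0.0413,0.0067,457.4,16.3,358.2,12.4,15.85,0.26,14.79,0.43,2.31,0.10,1.7434
Formicinae,Myrmecocystus,mexicanus-01,73.8,1.1,4,nocturnal,nocturnal,,,,,,,,,,,,,,,
Formicinae,Myrmecocystus,mexicanus-02,78.4,4.5,3,nocturnal,nocturnal,0.1609,0.0118,0.1207,0.0067,524.1,21.3,425.1,12.4,21.83,0.50,20.78,0.43,2.31,0.08,1.7434
Formicinae,Myrmecocystus,navajo,74.1,2.8,6,"nocturnal, crepuscular in cooler months",nocturnal,0.1052,0.0068,0.1103,0.0052,349.8,14.5,352.3,9.6,20.27,0.37,20.41,0.33,1.67,0.07,1.7434
Formicinae,Myrmecocystus,testaceus,72.3,1.7,3,nocturnal,nocturnal,,,,,,,,,,,,,,,
Formicinae,Myrmecocystus,yuma,38.7,7.1,3,matinal-crepuscular,variable,0.0378,0.0009,0.0825,0.0079,287.0,4.2,397.1,14.4,13.25,0.21,14.42,0.50,1.12,0.02,1.7434
Myrmicinae,Aphaenogaster,boulderensis,53.7,8.0,2,"crepuscular, nocturnal, matinal",variable,0.0480,0.0000,0.0176,0.0067,147.5,3.5,81.3,18.7,19.88,0.38,18.49,1.03,2.14,0.02,1.5468
Myrmicinae,Aphaenogaster,megommata,76.9,2.9,6,"crepuscular, nocturnal",variable,0.0815,0.0032,0.0745,0.0020,241.4,7.9,226.1,5.7,23.10,0.23,22.78,0.31,1.68,0.03,1.5468
Myrmicinae,Aphaenogaster,occidentalis,46.7,3.4,6,variable,variable,0.0264,0.0008,0.0328,0.0019,79.8,2.1,93.7,5.4,19.58,0.26,19.87,0.30,1.42,0.03,1.5468
Myrmicinae,Aphaenogaster,patruelis,42.4,4.2,9,variable,variable,0.0331,0.0019,0.0388,0.0019,104.1,4.9,116.6,5.3,19.96,0.26,20.22,0.29,1.44,0.02,1.5468
Myrmicinae,Temnothorax,BCA-5,87.3,0.2,2,nocturnal,nocturnal,0.0238,0.0026,0.0201,0.0011,92.2,6.9,80.8,3.7,18.30,0.29,17.76,0.39,0.93,0.06,0.7534
Myrmicinae,Temnothorax,neomexicanus,35.4,2.8,4,crepuscular,variable,0.0109,0.0002,0.0128,0.0006,66.3,0.9,72.0,2.1,13.17,0.16,14.43,0.23,0.67,0.02,0.7534
Myrmicinae,Temnothorax,tricarinatus,39.3,3.2,3,crepuscular,variable,0.0138,0.0003,0.0135,0.0005,89.0,2.1,88.1,1.7,13.46,0.23,13.42,0.10,0.77,0.02,0.7534
Myrmicinae,Veromessor,andrei,40.1,2.2,15,variable,variable,0.0663,0.0045,0.0492,0.0022,198.4,9.1,170.5,4.9,21.00,0.29,20.27,0.29,2.14,0.06,1.8333
Myrmicinae,Veromessor,chamberlini,47.9,4.2,6,diurnal,diurnal,0.0395,0.0013,0.0513,0.0021,126.7,3.2,145.9,4.7,19.60,0.23,20.11,0.28,1.62,0.03,1.8333
Myrmicinae,Veromessor,chicoensis,44.6,2.1,6,variable,variable,0.0678,0.0062,0.0629,0.0019,167.6,10.1,159.6,4.2,21.00,0.26,20.79,0.25,1.92,0.09,1.8333
Myrmicinae,Veromessor,julianus,46.1,4.1,6,crepuscular-nocturnal-matinal,variable,0.0771,0.0038,0.0629,0.0020,198.8,7.7,175.5,4.5,22.07,0.27,21.46,0.26,2.09,0.06,1.8333
Myrmicinae,Veromessor,lariversi,68.5,1.6,9,nocturnal,nocturnal,0.0796,0.0027,0.0920,0.0019,223.5,4.9,243.7,4.4,21.00,0.31,21.53,0.26,1.61,0.05,1.8333
Myrmicinae,Veromessor,lobognathus,50.4,5.0,6,variable,variable,0.0808,0.0024,0.0752,0.0020,223.8,2.4,214.7,4.5,20.98,0.33,20.74,0.27,1.94,0.05,1.8333
Myrmicinae,Veromessor,pergandei,32.3,1.8,4,variable,variable,0.0805,0.0049,0.0771,0.0018,231.9,8.8,226.3,4.0,19.87,0.26,19.72,0.24,1.90,0.06,1.8333
Myrmicinae,Veromessor,RAJ-pseu,65.1,1.6,8,nocturnal,nocturnal,0.0910,0.0016,0.1112,0.0022,250.6,3.6,283.7,4.9,21.17,0.26,22.04,0.29,1.47,0.18,1.8333
Myrmicinae,Veromessor,smithi,55.5,3.9,6,crepuscular-nocturnal,variable,0.1010,0.0035,0.1032,0.0020,240.1,5.8,243.6,4.5,22.52,0.32,22.61,0.26,1.79,0.04,1.8333
Myrmicinae,Veromessor,stoddardi,42.9,1.2,4,crepuscular-nocturnal,variable,0.0483,0.0035,0.0476,0.0018,130.7,6.4,129.5,4.0,20.43,0.31,20.40,0.24,1.85,0.08,1.8333
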