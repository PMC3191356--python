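comparison,level,row_category,n_neg,n_2plus,n_3plus
ve1_vs_ve2,spot,0/1+,475,15,0
ve1_vs_ve2,spot,2+,0,21,4
ve1_vs_ve2,spot,3+,0,4,56
ve1_vs_da,spot,0/1+,458,32,0
ve1_vs_da,spot,2+,4,18,3
ve1_vs_da,spot,3+,0,0,60
ve2_vs_da,spot,0/1+,454,21,0
ve2_vs_da,spot,2+,8,26,6
ve2_vs_da,spot,3+,0,3,57
ve1_vs_ve2,patient,0/1+,129,7,0
ve1_vs_ve2,patient,2+,0,7,1
ve1_vs_ve2,patient,3+,0,1,16
ve1_vs_da,patient,0/1+,122,14,0
ve1_vs_da,patient,2+,0,5,3
ve1_vs_da,patient,3+,0,0,17
ve2_vs_da,patient,0/1+,121,8,0
ve2_vs_da,patient,2+,1,11,3
ve2_vs_da,patient,3+,0,0,17
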