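scenario_id,group,percent_of_mass
S1,legumes,0.00
S1,processed meat,2.78
S1,red meat,5.56
S1,white meat,4.17
S2M1,legumes,0.67
S2M1,processed meat,1.39
S2M1,red meat,4.89
S2M1,white meat,3.47
S2M2,legumes,0.83
S2M2,processed meat,1.39
S2M2,red meat,4.89
S2M2,white meat,4.00
S2M3,legumes,1.11
S2M3,processed meat,2.50
S2M3,red meat,4.89
S2M3,white meat,4.00
S5,legumes,5.56
S5,processed meat,1.39
S5,red meat,2.78
S5,white meat,3.47
S7M1,legumes,6.89
S7M1,processed meat,1.39
S7M1,red meat,1.44
S7M1,white meat,3.47
S8M1,legumes,7.56
S8M1,processed meat,1.39
S8M1,red meat,0.78
S8M1,white meat,3.47
S9M2,legumes,8.89
S9M2,processed meat,0.56
S9M2,red meat,0.78
S9M2,white meat,2.97
S9M3,legumes,10.00
S9M3,processed meat,0.28
S9M3,red meat,0.11
S9M3,white meat,2.81
S10,legumes,11.11
S10,processed meat,0.00
S10,red meat,0.00
S10,white meat,2.78
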