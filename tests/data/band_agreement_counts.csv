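population,group,n_high,n_intermediate,n_low
validation,amMs <9,0,0,4
validation,amMs <=10,0,2,22
validation,amMs <=11,0,7,45
validation,amMs <=12,0,13,84
validation,amMs <=14,0,22,125
validation,amMs <=15,1,36,206
validation,amMs <18,1,63,261
validation,histologic low risk,0,11,56
validation,amMs >30,17,0,0
original,amMs <9,0,0,5
original,amMs <=10,0,2,21
original,amMs <=11,0,5,31
original,amMs <=12,0,9,43
original,amMs <=14,0,12,61
original,amMs <=15,0,26,96
original,amMs <18,0,42,116
original,histologic low risk,0,4,34
original,amMs >30,8,0,0
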