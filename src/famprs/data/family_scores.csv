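family_id,individual_id,affected,wprs,hla_drb1_1501
1,1-3,1,24.38,+/-
1,1-4,1,24.51,+/-
1,1-5,1,25.74,+/+
1,1-7,0,23.40,+/-
1,1-8,0,23.79,+/-
1,1-9,0,23.25,-/-
1,1-10,0,24.56,+/-
2,2-1,1,21.35,-/-
2,2-2,1,21.98,-/-
2,2-3,1,22.71,-/-
2,2-6,1,23.70,-/-
2,2-4,0,22.04,-/-
2,2-5,0,22.46,-/-
3,3-1,1,23.13,-/-
3,3-2,1,22.91,-/-
3,3-3,0,21.98,-/-
3,3-4,0,21.32,-/-
3,3-5,0,21.55,-/-
3,3-6,0,22.66,-/-
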