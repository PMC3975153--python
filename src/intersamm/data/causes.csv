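# Canonical registry of the 10 direct/indirect morbidity cause categories.
code,label,index
puerperal_infection,Puerperal Infection,1
antepartum_haemorrhage,Antepartum Haemorrhage,2
postpartum_haemorrhage,Postpartum Haemorrhage,3
preeclampsia,Pre-eclampsia,4
eclampsia,Eclampsia,5
obstructed_labour,Obstructed Labour,6
uterine_rupture,Uterine Rupture/Pre-rupture,7
anaemia,Anaemia,8
malaria,Malaria,9
other_infection,Other infections,10
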