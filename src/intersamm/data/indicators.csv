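# Canonical registry of the 72 self-reported sign/symptom/care-event indicators.
code,label,index
age_lt20,aged under 20 yrs,1
age_20_34,aged 20 to 34 yrs,2
age_ge35,aged 35 yrs or more,3
first_pregnancy,was this her first pregnancy,4
parity_2_4,has she had 2 to 4 pregnancies,5
parity_gt4,were there >4 previous pregnancies,6
multiple_pregnancy,was this a multiple pregnancy,7
attempted_termination,any attempt to terminate this pregnancy,8
pregnancy_end_lt5m,was she <5 months pregnant at end of pregnancy,9
iv_antibiotics,any IV or IM antibiotics required,10
transfusion_required,any blood transfusion required,11
transfusion_received,any blood transfusion received,12
bedbound_gt1d_pp,was she bedbound for more than 1 day postpartum,13
breathless_ap,breathless carrying out normal activities antepartum,14
breathless_pp,breathless carrying out normal activities postpartum,15
loss_of_consciousness,any loss of consciousness,16
acute_fever_ap,any acute fever before pregnancy end,17
acute_fever_pp,any acute fever after pregnancy end,18
recurrent_fever,any recurrent fever,19
fever_shivering,any shivering with fever,20
fits_ever,did she ever have fits,21
epilepsy_diagnosis,did she have a diagnosis of epilepsy,22
hysterectomy,any hysterectomy,23
hb_lt8,haemoglobin less than 8g/dl,24
anaemia_diagnosis,any diagnosis of anaemia,25
pallor,any pallor,26
jaundice,any jaundice or yellow eyes,27
cyanosis,any cyanosis or blue lips,28
baby_born_alive,was baby delivered alive,29
baby_born_dead,was baby delivered dead,30
abnormal_position,was baby's position abnormal,31
bleeding_first_3m,major bleeding in 1st 3 months of pregnancy,32
bleeding_late_pregnancy,major bleeding >3m & before labour,33
bleeding_during_labour,major bleeding during labour,34
bleeding_after_delivery,major bleeding after delivery,35
raised_bp_pregnancy,was blood pressure raised during pregnancy,36
forceps_ventouse,was delivery by forceps/ventouse,37
caesarean,was delivery by Caesarean,38
delivery_home,was delivery at home,39
delivery_facility,was delivery at a health facility,40
fits_pregnancy_only,were fits only pregnancy related,41
labour_gt24h,was labour prolonged >24 hrs,42
labour_gt48h,was labour prolonged >48 hrs,43
delayed_placenta,was delivery of the placenta delayed,44
manual_removal_placenta,was there manual removal of the placenta,45
professional_assistance,had professional assistance at delivery,46
intended_facility_delivery,intention to deliver at health facility,47
proteinuria,abnormal proteinuria reported,48
visited_multiple_facilities,did she visit more than one health facility,49
intended_home_delivery,intent to deliver at home,50
intended_home_delivered_facility,intend to deliver at home but delivered in facility,51
abdominal_pain_before_labour,any acute abdominal pain before labour,52
abdominal_pain_after_delivery,any acute abdominal pain after delivery,53
previous_caesarean,any previous c-section,54
genital_infection_discharge,genital infection/foul smelling discharge postpartum,55
leaking_membranes,leaking membranes before labour start,56
labour_augmentation,any augmentation of labour,57
persistent_fever_gt3wk,any persistent fever >3 wks,58
swollen_glands,any swollen glands,59
iron_injections,did she require iron injections,60
facial_swelling,any swelling of face,61
blurred_vision,any blurred vision,62
severe_headache_before_labour,any severe headache before labour,63
severe_headache_after_delivery,any severe headache after delivery,64
migraine_history,any history of migraine,65
haemorrhage_diagnosis,any diagnosis of haemorrhage,66
hypertension_diagnosis,any diagnosis of hypertension,67
malaria_diagnosis,any diagnosis of malaria,68
infection_diagnosis,any diagnosis of infection,69
rupture_diagnosis,any diagnosis of rupture,70
delivery_uncomplicated,was delivery said to be uncomplicated,71
self_reported_complication,self-reported delivery complication,72
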