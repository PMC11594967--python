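# Zero-variate observations for Chironomus riparius (single-point data with
# rearing temperature and measurement convention). Ages in d, lengths in cm,
# weights in mg; event ages are since hatch except age_at_birth (since
# oviposition) and age_at_emergence_since_oviposition.
name,observable,value,unit,T_celsius,shape
age_at_birth_21C,age_at_birth,2.0,d,21,alive
time_since_birth_at_puberty_21C,age_at_puberty,7.0,d,21,alive
time_since_birth_at_pupation_21C,age_at_pupation,15.0,d,21,alive
time_since_birth_at_pupation_15C,age_at_pupation,25.0,d,15,alive
time_at_emergence_20C,age_at_emergence,19.3,d,20,alive
length_at_birth,length_at_birth,0.09,cm,21,alive
length_at_pupation,length_at_pupation,1.38,cm,21,dead
initial_egg_dry_weight,egg_dry_weight,0.00099,mg,21,alive
wet_weight_at_pupation,wet_weight_at_pupation,10.0,mg,21,alive
dry_weight_of_imago,imago_dry_weight,1.1,mg,21,alive
duration_instar1_21C,instar1_duration,2.0,d,21,alive
duration_instar2_21C,instar2_duration,2.0,d,21,alive
duration_instar3_21C,instar3_duration,3.0,d,21,alive
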