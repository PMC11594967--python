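# Estimated scaled functional responses per TetraMin ration, by experiment.
# "declining" protocols use f=1 until puberty then a linear decline to f_min
# over 7.5 d; "constant" protocols hold f fixed throughout.
study,ration_mg_per_larva_per_day,protocol,f
current,0.60,declining,1.00
current,0.30,declining,0.58
current,0.15,declining,0.25
current,0.10,declining,0.12
literature_growth,0.40,constant,1.23
literature_growth,0.30,constant,1.00
literature_growth,0.20,constant,0.83
literature_growth,0.10,constant,0.46
literature_sexes,1.40,constant,1.93
literature_temperature_adlib,,constant,1.50
literature_temperature_limited,0.20,constant,0.84
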