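# Chironomus riparius DEB parameter set, reference temperature 20 degC.
# Units: energies J, volumes cm^3, lengths cm, times d, temperatures K.
pAm: 203.0        # J/(d cm^2)  surface-area-specific max assimilation {p_Am}
v: 0.007          # cm/d        energy conductance
kappa: 0.44       # -           allocation fraction to soma
pM: 145.1         # J/(d cm^3)  volume-specific somatic maintenance [p_M]
kJ: 0.036         # 1/d         maturity maintenance rate coefficient
EG: 4018          # J/cm^3      specific cost for structure [E_G]
EHb: 0.003        # J           maturity at birth
EHp: 0.277        # J           maturity at puberty
EHe: 1.072        # J           maturity at emergence
ERj: 5323         # J/cm^3      reproduction buffer density at pupation [E_Rj]
kappaV: 1.1e-6    # -           conversion efficiency E->V->E at pupation
kappaR: 0.95      # -           reproduction efficiency (egg-number formula only)
TA: 6420          # K           Arrhenius temperature
TAH: 18250        # K           Arrhenius temperature, upper boundary
TH: 309.9         # K           upper boundary of the tolerance range
Tref: 293.15      # K           reference temperature (20 degC)
deltaM1: 0.083    # -           shape coefficient, alive measurements
deltaM2: 0.067    # -           shape coefficient, dead measurements
s1: 2.48          # -           Dyar constant, 1st molt
s2: 2.48          # -           Dyar constant, 2nd molt
hb: 0.02          # 1/d         background hazard rate coefficient
kstarv: 3.09      # 1/d         starvation killing rate coefficient
pAmm: 172.3       # J/(d cm^2)  male max assimilation rate {p_Amm}
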