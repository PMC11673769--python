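label,energy_ev,osc_strength,rotatory_strength,ct_character_au,character,target_minimum
S1,5.40,0.20,-10.0,0.00,pipi*G(La),min-pipi*G(La)
S2,5.55,0.28,12.0,0.00,pipi*A,min-npi*A
S4,5.85,0.03,5.0,0.60,CT,min-exciton
S9,6.337,0.05,-3.0,0.80,CT,min-CT
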