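label,energy_ev,osc_strength,rotatory_strength,ct_character_au,character,target_minimum
min-CT,4.60,0.0,0.0,0.70,CT,none
min-pipi*G(La),4.90,0.0,0.0,0.00,pipi*G(La),none
min-npi*A,4.70,0.0,0.0,0.00,npi*A,none
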