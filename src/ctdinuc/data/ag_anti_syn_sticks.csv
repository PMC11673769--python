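label,energy_ev,osc_strength,rotatory_strength,ct_character_au,character,target_minimum
S1,5.35,0.18,9.0,0.00,pipi*G(La),min-pipi*G(La)
S2,5.62,0.36,-14.0,0.40,pipi*A,min-CT
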