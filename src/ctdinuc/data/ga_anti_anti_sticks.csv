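label,energy_ev,osc_strength,rotatory_strength,ct_character_au,character,target_minimum
S1,5.20,0.050,-12.0,0.00,pipi*G(La),min-CT
S2,5.35,0.150,-8.0,0.30,mixed,min-CT
S3,5.50,0.267,30.0,0.10,pipi*G(La),min-pipi*G(La)
S4,5.75,0.020,10.0,0.00,npi*A,min-npi*A
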