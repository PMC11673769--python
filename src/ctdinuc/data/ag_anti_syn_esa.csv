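from_state,delta_e_ev,dipole_sq_au
S1,2.75,0.8
S1,3.40,1.2
S2,2.62,1.5
S2,3.85,1.0
min-CT,2.77,2.5
min-CT,3.92,1.5
min-pipi*G(La),3.47,1.8
min-pipi*G(La),3.88,0.9
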