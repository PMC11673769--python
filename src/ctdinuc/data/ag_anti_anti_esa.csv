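from_state,delta_e_ev,dipole_sq_au
S1,3.42,1.2
S2,2.70,1.0
S2,3.60,0.8
S4,2.90,0.5
S9,2.55,0.6
min-pipi*G(La),3.47,1.8
min-pipi*G(La),3.88,0.9
min-npi*A,2.62,2.0
min-npi*A,3.55,1.0
min-exciton,3.00,1.0
min-CT,2.85,2.0
min-CT,4.00,1.2
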