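from_state,delta_e_ev,dipole_sq_au
S1,2.60,1.5
S1,3.85,1.0
S2,2.65,2.0
S2,3.90,1.2
S3,3.45,1.5
S3,4.05,1.0
S4,2.40,0.8
S4,3.30,0.6
min-CT,2.79,3.5
min-CT,3.95,2.0
min-pipi*G(La),3.47,2.0
min-pipi*G(La),3.88,1.0
min-npi*A,2.50,1.0
min-npi*A,3.60,0.8
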