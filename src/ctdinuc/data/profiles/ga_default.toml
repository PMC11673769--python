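# GA dinucleotide reference run: anti-anti conformer, published study constants
[run]
dinucleotide = "GA"
conformer = "anti-anti"
seed = 7

[broadening]
fwhm_ev = 0.4
shift_ev = -0.65

[scheme]
relax_ps = 0.1
tau_short_ps = 2.7
tau_ct_ps = 170.0
ct_yield = 0.32

[simulate]
irf_fwhm_fs = 30.0
noise_sigma = 0.0
pump_nm = 266.0

[fit]
n_exp = 2
window_ps = [4.0, 45.0]
fix_long = true

[yield]
epsilon_m1cm1 = 1230.0
path_cm = 0.1
c_abs_molar = 8e-6
t_ref_ps = 40.0
band_nm = [500.0, 645.0]
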