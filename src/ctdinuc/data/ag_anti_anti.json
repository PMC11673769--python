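{
 "name": "anti-anti",
 "dinucleotide": "AG",
 "delta_g_ev": 0.0,
 "sticks": "ag_anti_anti_sticks.csv",
 "minima": "ag_anti_anti_minima.csv",
 "esa": "ag_anti_anti_esa.csv",
 "note": "synthetic stand-in stick table; values constructed to satisfy the qualitative constraints of the published study, not computed ab initio"
}
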