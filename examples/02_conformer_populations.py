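"""Boltzmann populations of the stacked conformers at room temperature.

The GA dinucleotide's second conformer lies 0.14 eV above anti-anti,
several times the thermal energy (~0.025 eV at 293 K), so a single
conformer dominates; the AG landscape is closer and mixes two.
"""

from ctdinuc import boltzmann_weights
from ctdinuc.constants import KB_EV_PER_K

print(f"thermal energy at 293 K: {KB_EV_PER_K * 293:.4f} eV")

ga = boltzmann_weights({"anti-anti": 0.0, "anti-syn": 0.14, "syn-syn": 0.25, "syn-anti": 0.33})
print("GA populations:", {k: f"{v:.2%}" for k, v in ga.items()})

ag = boltzmann_weights({"anti-syn": -0.05, "anti-anti": 0.0, "syn-anti": 0.08, "syn-syn": 0.13})
print("AG populations:", {k: f"{v:.2%}" for k, v in ag.items()})

# GA is essentially a one-conformer solution (anti-anti > 99%), while AG
# retains a minor anti-anti fraction next to the dominant anti-syn form.
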