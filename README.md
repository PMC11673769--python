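# ctdinuc

Charge-transfer photophysics of stacked adenine/guanine dinucleotides:
from quantum-chemistry stick tables and femtosecond transient-absorption
matrices to decay-associated spectra and charge-transfer quantum yields.

## The problem

UV photons absorbed by DNA can push an electron from one stacked base to
its neighbour, creating an excited charge-transfer (CT) state
(G⁺→A⁻ in the systems treated here). These states are precursors of
low-energy photoionization and oxidative damage, and how efficiently they
form depends on strand polarity: the dinucleotide 5′-dGpdA-3′ (**GA**)
funnels roughly twice as many absorbed photons into its CT state as
5′-dApdG-3′ (**AG**). This package implements, as a tested pipeline, the
computational chain used to establish that result:

* **electronic_structure** — validated containers for per-conformer stick
  data (vertical energies E_i, oscillator strengths f_i, rotatory
  strengths R_i, Mulliken CT characters δq, excited-state→excited-state
  lines ΔE_ij, |μ_ij|²), Boltzmann conformer populations
  w_i ∝ exp(−ΔG_i/k_BT), and f = (2/3)·ΔE[a.u.]·|μ|².
* **spectra** — stick→band construction: each transition is shifted by a
  fixed calibration (−0.65 eV) and dressed with a unit-area Gaussian of
  0.4 eV FWHM in the energy domain; builders for absorption, CD,
  excited-state absorption (ESA), the pump-weighted Franck–Condon
  superposition at 266 nm, and thermal-difference/hypochromism analysis.
* **kinetics** — synthetic-data generator: first-order compartment schemes
  (dc/dt = Kc, solved by matrix exponential), closed-form convolution with
  a ~30 fs Gaussian instrument response, Beer–Lambert signal assembly
  DA(t,λ) = Σ_k c_k(t)·ε_k(λ)·l·c_abs, seeded Gaussian noise.
* **global_analysis** — decay-associated spectra (DAS) by
  variable-projection global fitting of DA(t,λ) = Σ_k A_k(λ)e^(−t/τ_k)
  over a late window (default 4–45 ps), with optional fixed lifetimes.
* **quantum_yield** — Φ_CT = DA₀/(ε·l·c_abs) with
  DA₀ = DA_t/exp(−t/τ_CT) read from the low-energy CT band peak at 40 ps
  (ε = 1230 mol⁻¹L cm⁻¹, l = 1 mm, c_abs = 8×10⁻⁶ mol L⁻¹).
* **pipeline / cli** — TOML-configured end-to-end runs
  (`ctdinuc {spectra,simulate,fit,yield,run}`) with deterministic,
  hash-stamped reports.

The packaged stick tables are *synthetic stand-ins*: they are constructed
to satisfy the qualitative constraints established for these systems (see
`docs/methods.md`), not computed ab initio.

## Worked example

```python
import ctdinuc as cd
from ctdinuc.quantum_yield import YieldConfig

tas = cd.reference_tas("GA", noise_sigma=1e-5, seed=7)   # synthetic matrix
das = cd.fit_das(tas, n_exp=2, fixed={1: 170.0}, window_ps=(4.0, 45.0))
phi = cd.extract_yield(cd.reference_tas("GA"), YieldConfig(tau_ct_ps=170.0))
print(das.lifetimes_ps, phi.phi_ct)
```

Running `python examples/04_global_analysis.py` and
`python examples/05_quantum_yield.py` prints:

```
tau =   2.71 ps          DAS extreme +7.51e-04 OD at 434 nm
tau = 170.00 ps (fixed)  DAS extreme +3.19e-04 OD at 581 nm
residual rms: 9.86e-06 OD (noise sigma 1e-5)

AG: band peak 585 nm, DA(40 ps) = 1.238e-04, DA(0) = 1.770e-04, phi_CT = 0.180 ...
GA: band peak 579 nm, DA(40 ps) = 2.487e-04, DA(0) = 3.147e-04, phi_CT = 0.320 ...
GA yield exceeds AG by 78%
```

The short DAS lifetime (2.71 ps vs the generating 2.7 ps) belongs to the
relaxed pipi\*G(La) minimum; the fixed 170 ps component carries the CT band
above 500 nm. The yield chain recovers the generating quantum yields 0.18
(AG) and 0.32 (GA) from the simulated matrices, and the residual rms sits
at the injected noise floor. Each script in `examples/` demonstrates one
capability end to end.

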