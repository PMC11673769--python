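# Methods

## Model overview

The package treats the photophysics of a stacked purine dinucleotide as a
three-stage chain and implements each stage as an independently testable
operation.

1. **Vertical excitation.** Each conformer (anti/anti, anti/syn, ... of the
   glycosidic bonds, 5′ base first) is described by a table of vertical
   transitions: energy, oscillator strength, rotatory strength, Mulliken
   charge-transfer character δq ∈ [0, 1], and the excited-state minimum the
   state relaxes to. Conformer abundances follow Boltzmann statistics on
   the relative ground-state energies, with k_B = 8.617333262×10⁻⁵ eV/K
   and room temperature taken as 293 K (thermal energy 0.0252 eV).
2. **Spectra.** Stick data become bands through a fixed additive
   calibration of the transition energies (default −0.65 eV, the offset
   that aligns the computed lowest bright state of deoxyguanosine with
   experiment; it absorbs, among other things, the missing vibronic
   structure) followed by a unit-area Gaussian of 0.4 eV FWHM per stick in
   the **energy** domain. Excited-state absorption uses the same shift and
   width, with stick intensities f = (2/3)·ΔE[hartree]·|μ|²[a.u.] from the
   excited-state→excited-state dipoles.
3. **Kinetics and observables.** Excitation at the pump wavelength
   populates Franck–Condon states in proportion to the value of their
   broadened band at the pump energy. Populations then follow first-order
   kinetics through the relaxation cascade (FC → minimum → ground) and the
   differential absorbance is the population-weighted, Beer–Lambert-scaled
   sum of species spectra convolved with the instrument response.

## Numerical choices

* **Wavelength sampling without Jacobian.** Bands are Gaussian in energy
  and sampled at wavelength grid points with no |dE/dλ| reweighting, the
  usual convention when computed spectra are overlaid on
  wavelength-axis experiments. A `jacobian` toggle on `BroadeningConfig`
  applies the factor for users who want per-nm densities.
* **Default grids.** 200–350 nm at 0.5 nm for steady-state/CD; 330–650 nm
  at 1 nm for transient spectra (the white-light probe range); delay axis
  −0.3 to 2 ps at 20 fs then quasi-logarithmic to 450 ps.
* **Propagation.** `propagate` uses the matrix exponential of the rate
  matrix (columns sum to zero; explicit absorbing ground compartment).
  The simulator decomposes the scheme into exponential eigenmodes and
  convolves each with the Gaussian instrument response in closed form
  (exp×Gauss → erfc, evaluated through erfcx where the naive expression
  overflows), so simulated matrices are exact to machine precision.
  Oscillatory (complex-eigenvalue) schemes are rejected — physical decay
  cascades have real spectra.
* **Variable projection.** At each trial lifetime vector the amplitudes
  are solved per wavelength by linear least squares and only the (log of
  the) free lifetimes are searched nonlinearly (Levenberg–Marquardt,
  ftol/xtol 10⁻¹⁴, at most 500 evaluations per start). Three starts from
  a log-spaced ladder across the fit window scaled by 0.3/1/3 guard
  against local minima; the fit is deterministic for given data.
  Lifetimes are reported ascending, fixed values untouched. Before
  fitting, the windowed matrix's singular values are checked: if its
  numerical rank (relative threshold 10⁻¹⁰) is below the requested number
  of exponentials, a degeneracy diagnostic is raised instead of returning
  an unidentifiable fit; the same happens if the design matrix at the
  optimum is singular.
* **No IRF in the fit model.** The default window starts at 4 ps, two
  orders of magnitude after the ~30 fs response and well after the ~100 fs
  relaxation, so plain exponentials are adequate; early delays are
  deliberately excluded rather than deconvolved.
* **Yield extraction.** The CT amplitude is the band *maximum* within
  500–645 nm of the spectrum at the delay nearest t_ref (default 40 ps,
  with the 15 ps variant of the same formula available through the
  config), not a band integral — matching how peak intensities are read.
  On noisy data the max statistic is biased upward by roughly the noise
  amplitude; the reference extraction therefore uses noise-free synthetic
  matrices, and yields from measured data should be read from smoothed or
  fitted band shapes. Extracted yields are annotated as upper limits
  because the computed CT band is more intense than the free radical-ion
  band whose ε calibrates the chain.

## The synthetic-data generator

`reference_scheme`/`reference_tas` encode one profile per dinucleotide:

| quantity | AG | GA |
|---|---|---|
| dominant conformer | anti-syn | anti-anti |
| short (pipi\*G(La)) lifetime | 4.5 ps | 2.7 ps |
| CT recombination lifetime | 112 ps | 170 ps |
| CT formation yield Φ_CT | 0.18 | 0.32 |

with shared constants: 266 nm pump, 30 fs IRF, 100 fs FC→minimum
relaxation, 1 mm path, 8×10⁻⁶ mol/L absorbed photons,
ε = 1230 mol⁻¹L cm⁻¹ for the CT band, noise default 10⁻⁵ OD (1% of the
10⁻³ OD signal ceiling), seeded and mandatory whenever noise is nonzero.
The CT species spectrum is scaled so the zero-time CT-band amplitude
equals Φ_CT·ε·l·c_abs — the profile's yield is therefore the ground truth
a correct extraction chain must recover, and the yield targets are exact
round-trips up to the ~0.1% distortion introduced by the finite 100 fs
rise. Short-lived FC and pipi\*/npi\* bands are given plausible molar
scales (1500–2000 M⁻¹cm⁻¹) chosen to keep the full matrix below 10⁻³ OD.

The FC→minimum rise is modelled as a single exponential; only the timing
(~100 fs) is constrained by observation, not the functional form, so the
rate is a configurable parameter of the scheme builder.

What the generator does **not** emulate: coherent artifacts around time
zero (the fit window starts at 4 ps for the same reason the analysis of
measured data does), solvated-electron and two-photon contributions,
polarization anisotropy (signals are magic-angle by construction),
ground-state bleach and stimulated emission (available only as an explicit
`gsb` term, off by default — computed transient spectra are ESA-only),
wavelength-dependent noise, and chirp of the white-light probe. Passing
tests on these matrices therefore validates the *analysis chain*
(identifiability of the lifetimes, correctness of the extraction algebra),
not the photophysical assignments themselves.

## Packaged stick tables

The per-state energies and intensities of the real systems live in
unpublished appendix material; the packaged CSVs are **synthetic**
stand-ins constructed once to satisfy every constraint established for
these systems: GA anti-anti has four FC states with oscillator strengths
spanning 0.020–0.267, S1/S2 feeding a δq = 0.7 CT minimum, S3 → the
pipi\*G(La) minimum and S4 (npi\*A) → its own minimum; AG anti-syn has S2
reaching a δq = 0.4 CT minimum; AG anti-anti reaches a CT minimum only
through a high-lying state at 218 nm on the calibrated scale (outside the
pump bandwidth); AG absorption maxima sit blue of GA and are more intense;
the GA CD shows a negative then a positive lobe from long wavelengths; the
GA CT minimum's low-energy ESA band is blue-shifted and more intense than
that of its Franck–Condon precursor; and the pump-weighted GA FC
superposition exceeds AG at both edges of the probe window. Any table
satisfying the schema can be substituted; the pipeline is correct for any
valid input.

## Design decisions taken where the procedure was open

* Pump weighting uses the broadened band value at exactly 266 nm; an
  overlap integral with a Gaussian laser spectrum is available
  (`laser_fwhm_nm`) but off by default, since the measured laser spectrum
  is not tabulated.
* CD is produced in arbitrary (rotatory-strength) units for shape-level
  comparison; no conversion to Δε or millidegrees.
* The relative-excess statistic is computed from the yields as given;
  applied to the rounded yields 0.32/0.18 it returns 77.8%, which differs
  from ratios quoted from unrounded band amplitudes.
* Energies are stored unshifted; the calibration is applied only at
  spectrum construction, so tables survive round-trips unmodified.
* Hartree↔eV fixed at 27.211386; photon conversion E[eV] = 1239.84198/λ[nm].

## Problem sizes

The reference matrices are 255 delays × 321 wavelengths; the windowed
fits use ~19 900 (4–45 ps) and ~37 900 (4–400 ps) residuals. The full
test suite, including a 50-realization lifetime-recovery study and
200 random yield round-trips, runs in a few seconds on one core.

## Known limitations

* Lifetime uncertainties are not propagated into the yields (the ±10 %
  bands on τ_CT translate into a comparable relative yield uncertainty
  through the 40 ps extrapolation).
* The fit reports no per-parameter confidence intervals; model adequacy
  is judged through residual traces and the AIC across `n_exp`.
* Target (compartment-constrained) analysis, lifetime-density methods and
  sub-ps deconvolution are out of scope.
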