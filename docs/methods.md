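# Methods

## Models and procedures

### First-order kinetics

Two PSII processes are treated as single exponentials
v(t) = baseline + amplitude·exp(−k t):

* **S₂Q_A⁻ recombination.** After a single turnover flash in the presence
  of DCMU (which blocks Q_A⁻ → Q_B electron transfer), the fluorescence
  yield decays as the trapped charge recombines. The record spans 0.3 ms
  to 120 s on a logarithmic grid, matching single-flash fluorometers.
  The baseline is fixed at 0 (the decay is complete at 120 s for rate
  constants of order 0.1 s⁻¹).
* **Photoinhibition (k_PI).** With lincomycin blocking D1 repair, the
  light-saturated oxygen-evolution rate decays to zero; the rate constant
  of that decay is the rate of the damaging reaction. Fits use a baseline
  fixed at 0: the inhibited decay is complete, and floating a baseline on
  seven points (10-min sampling over 1 h) would be poorly constrained.

`fit_first_order` uses derivative-based nonlinear least squares (lmfit /
MINPACK). The automatic initializer is k₀ = ln 2 / t½, where t½ is the
first sample at which the signal has lost half its initial amplitude; on
non-convergence the fit restarts once at 10× and once at 0.1× k₀. Inputs
with all values equal raise an explicit "no decay" error rather than
returning a degenerate fit; non-convergence raises an error carrying the
last iterate. Rate constants are bounded positive.

### Damage–repair equilibrium

Without lincomycin, active centres A are lost at rate k_PI and restored at
rate k_rec from the inactive pool (A₀ − A):

    dA/dt = −k_PI·A + k_rec·(A₀ − A)

with closed form A(t) = A_eq + (A₀ − A_eq)·exp(−(k_PI + k_rec)·t) and
A_eq = A₀·k_rec/(k_PI + k_rec). `fit_damage_repair` holds k_PI at the
value fitted from the parallel +lincomycin series — the standard
identification strategy, since (k_PI, k_rec, A₀) are not jointly well
constrained by a single plateauing curve — and estimates (A₀, k_rec);
A_eq follows from the model identity. The closed form is verified against
direct ODE integration in the test suite (agreement to 10⁻⁶ relative).

### Randall–Wilkins thermoluminescence

A single trap emptied by first-order kinetics during a linear ramp gives
I(T) = k(T)·n(T) with k(T) = s·exp(−E_a/(k_B T)) and n(T) depleted
self-consistently (the conservation-integrating form: the emitted
intensity is the rate of the reaction, so ∫I dt = n₀ − n(T_end)). The
simulator integrates k by trapezoidal quadrature on a uniform grid
(default 0.01 K; the integrand is smooth, so the quadrature error is far
below the 0.1 °C reporting precision, and charge conservation holds to
better than 10⁻⁶·n₀).

Defaults: E_a = 501 meV, ramp 274→340 K at β = 0.66 K s⁻¹, n₀ = 1 (the
initial population is unknown and only relative intensities matter).
Temperatures are kelvin internally; peak positions are reported in °C
(offset 273.15), matching how glow bands are quoted.

The band peak satisfies β·E_a/(k_B·T_m²) = k(T_m). `solve_peak_condition`
finds T_m by bracketed root finding on the ramp; `s_from_peak` inverts the
condition in closed form, which is how the fixture generator places a band
at a requested peak temperature. A smaller s shifts T_m up and widens the
band — the mechanism proposed for the wider, upshifted B band of EL cells.

**Half widths.** `band_features` locates the peak by parabolic
interpolation through the three grid points around the argmax and finds
half-maximum crossings by linear interpolation on each flank. With the
default parameter set the band is wide (FWHM of order 30 K at
E_a = 501 meV) and its low-temperature half-maximum lies *below* the
274 K ramp start, so the full width is undefined for the recorded curve.
In that case `fwhm` is NaN and `hwhm` is reported as the descending-flank
half width T_half,right − T_peak, which is always defined for a band that
decays within the ramp and preserves the diagnostic ordering (HWHM
strictly decreasing in s). When both flanks are inside the ramp,
`hwhm = fwhm/2` as usual.

### Fluorescence features

* F₀ is operationalized as the earliest recorded sample of the induction
  trace (induction fluorometers report the first reliable point, tens of
  microseconds in). F_M is the global maximum, t_Fm its time; a trace
  still rising at its last sample is flagged truncated.
* OJIP step levels are read at the conventional J = 2 ms and I = 30 ms by
  linear interpolation on a logarithmic time axis.
* The 77 K PSII/PSI ratio uses band maxima in 675–700 nm (PSII) and
  705–725 nm (PSI), windows bracketing the classic ~686 nm and
  ~713–720 nm emission peaks. The ratio is scale invariant and therefore
  unchanged by the 713 nm normalization. Whether the published ratios
  used band maxima or fixed wavelengths is not documented; band maxima
  are adopted, and for the synthetic spectra the two coincide to within
  the 0.5 nm grid.

### Assays

* **Pigments.** Wellburn methanol equations (1–4 nm spectrophotometer
  resolution set): chl a = 16.72·A₆₆₅.₂ − 9.16·A₆₅₂.₄,
  chl b = 34.09·A₆₅₂.₄ − 15.28·A₆₆₅.₂,
  carotenoids = (1000·A₄₇₀ − 1.63·chl a − 104.96·chl b)/221, all scaled by
  the dilution factor. The map is linear through the origin; genuinely
  negative outputs (possible for noisy near-zero absorbances) are clipped
  to 0 with a warning. The coefficients are pinned as module constants.
* **SOSG slope.** The probe signal is sampled once per 10-min
  illumination period, so each period's slope is the endpoint difference
  quotient, and the statistic is the mean over three consecutive periods
  — not a regression, which would be overkill for one point per boundary.
  It is invariant to additive offsets.
* **Growth table.** A culture counts as acclimated at horizon h if its
  OD₇₃₀ reached 0.05 at any sampled time up to h; horizons are cumulative
  (monotone percentages), the natural reading of daily monitoring.

## Synthetic data: what it emulates and what it does not

Each generator produces the *shape* of the corresponding instrument
record with the preset phenotype value built in, so that the analysis
operator recovers that value — exactly with noise off, within a
Monte-Carlo tolerance (mean bias < 5 % at σ = 0.01 over 50 seeds) with
noise on. Presets: `control` (k_recomb 0.24 s⁻¹, k_PI 1.47×10⁻³ s⁻¹,
F₀/F_M 0.24, PSII/PSI 1.5, Q/B bands 15.5/20.0 °C, equilibrium O₂ rate
21.57 µmol O₂ µg Chl⁻¹ h⁻¹, chl 11.08 µg ml⁻¹ at OD₇₃₀ 0.5, 80 %
acclimation by 96 h) and `EL` (0.08 s⁻¹, 1.38×10⁻³ s⁻¹, 0.70, 0.95,
13.6/21.6 °C, 22.29, 3.89 µg ml⁻¹, 56.7 %).

Deliberately phenomenological choices, pinned as constants:

* **OJIP shape.** Sums of sigmoids in log time (control: O–J, J–I, I–P
  components; EL and +DCMU: a single O–J rise, since no J–I transition is
  resolved in EL cells), normalized to reach F_M exactly at t_Fm = 161 ms
  and declining after the peak (strongly for EL). Only F₀, F_M, t_Fm and
  the qualitative morphology are meaningful; step amplitudes and sigmoid
  widths are unconstrained by any measurement.
* **−DCMU flash decay.** Biexponential with a fast Q_A⁻ → Q_B phase at
  300 s⁻¹ and fast-phase fraction 0.55 (control) / 0.75 (EL); invented
  values that reproduce the observed ordering (the fast phase is larger
  in EL cells), not measured rates.
* **77 K spectra.** Two Gaussian bands (686 nm / σ = 8 nm; 713 nm /
  σ = 12 nm). Band widths are not measured quantities; the PSII amplitude
  is solved numerically so the *measured* band-maximum ratio equals the
  preset after the bands overlap — the enforcement is on the statistic,
  not the amplitudes.
* **Photoinhibition fixtures.** A₀ = 50 µmol O₂ µg Chl⁻¹ h⁻¹ is
  arbitrary (only equilibrium rates are phenotype-pinned); without
  lincomycin, k_rec is derived from k_PI and the preset plateau via the
  equilibrium identity.
* **Growth curves.** OD₇₃₀ at 0/24/48/96 h starting at exactly 0.01, with
  a universal first-day dip (cell death on transfer). A seeded draw marks
  round(fraction·n) cultures as acclimating; these cross OD 0.05 between
  48 h and 96 h, the rest stay below. Jitter amplitudes are chosen so the
  threshold classification is deterministic given the draw.
* **SOSG.** Piecewise linear; the control slope is 1.0 a.u. min⁻¹ on an
  arbitrary scale — only the EL/control ratio (10.2 %) is meaningful.
* **Noise.** Additive i.i.d. Gaussian, seed mandatory when enabled;
  glow-curve noise is clipped at zero (photon counts).

Because the generators encode the phenotype constants by construction,
passing roundtrip tests demonstrates that the *analysis operators* are
correct and unbiased for data of the assumed shape — not that real
measurements have that shape. Features of real records that are not
emulated: multiphasic recombination beyond one or two exponentials,
baseline drift, detector nonlinearity, S-state heterogeneity in
thermoluminescence, overlapping vibronic structure at 77 K, and biological
replicate scatter.

## Numerical choices

* Temperature grid 0.01 K (glow curves); peak roundtrip error is bounded
  by the grid spacing and verified by grid-refinement tests.
* Peak-condition root finding: Brent's method, xtol 10⁻⁴ K.
* 77 K amplitude solve: Brent's method on the measured-ratio residual,
  xtol 10⁻¹², bracket (10⁻⁹, 100).
* Fits: MINPACK Levenberg–Marquardt via lmfit with analytic-free
  numerical Jacobians; rate constants bounded below by 10⁻¹⁵.
* Degenerate inputs fail loudly: constant series ("no decay"), bands
  peaking at a ramp endpoint ("truncated band"), non-positive F₀,
  missing SOSG period boundaries, empty growth-curve lists.

## Problem sizes

Default fixtures are deliberately small: 200-point flash decays,
~260-point OJIP traces and 77 K spectra, 7-point photoinhibition series
(10-min sampling over 1 h), 6601-point glow curves, 30-culture growth
experiments. The whole roundtrip report runs in a couple of seconds on a
single core.

## Known limitations

* Single-trap, first-order thermoluminescence only; no fitting of
  measured glow curves to extract (s, E_a) — the package simulates and
  characterises bands, it does not deconvolve experimental ones.
* No multi-component deconvolution of recombination kinetics; the −DCMU
  biexponential fixture is analyzed only qualitatively (slow-tail fits
  with a floating baseline are possible via the generic fitter but are
  not a calibrated procedure).
* No light-intensity dependence of k_PI; no NPQ analysis or spectral
  Gaussian decomposition; no hypothesis testing between conditions.
* The acclimation table assumes cumulative horizons; percentages at 24 h
  and 48 h for synthetic data reflect the generator's simple two-class
  growth model, and only the 96 h column is phenotype-pinned.
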