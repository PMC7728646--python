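# photoacclim

Kinetic and spectral analysis of how the green alga *Chlamydomonas
reinhardtii* acclimates to extreme light (≈1.5× full sunlight, PPFD
3000 µmol m⁻² s⁻¹). The package implements the quantitative procedures used
to characterise the acclimated ("EL") phenotype against moderate-light
controls, together with a synthetic instrument-data generator so the entire
simulate → analyze → fit pipeline runs with no external dataset.

## What it computes

**First-order kinetics** (`photoacclim.kinetics`). Both the decay of
chlorophyll *a* fluorescence after a single turnover flash (+DCMU, probing
S₂Q_A⁻ charge recombination) and the loss of oxygen evolution under
photoinhibitory light (+lincomycin, probing the damaging reaction of
photoinhibition) follow v(t) = A·exp(−kt); `fit_first_order` estimates k by
nonlinear least squares. Without lincomycin, damage competes with repair:

    dA/dt = −k_PI·A + k_rec·(A₀ − A)  ⇒  A(t) = A_eq + (A₀ − A_eq)·e^−(k_PI+k_rec)t,
    A_eq = A₀·k_rec/(k_PI + k_rec)

`fit_damage_repair` recovers (A₀, k_rec) with k_PI fixed from the
+lincomycin experiment and reports the equilibrium activity A_eq.

**Thermoluminescence** (`photoacclim.thermoluminescence`). Randall–Wilkins
simulation of a first-order glow band, I(T) = k(T)·n(T) with
k(T) = s·exp(−E_a/(k_B T)) during a linear ramp (default E_a = 501 meV,
274→340 K at 0.66 K s⁻¹), plus the analytic peak condition
β·E_a/(k_B·T_m²) = k(T_m) solved in both directions, and glow-band feature
extraction (peak, half widths, integral).

**Fluorescence features** (`photoacclim.fluorescence`). Double
normalization of flash decays; OJIP induction landmarks (F₀, F_M, F_V/F_M,
t at F_M, J/I steps); 77 K emission spectra normalized at 713 nm and the
PSII/PSI band-maximum ratio.

**Assays** (`photoacclim.assays`). Wellburn pigment equations for methanol
extracts, the SOSG singlet-oxygen slope statistic, oxygen-rate
normalizations per chlorophyll and per OD₇₃₀, and threshold-crossing
summaries of OD₇₃₀ growth curves.

**Synthetic data** (`photoacclim.synthetic`). Generators for every signal
above, parameterized by the `control` / `EL` presets in
`photoacclim.presets`, deterministic given a seed.

## Worked example

```python
from photoacclim import (EL, gen_flash_decay, double_normalize_decay,
                         fit_first_order)

series = gen_flash_decay(EL, with_dcmu=True)           # 0.3 ms – 120 s decay
norm = double_normalize_decay(series, F0_pre=0.0,
                              Fmax=float(series.values.max()))
fit = fit_first_order(norm, role="recombination")
print(f"k = {fit.k:.4f} s^-1, half-life {fit.halflife:.1f} s")
```

prints

```
k = 0.0800 s^-1, half-life 8.7 s
```

i.e. S₂Q_A⁻ recombination in extreme-light-acclimated cells is threefold
slower than the control value of 0.24 s⁻¹ — the EL phenotype's key kinetic
signature. The same end-to-end comparison for every phenotype constant is
available from the command line:

```sh
photoacclim reproduce-paper --seed 1
```

which prints a table of expected (preset) versus recovered (analyzed)
values for both conditions: recombination and photoinhibition rate
constants, F_V/F_M, 77 K PSII/PSI ratios, thermoluminescence band peaks,
equilibrium oxygen rates, acclimation percentages and the SOSG ratio.

The CLI also exposes the individual stages, e.g.

```sh
photoacclim simulate ojip --preset EL --out ojip.tsv
photoacclim analyze ojip ojip.tsv        # {"FvFm": 0.30, "t_Fm_ms": 161.0, ...}
photoacclim simulate glow --s 1.7e7 --out glow.tsv
photoacclim analyze glow glow.tsv
```

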