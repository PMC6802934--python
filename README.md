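# bilayergate

Analysis toolkit for studies of **hydrophobic matching** between lipid
bilayers and membrane channels — the interplay between a bilayer's
hydrophobic thickness and the gating of a potassium channel such as KcsA.
It covers the three quantitative legs such a study stands on:

1. **Bilayer structure from SAXS.** Lamellar quasi-Bragg peaks in I(q) are
   fitted with Lorentzians; the form factor of order *h* is
   F(h) = √(peak area); the relative electron-density profile is the signed
   cosine series ρ\*(z) = Σ<sub>h</sub> ±F<sub>h</sub> cos(2πhz/d); and the
   profile is parameterised by a **tri-Gaussian model** — headgroup
   Gaussians at ±z<sub>H</sub> (width σ<sub>H</sub>) and a negative
   hydrocarbon-core Gaussian (width σ<sub>C</sub>, relative amplitude
   ρ<sub>r</sub>):

   ρ(z) = e<sup>−(z−z_H)²/2σ_H²</sup> + e<sup>−(z+z_H)²/2σ_H²</sup> − ρ_r e<sup>−z²/2σ_C²</sup>

   Derived thickness measures: FWHM<sub>H</sub> = 2√(2 ln 2) σ<sub>H</sub>,
   d<sub>c</sub> = z<sub>H</sub> − FWHM<sub>H</sub>/2 (hydrophobic
   half-thickness), 2d<sub>c</sub>, d<sub>hh</sub> = 2z<sub>H</sub>,
   d<sub>b</sub> = d<sub>hh</sub> + FWHM<sub>H</sub>, and the water layer
   d<sub>w</sub> = d − d<sub>b</sub>.

2. **Geometric observables of coordinate frames.** After aligning the
   channel's pore axis to +z: helix tilt (endpoint Cα chord vs the axis),
   helix kink (180° minus the angle between the lower and upper segment
   vectors), hydrophobic helix length (|Δz| of the endpoints), the
   **radial hydrophobic thickness profile** (leaflet-resolved mean
   separation of the first acyl-chain carbons, binned in annuli around the
   pore), and selectivity-filter **carbonyl flip states**.  Time-series
   error bars use **blocking transforms** (iterated pairwise averaging,
   robust to autocorrelation).

3. **Single-channel and flux statistics.** Current levels from a
   two-Gaussian fit of the all-points histogram, half-amplitude threshold
   idealization with a dead time, open probability, unitary conductance
   from the i–V slope, **left-truncated exponential dwell-time mixtures**
   fitted by EM with BIC model selection, and valinomycin-normalized
   ⁸⁶Rb⁺ uptake.

Because raw experimental data for such studies are rarely deposited, the
package ships first-class, seeded **synthetic-data generators**
(`bilayergate.synthetic`) that emulate each input — lamellar scattering
curves, deformable pseudo-membranes, ideal helices, two-level Markov
channel currents, uptake kinetics — and attach their ground truth so every
estimator is validated by parameter recovery.

## Worked example

```python
import warnings
from bilayergate import TriGaussianParams, analyze_curve, detect_levels, \
    idealize, open_probability, structure_from_zh_fwhm
from bilayergate.saxs import average_exposures
from bilayergate.synthetic import gen_markov_trace, gen_trigaussian_saxs

# --- bilayer structure from a (synthetic) lamellar scattering curve
truth = TriGaussianParams(z_H=20.0, sigma_H=3.0, rho_r=0.8, sigma_C=6.0)
exposures = [gen_trigaussian_saxs(truth, d_space=63.0, n_orders=4,
                                  noise_sd=0.27, seed=100 + e)[0]
             for e in range(10)]
report = analyze_curve(average_exposures(exposures), n_orders=4)
print(report.trigaussian.summary())

# --- single-channel gating from a (synthetic) two-level current trace
trace, gt = gen_markov_trace(open_rate=40.0, close_rate=10.0, i_unitary=2.0,
                             noise_sd=0.2, fs=50000.0, duration=10.0, seed=7)
levels = detect_levels(trace)
ideal = idealize(trace, levels, dead_time=0.3)
print(f"i_unitary = {levels.i_unitary:.2f} pA   "
      f"P_open = {open_probability(ideal):.3f}")

# --- derived thickness measures from measured bilayer parameters
row = structure_from_zh_fwhm(z_H=20.2, fwhm_H=15.4, d_space=65.9)
print(f"d_c = {row.d_c:.1f} A   2d_c = {row.hydrophobic_thickness:.1f} A")
```

prints

```
Tri-Gaussian electron-density fit
==========================================
z_H (A)           20.000  +/- 0.000
sigma_H (A)        3.120  +/- 0.000
rho_r              0.800  +/- 0.000
sigma_C (A)        6.034  +/- 0.000
FWHM_H (A)         7.347
...
i_unitary = 2.00 pA   P_open = 0.785
d_c = 12.5 A   2d_c = 25.0 A
```

The first block recovers the generator's tri-Gaussian parameters through
the full peak-fitting → form-factor → reconstruction → model-fit chain
(z_H exactly, σ_H within 4%); the gating block recovers the simulator's
stationary open probability of 0.8 and 2 pA unitary current; the last line
is the hydrophobic-thickness arithmetic for a di-C18:1 PC / POPG bilayer
(headgroup position 20.2 Å, headgroup FWHM 15.4 Å, repeat 65.9 Å →
hydrophobic thickness 25.0 Å).

## Command line

```sh
bilayergate saxs --input sample.csv --buffer buffer.csv --orders 2 --out out.json
bilayergate geom --pdb channel.pdb --preset kcsa-m1 --preset kcsa-m2 --out geom.json
bilayergate gating --trace trace.csv --fs 50000 --dead-time 0.3 --out gating.json
bilayergate simulate saxs --z-h 20 --sigma-h 3 --out curve.csv
bilayergate run --config pipeline.yaml
```

## Layout

| module | contents |
| --- | --- |
| `bilayergate.saxs` | curves, peak/tri-Gaussian models, bilayer structure |
| `bilayergate.geometry` | frames, alignment, helix angles, radial thickness, flips |
| `bilayergate.blocking` | blocking-transform standard errors |
| `bilayergate.gating` | levels, idealization, dwell mixtures, conductance, flux |
| `bilayergate.synthetic` | seeded generators with ground truth |
| `bilayergate.io` / `.pipeline` / `.cli` | formats, config-driven runner, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
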