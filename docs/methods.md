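# Methods

This note documents the models, estimators, numerical choices and
limitations behind `bilayergate`, in the order of the analysis chain.

## SAXS bilayer structure

**Model.** Extruded liposome suspensions produce quasi-Bragg lamellar
peaks at q_h = 2πh/d.  Each analysed order is fitted inside its own q
window with `baseline + A·γ²/((q−q0)²+γ²)`; the baseline-free analytic
area πAγ gives the form-factor magnitude F(h) = √area.  The relative
electron density is reconstructed as ρ*(z) = Σ_h ±F_h cos(2πhz/d) and
parameterised by the tri-Gaussian model (headgroup Gaussians at ±z_H,
negative core Gaussian).  Derived measures: FWHM_H = 2√(2 ln 2)·σ_H,
d_c = z_H − FWHM_H/2, 2d_c, d_hh = 2z_H, d_b = d_hh + FWHM_H,
d_w = d − d_b.  The d_c convention uses the headgroup *FWHM* half-width;
it is the relation consistent with all published thickness tables we
checked.

**Phases.** Peak intensities cannot determine the signs of F_h; they are
explicit configuration with the standard fluid-phase
phosphatidylcholine convention (−, −, +, −) for orders 1–4 as default,
and a warning whenever the default is used.

**Peak windows and d-spacing.** The first-order position is the global
maximum of a lightly box-smoothed intensity above q_min (default
0.05 Å⁻¹); order h gets the window h·q1 ± 0.45·q1 (lamellar indexing —
windows cannot overlap).  Fits run on raw data.  d is the 1/γ²-weighted
mean of 2πh/q0 over fitted orders.

**Band-limited tri-Gaussian fitting.** A reconstruction from n orders is
a band-limited image of the true profile.  Fitting the continuous
tri-Gaussian directly to it chases truncation ripples and is badly
biased (for a 2-order reconstruction of a typical profile, z_H fits
≈11% low).  `TriGaussianModel(profile, band_limit=(d, orders))`
therefore compares the model through its *own* truncated cosine series
(coefficients by trapezoidal integration on the data grid), which is
exact in the noiseless limit.  `analyze_curve` always uses this mode.
Caveat: n orders carry only n independent coefficients while the model
has four shape parameters plus a scale, so below ~4 orders the
parameters are only partially identified — the optimiser lands on the
solution manifold near its initialisation (z_H from the profile argmax).
With 4 orders recovery is ≈0.2% on z_H; with 2 orders expect ~5%.

**Exposure averaging.** Weak high orders sit near the noise floor of a
single exposure; `average_exposures` implements the standard
multiple-short-exposure protocol (the emulated acquisition uses ten
30-s exposures), reducing noise by √n_exposures before analysis.

**Numerics.** Bounded least squares (`scipy.optimize.least_squares` /
`curve_fit`), xtol=ftol=1e-8, ≤5000 evaluations; tri-Gaussian bounds
keep z_H, σ_H, σ_C within (0, z_max] and ρ_r in [0, 10]; a fit with z_H
below 5% of z_max raises a degenerate-fit error.  Scale and offset are
nuisance parameters (the reconstruction's units are arbitrary).
Standard errors come from the Gauss–Newton covariance at the optimum.

**Degenerate inputs.** A single diffraction order still yields a
reconstruction, but the tri-Gaussian stage refuses <2 orders.

## Frame geometry

**Alignment.** The pore axis is fixed once per frame: the
selectivity-filter Cα centroid (residues 75–79, all chains) moves to
the origin; the smallest-moment principal axis of the pore-domain Cα
cloud rotates onto +z; the sign is chosen so the filter side
(extracellular) is +z.  All observables then use the z axis, keeping
them consistent across frames.

**Helix observables.** Tilt is the angle of the endpoint Cα chord from
+z in [0°, 90°]; kink is 180° minus the angle between the lower and
upper segment vectors, both taken N→C (straight helix ≈ 180°);
hydrophobic length is |Δz| of the endpoint pair.  Shipped presets for
the KcsA pore domain: M1 tilt span 24–51, kink segments 24–42 / 44–51,
length span 26–45; M2 tilt span 86–122, kink segments 86–103 / 105–121,
length span 87–113.  (Two span conventions exist for length vs tilt;
both are explicit in the preset.)  Note the chord of a real helix only
parallels its axis when the endpoints share helical phase; for ideal
test helices we use spans with (n−1)·turn ≡ 0 (mod 360°).

**Radial hydrophobic thickness.** Selected atoms are the first
acyl-chain carbons after the glycerol ester (CHARMM36 names C22/C32;
configurable).  Leaflets are assigned by sign of z about a midplane
iterated twice from the leaflet means, excluding a ±2 Å band.  Per
annulus the thickness is the difference of leaflet z means pooled over
every atom of every frame (the time-averaged radial density), so sparse
bins use all their observations; the error bar is the blocking-transform
standard error of the per-frame thickness series, which is conservative
where single frames miss a leaflet.  Bins empty in either leaflet are
NaN, never zero.  `bulk_thickness` is the count-weighted mean beyond
r_min (default 45 Å — far field, outside the protein's deformation
footprint).  Radial binning assumes a whole, centred protein;
pre-wrapped frames are required (no minimum-image handling).

**Carbonyl flips.** The per-frame classifier is the sign of u·r̂, where
u is the unit backbone C→O vector and r̂ the outward radial unit vector
at the carbonyl carbon: negative = oxygen toward the axis ("inward"),
positive = "flipped".  Time-series classification applies hysteresis: a
switch requires |u·r̂| > 0.17 (≈10° past perpendicular), suppressing
chatter at the boundary.  Both criterion and band are configuration;
orientation-based criteria and dihedral-based ones broadly agree for
well-resolved flips.  Dwell statistics are run-length encodings with the
first and last dwell flagged as censored.

## Blocking-transform errors

Each transform halves the series by averaging neighbour pairs; at each
level the naive SEM estimate is √(c₀/(n−1)) with c₀ the biased sample
variance.  For correlated data the estimate grows with block size until
blocks exceed the correlation time.  The plateau is the first level
whose estimate changes, over each of the next two levels, by less than
max(5%, 1/√(2(n_blocks−1))) — the second term is the sampling noise of
the later level's own estimate, without which moderate-length series
never register as flat.  If no plateau exists the maximum-level estimate
is returned with a no-plateau flag.  Validation: within 25% of σ/√n on
iid data and of √((1+φ)/(1−φ))/√n on AR(1) data.

## Single-channel analysis

**Levels.** The all-points histogram (Freedman–Diaconis bins) is fitted
with two Gaussians; initial means come from a 1-D two-means split of the
samples, and a valley test (smoothed histogram must dip below 70% of the
smaller mode between the cluster means) rejects unimodal traces before
fitting.  Discrete (noiseless) traces resolve exactly from their two
dominant values.  The smaller-|i| level is "closed" (traces are assumed
baseline-corrected; drift is not modelled).

**Idealization.** Half-amplitude threshold at the level midpoint;
crossings define events; events shorter than the dead time (default
0.3 ms ≈ 1.5× the 10–90% rise of a 2 kHz Bessel filter) are merged,
shortest first, into their neighbours.  States alternate and durations
sum exactly to the trace span, so a noiseless trace round-trips through
resynthesis exactly.

**Dwell mixtures.** Durations below the dead time are unobservable, so
the exponential-mixture likelihood is conditioned on t ≥ t_d.  By
memorylessness the shifted data t − t_d follow an ordinary mixture with
the same means and reweighted proportions; EM runs on the shifted data
(log-space responsibilities; quantile-sliced initial means, which makes
the whole fit exactly scale-equivariant) and the weights are
un-truncated afterwards via w_j ∝ w'_j exp(t_d/τ_j).  Convergence: the
log-likelihood change below 1e-10 per event; component count by BIC over
k = 1..4, skipping degenerate (collapsed-mean) fits.  Reported means are
the component time constants in ms.

**Conductance and flux.** γ (pS) is 1000× the least-squares i–V slope,
reversal = −intercept/slope, requiring ≥3 distinct voltages.  Uptake
normalization is (counts − background)/(valinomycin − background);
relative activity divides by a reference lipid's value.

## Synthetic generators

All generators take a mandatory seed, use one `numpy` Generator per
call, are byte-deterministic, and attach a ground-truth record.  What
they emulate — and what they do not:

- `gen_trigaussian_saxs`: exact forward model of the reconstruction
  chain (true cosine coefficients → Lorentzian peaks → additive
  Gaussian noise).  No instrument smearing, polydispersity, or
  structure-factor (Caillé) effects, so passing recovery tests shows
  estimator correctness, not robustness to those real-data features.
- `gen_membrane_frames`: point atoms at the first-alkyl-carbon
  positions, uniform xy resampled per frame (lateral diffusion between
  widely spaced frames), z = ±(leaflet_z − deformation(r)) + noise.
  Defaults: 15 Å leaflet height (30 Å flat thickness), 0.5 Å atomic
  noise, ~65 Å² per lipid, 70/30 PC/PG.  Recovery tests use 150 frames —
  one frame per ns over a 150-ns analysis window — and a Gaussian dimple
  (depth 5 Å at r = 20 Å) mimicking the near-protein deformation.  No
  correlated undulations or finite lipid shapes.
- `gen_ideal_helix`: canonical α-helix (rise 1.5 Å, radius 2.3 Å, turn
  100°) with optional tilt and kink; radius 0 degenerates to exact axis
  points for angle fixtures.  `synthetic_kcsa_tetramer` is a
  **constructed** closed-state pore-domain Cα model (labelled synthetic)
  whose M1/M2 geometry is built to the published crystal-structure
  values (tilt 20°/33°, kink 140°/169°); it exercises the full
  alignment-and-measurement path where the real coordinates are not
  shipped.
- `gen_markov_trace`: continuous-time two-state gating (or an
  aggregated closed-dwell mixture) sampled at fs with white Gaussian
  noise; stationary start.  No 1/f or correlated noise, no filter
  artefacts.
- `gen_flux_counts`: first-order uptake background + capacity·(1−e^(−kt)),
  optional Poisson counting noise.
- `gen_flip_series`: per-frame two-state Markov chain with stationary
  initial distribution.

## Problem sizes

Defaults keep every recovery suite fast while statistically meaningful:
membrane recovery uses 150 frames × 300 lipids/leaflet; gating recovery
uses 40-s traces at 25 kHz across P_open ∈ {0.1, 0.5, 0.8}; dwell
mixtures use 5000 events; blocking validation uses 4096 (iid) and 65536
(AR(1)) samples; the SAXS round trip averages ten exposures of ~1900
points.  The full test suite runs in a few seconds.

## Known limitations

- Phase assignment is conventional, not determined; wrong phases yield a
  wrong (but internally consistent) profile.
- Tri-Gaussian parameters are only partially identified below ~4
  diffraction orders (see above); reported uncertainties do not include
  phase or truncation ambiguity.
- Lamellarity of extruded (typically unilamellar) liposomes is assumed
  compatible with lamellar indexing, mirroring the analysis convention
  of the emulated experiments.
- The leaflet assignment is geometric; membranes folded back over the
  midplane (extreme deformations) would be misassigned.
- Open probability is aggregate over the trace, not per-sweep; multi-
  channel patches are out of scope.
- Dwell components with nearly equal time constants are flagged
  degenerate rather than resolved; Table-style "±0" components are
  treated as point estimates.
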